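"""Five-step lactic acid recovery flowsheet.

The spent-media stream is propagated through microfiltration (MF), activated
carbon (AC), ion exchange (IEX), staged nanofiltration (NF/RO) and a
multi-effect evaporator (MEE), producing every material flow A-M:

====  =========================================
A     spent media feed
B     MF retentate (to wastewater)
C     MF permeate
D     AC regeneration water demand (recycled water)
E     AC regeneration effluent (to wastewater)
F     AC eluate
G     IEX regenerant (1 M H2SO4)
H     IEX regeneration effluent (to wastewater)
I     IEX eluate
J     NF retentate (concentrated lactic acid)
K     NF permeate (water for reuse)
L     MEE distillate (water for reuse)
M     88 wt% lactic acid product
====  =========================================

Streams are tracked by component mass rate; with the dilute-stream density of
1.00 kg/L the volumetric rate equals the total mass rate.  Cations are carried
as charge equivalents (``salts``, eq/h) whose mass is negligible and excluded
from the mass/volume closure.  No reactions occur anywhere, so every component
is conserved exactly at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .scenario import (
    FacilityScenario,
    ProcessParameterBook,
    ScenarioBundle,
    SpentMediaComposition,
    L_PER_FT3,
)

__all__ = [
    "Stream",
    "UnitOpReport",
    "FlowsheetResult",
    "WaterBalance",
    "spent_media_rate",
    "make_feed",
    "run_mf",
    "run_ac",
    "run_iex",
    "run_nf",
    "run_mee",
    "solve_flowsheet",
    "water_balance",
]

#: kg of H2SO4 per mole
H2SO4_KG_PER_MOL = 0.098

MASS_COMPONENTS = ("lactic_acid", "glucose", "water", "protein")
COMPONENTS = MASS_COMPONENTS + ("salts",)


@dataclass
class Stream:
    """A material flow: volumetric rate plus per-component mass rates.

    ``component_mass_rates`` holds kg/h for the mass components and eq/h for
    the ``salts`` charge carrier.
    """

    label: str
    volumetric_rate: float  # L/h
    component_mass_rates: dict[str, float] = field(default_factory=dict)
    density: float = 1.0  # kg/L

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            self.component_mass_rates.setdefault(name, 0.0)
        negative = [k for k, v in self.component_mass_rates.items() if v < -1e-12]
        if self.volumetric_rate < -1e-12 or negative:
            raise ValueError(f"stream {self.label}: negative rate ({negative})")

    def __getitem__(self, component: str) -> float:
        return self.component_mass_rates[component]

    @property
    def total_mass(self) -> float:
        """kg/h of tracked mass (salt equivalents excluded)."""
        return sum(self.component_mass_rates[c] for c in MASS_COMPONENTS)

    def conc(self, component: str) -> float:
        """g/L (or eq/L for ``salts``); zero for an empty stream."""
        if self.volumetric_rate == 0:
            return 0.0
        scale = 1000.0 if component != "salts" else 1.0
        return self.component_mass_rates[component] / self.volumetric_rate * scale


def _stream(label: str, rates: dict[str, float], density: float = 1.0) -> Stream:
    """Build a stream whose volume follows from its mass (dilute assumption)."""
    rates = {c: max(0.0, rates.get(c, 0.0)) for c in COMPONENTS}
    vol = sum(rates[c] for c in MASS_COMPONENTS) / density
    return Stream(label=label, volumetric_rate=vol, component_mass_rates=rates, density=density)


@dataclass
class UnitOpReport:
    """One unit operation: streams in/out, recovery, utilities and sizing."""

    name: str
    inlet: Stream
    outlets: dict[str, Stream]
    aux_inlets: dict[str, Stream] = field(default_factory=dict)
    la_recovery: float = 1.0
    #: steam kg/h, electricity kWh/h, regen water L/h, sulfuric acid kg/h
    utility_demands: dict[str, float] = field(default_factory=dict)
    #: membrane area m2, bed volume L, bed mass kg, evaporation kg/h ...
    sizing: dict[str, float] = field(default_factory=dict)

    def conservation_residual(self) -> float:
        """Largest relative component imbalance across the operation."""
        worst = 0.0
        for comp in COMPONENTS:
            inflow = self.inlet.component_mass_rates[comp] + sum(
                s.component_mass_rates[comp] for s in self.aux_inlets.values()
            )
            outflow = sum(s.component_mass_rates[comp] for s in self.outlets.values())
            scale = max(abs(inflow), abs(outflow), 1e-30)
            worst = max(worst, abs(inflow - outflow) / scale)
        return worst


@dataclass
class FlowsheetResult:
    streams: dict[str, Stream]
    step_reports: list[UnitOpReport]
    product_rate_88pct: float  # kg/h of 88 wt% solution
    contained_la_rate: float  # kg/h of 100% lactic acid
    overall_recovery: float
    annual_product_mt: float  # MT/yr of 88% solution
    la_per_kg_cm: float  # kg 88% product per kg CM
    media_rate_lph: float
    operating_hours: float
    #: annual chemical/consumable/utility ledger feeding costing and the LCI.
    annual_ledger: dict[str, float] = field(default_factory=dict)
    zero_feed: bool = False

    @property
    def annual_product_kg(self) -> float:
        return self.product_rate_88pct * self.operating_hours


@dataclass
class WaterBalance:
    recovered_water_lph: dict[str, float]  # NF permeate K, MEE distillate L
    regen_water_demand_lph: float  # flow D
    baseline_reuse_lph: float
    net_water_lpm: float
    net_water_m3_per_yr: float
    wastewater_lph: dict[str, float]  # flows B, E, H
    baseline_wastewater_lph: float
    net_wastewater_change_lpm: float  # negative = avoided treatment
    net_wastewater_change_m3_per_yr: float
    closure_residual: float

    @property
    def total_recovered_lph(self) -> float:
        return sum(self.recovered_water_lph.values())

    @property
    def total_wastewater_lph(self) -> float:
        return sum(self.wastewater_lph.values())


# ---------------------------------------------------------------------------
# feed
# ---------------------------------------------------------------------------

def spent_media_rate(facility: FacilityScenario) -> float:
    """Hourly spent-media production, L/h.

    rate = (media_per_batch / batch_mass) * annual CM production / hours.
    """
    if facility.operating_hours <= 0:
        raise ValueError("operating_hours must be positive")
    return (
        facility.media_per_batch
        / facility.batch_mass
        * facility.cm_annual_production
        / facility.operating_hours
    )


def make_feed(rate_lph: float, media: SpentMediaComposition) -> Stream:
    """Spent-media stream A from a volumetric rate and composition."""
    la = rate_lph * media.lactic_acid_conc / 1000.0
    glucose = rate_lph * media.glucose_conc / 1000.0
    protein = rate_lph * media.protein_conc / 1000.0
    salts = rate_lph * media.cation_equivalents  # eq/h
    water = rate_lph * media.density - (la + glucose + protein)
    if water < 0:
        raise ValueError("spent media solutes exceed the stream mass")
    return Stream(
        label="A",
        volumetric_rate=rate_lph,
        component_mass_rates={
            "lactic_acid": la,
            "glucose": glucose,
            "protein": protein,
            "salts": salts,
            "water": water,
        },
        density=media.density,
    )


# ---------------------------------------------------------------------------
# unit operations
# ---------------------------------------------------------------------------

def run_mf(feed: Stream, params: ProcessParameterBook) -> UnitOpReport:
    """Crossflow microfiltration: protein to retentate B, solutes with water to C.

    Non-protein solutes are assumed uniformly distributed between permeate and
    retentate, so the passage fraction is (CF - 1)/CF at concentration factor
    CF (override with ``mf_la_passage`` for lactate).
    """
    cf = params.mf_concentration_factor
    if cf <= 1:
        raise ValueError(f"mf_concentration_factor must exceed 1, got {cf}")
    water_passage = (cf - 1.0) / cf
    la_passage = params.mf_la_passage if params.mf_la_passage is not None else water_passage

    perm = {
        "lactic_acid": feed["lactic_acid"] * la_passage,
        "glucose": feed["glucose"] * water_passage,
        "salts": feed["salts"] * water_passage,
        "protein": 0.0,
        "water": feed["water"] * water_passage,
    }
    ret = {c: feed.component_mass_rates[c] - perm[c] for c in COMPONENTS}
    permeate = _stream("C", perm, feed.density)
    retentate = _stream("B", ret, feed.density)
    area = permeate.volumetric_rate / params.mf_flux_lmh
    elec = params.specific_electricity_kwh_per_m3["mf"] * feed.volumetric_rate / 1000.0
    return UnitOpReport(
        name="membrane_filtration",
        inlet=feed,
        outlets={"permeate": permeate, "retentate": retentate},
        la_recovery=la_passage,
        utility_demands={"electricity_kwh_per_h": elec},
        sizing={"membrane_area_m2": area},
    )


def run_ac(feed: Stream, params: ProcessParameterBook) -> UnitOpReport:
    """Duplex activated-carbon beds: glucose removal, water-regenerated.

    One bed holds a loading cycle's glucose at the working capacity while the
    twin regenerates with ``ac_regen_bed_volumes`` of recycled water (flow D),
    discharged to wastewater (flow E).
    """
    if params.ac_glucose_capacity <= 0:
        raise ValueError("ac_glucose_capacity must be positive")
    glucose_removed = feed["glucose"] * (1.0 - params.ac_glucose_residual)
    la_lost = feed["lactic_acid"] * (1.0 - params.ac_la_recovery)

    cycle_glucose = feed["glucose"] * params.ac_cycle_hours  # kg per loading cycle
    bed_mass = cycle_glucose / (params.ac_glucose_capacity / 1000.0) if cycle_glucose else 0.0
    bed_volume = bed_mass / params.ac_bulk_density
    regen_lph = params.ac_regen_bed_volumes * bed_volume / params.ac_cycle_hours

    regen_in = _stream("D", {"water": regen_lph * feed.density})
    eluate = _stream(
        "F",
        {
            "lactic_acid": feed["lactic_acid"] - la_lost,
            "glucose": feed["glucose"] - glucose_removed,
            "salts": feed["salts"],
            "water": feed["water"],
        },
        feed.density,
    )
    effluent = _stream(
        "E",
        {
            "lactic_acid": la_lost,
            "glucose": glucose_removed,
            "water": regen_in["water"],
        },
        feed.density,
    )
    elec = params.specific_electricity_kwh_per_m3["ac"] * feed.volumetric_rate / 1000.0
    return UnitOpReport(
        name="activated_carbon",
        inlet=feed,
        outlets={"eluate": eluate, "regen_effluent": effluent},
        aux_inlets={"regen_water": regen_in},
        la_recovery=params.ac_la_recovery,
        utility_demands={
            "electricity_kwh_per_h": elec,
            "regen_water_lph": regen_lph,
        },
        sizing={"bed_mass_kg": bed_mass, "bed_volume_l": bed_volume, "n_beds": 2},
    )


def run_iex(feed: Stream, params: ProcessParameterBook) -> UnitOpReport:
    """Duplex cation exchange: salt removal, regenerated with 1 M H2SO4.

    Bed volume holds one cycle's cation equivalents at the resin capacity;
    regeneration takes ``iex_regen_bed_volumes`` of acid (flow G) discharged
    to wastewater (flow H).
    """
    if params.iex_resin_capacity <= 0:
        raise ValueError("iex_resin_capacity must be positive")
    salts_removed = feed["salts"] * (1.0 - params.iex_salt_residual)
    la_lost = feed["lactic_acid"] * (1.0 - params.iex_la_recovery)

    cycle_eq = feed["salts"] * params.iex_cycle_hours
    bed_volume = cycle_eq / params.iex_resin_capacity  # L resin
    acid_lph = params.iex_regen_bed_volumes * bed_volume / params.iex_cycle_hours
    acid_kg_ph = acid_lph * params.iex_regen_acid_molarity * H2SO4_KG_PER_MOL

    regen_in = _stream("G", {"water": acid_lph * feed.density})  # acid carried as utility
    eluate = _stream(
        "I",
        {
            "lactic_acid": feed["lactic_acid"] - la_lost,
            "glucose": feed["glucose"],
            "salts": feed["salts"] - salts_removed,
            "water": feed["water"],
        },
        feed.density,
    )
    effluent = _stream(
        "H",
        {"lactic_acid": la_lost, "salts": salts_removed, "water": regen_in["water"]},
        feed.density,
    )
    elec = params.specific_electricity_kwh_per_m3["iex"] * feed.volumetric_rate / 1000.0
    return UnitOpReport(
        name="iex",
        inlet=feed,
        outlets={"eluate": eluate, "regen_effluent": effluent},
        aux_inlets={"regenerant": regen_in},
        la_recovery=params.iex_la_recovery,
        utility_demands={
            "electricity_kwh_per_h": elec,
            "sulfuric_acid_kg_per_h": acid_kg_ph,
            "regen_acid_lph": acid_lph,
        },
        sizing={"bed_volume_l": bed_volume, "n_beds": 2},
    )


def run_nf(feed: Stream, params: ProcessParameterBook) -> UnitOpReport:
    """Three-stage NF/RO concentration to 77 g/L lactic acid.

    Lactic acid yield is ``retention ** stages``; retentate volume is set so
    the retentate hits ``nf_target_conc`` (or, when
    ``nf_retentate_volume_lph`` is set, the fixed baseline permeate duty).
    Residual neutral solutes leave with the permeate.
    """
    retention = params.nf_stage_retention
    if not 0 < retention <= 1:
        raise ValueError("nf_stage_retention must be in (0, 1]")
    la_yield = retention**params.nf_stages
    la_ret = feed["lactic_acid"] * la_yield

    if params.nf_retentate_volume_lph is not None:
        ret_vol = params.nf_retentate_volume_lph
    else:
        feed_conc = feed.conc("lactic_acid")
        if params.nf_target_conc <= feed_conc:
            raise ValueError(
                f"nf_target_conc ({params.nf_target_conc} g/L) must exceed the "
                f"feed concentration ({feed_conc:.2f} g/L)"
            )
        ret_vol = la_ret * 1000.0 / params.nf_target_conc
    ret_water = ret_vol * feed.density - la_ret
    if ret_water < 0:
        raise ValueError("NF retentate volume cannot hold the retained lactic acid")

    retentate = _stream("J", {"lactic_acid": la_ret, "water": ret_water}, feed.density)
    permeate = _stream(
        "K",
        {
            "lactic_acid": feed["lactic_acid"] - la_ret,
            "glucose": feed["glucose"],
            "salts": feed["salts"],
            "water": feed["water"] - ret_water,
        },
        feed.density,
    )
    area = permeate.volumetric_rate / params.nf_flux_lmh
    elec = params.specific_electricity_kwh_per_m3["nf"] * feed.volumetric_rate / 1000.0
    return UnitOpReport(
        name="nf_ro",
        inlet=feed,
        outlets={"retentate": retentate, "permeate": permeate},
        la_recovery=la_yield,
        utility_demands={"electricity_kwh_per_h": elec},
        sizing={"membrane_area_m2": area, "n_stages": params.nf_stages},
    )


def run_mee(feed: Stream, params: ProcessParameterBook) -> UnitOpReport:
    """Five-effect evaporation to the 88 wt% product.

    product = lactic acid / 0.88; steam = evaporated water / steam economy.
    """
    w = params.product_mass_fraction
    total = feed.total_mass
    feed_frac = feed["lactic_acid"] / total if total > 0 else 0.0
    if feed_frac > w * (1.0 + 1e-12):
        raise ValueError(
            f"MEE feed is already above the target mass fraction ({feed_frac:.3f} > {w})"
        )
    product_mass = feed["lactic_acid"] / w
    product_water = product_mass - feed["lactic_acid"]
    evaporated = feed["water"] - product_water
    steam = evaporated / params.mee_steam_economy

    product = Stream(
        label="M",
        volumetric_rate=product_mass,  # tracked by mass; density ~1 placeholder
        component_mass_rates={"lactic_acid": feed["lactic_acid"], "water": product_water},
    )
    distillate = _stream("L", {"water": evaporated}, feed.density)
    elec = params.specific_electricity_kwh_per_m3["mee"] * feed.volumetric_rate / 1000.0
    return UnitOpReport(
        name="mee",
        inlet=feed,
        outlets={"product": product, "distillate": distillate},
        la_recovery=1.0,
        utility_demands={"steam_kg_per_h": steam, "electricity_kwh_per_h": elec},
        sizing={"evaporation_kg_per_h": evaporated, "n_effects": params.mee_effects},
    )


# ---------------------------------------------------------------------------
# full flowsheet
# ---------------------------------------------------------------------------

def solve_flowsheet(bundle: ScenarioBundle) -> FlowsheetResult:
    """Chain the five unit operations and assemble flows A-M plus the ledger."""
    facility, media, params = bundle.facility, bundle.spent_media, bundle.process
    rate = spent_media_rate(facility)
    feed = make_feed(rate, media)

    mf = run_mf(feed, params)
    ac = run_ac(mf.outlets["permeate"], params)
    iex = run_iex(ac.outlets["eluate"], params)
    nf = run_nf(iex.outlets["eluate"], params)
    mee = run_mee(nf.outlets["retentate"], params)
    reports = [mf, ac, iex, nf, mee]

    streams = {
        "A": feed,
        "B": mf.outlets["retentate"],
        "C": mf.outlets["permeate"],
        "D": ac.aux_inlets["regen_water"],
        "E": ac.outlets["regen_effluent"],
        "F": ac.outlets["eluate"],
        "G": iex.aux_inlets["regenerant"],
        "H": iex.outlets["regen_effluent"],
        "I": iex.outlets["eluate"],
        "J": nf.outlets["retentate"],
        "K": nf.outlets["permeate"],
        "L": mee.outlets["distillate"],
        "M": mee.outlets["product"],
    }

    product_rate = streams["M"].total_mass
    contained = streams["M"]["lactic_acid"]
    feed_la = rate * media.lactic_acid_conc / 1000.0
    zero_feed = feed_la == 0
    recovery = 0.0 if zero_feed else contained / feed_la

    hours = facility.operating_hours
    electricity = sum(r.utility_demands.get("electricity_kwh_per_h", 0.0) for r in reports)
    lifetime = bundle.costs.membrane_lifetime_years
    ledger = {
        "steam_kg": mee.utility_demands["steam_kg_per_h"] * hours,
        "electricity_kwh": electricity * hours,
        "sulfuric_acid_kg": iex.utility_demands["sulfuric_acid_kg_per_h"] * hours,
        "caustic_kg": params.cip_caustic_kg_per_m3_media * rate / 1000.0 * hours,
        "activated_carbon_kg": 2.0 * ac.sizing["bed_mass_kg"] / params.ac_carbon_lifetime_years,
        "iex_resin_ft3": 2.0 * iex.sizing["bed_volume_l"] / L_PER_FT3 / params.iex_resin_lifetime_years,
        "mf_membrane_m2": mf.sizing["membrane_area_m2"] / lifetime,
        "nf_membrane_m2": nf.sizing["membrane_area_m2"] / lifetime,
    }

    return FlowsheetResult(
        streams=streams,
        step_reports=reports,
        product_rate_88pct=product_rate,
        contained_la_rate=contained,
        overall_recovery=recovery,
        annual_product_mt=product_rate * hours / 1000.0,
        la_per_kg_cm=product_rate * hours / facility.cm_annual_production,
        media_rate_lph=rate,
        operating_hours=hours,
        annual_ledger=ledger,
        zero_feed=zero_feed,
    )


def water_balance(result: FlowsheetResult, facility: FacilityScenario) -> WaterBalance:
    """Net water use and wastewater change versus the reference facility.

    The reference facility draws ``facility_water_per_media`` L of water per L
    of media and already reuses ``water_reuse_fraction`` of it; the recovery
    block replaces that reuse with NF permeate (K) and MEE distillate (L)
    while consuming regeneration water (D) and sending flows B, E, H to
    wastewater treatment.
    """
    s = result.streams
    hours = result.operating_hours
    recovered = {
        "nf_permeate": s["K"].volumetric_rate,
        "mee_distillate": s["L"].volumetric_rate,
    }
    regen_demand = s["D"].volumetric_rate
    facility_water = facility.facility_water_per_media * result.media_rate_lph
    baseline_reuse = facility.water_reuse_fraction * facility_water
    net_water_lph = regen_demand + baseline_reuse - sum(recovered.values())

    wastewater = {
        "mf_retentate": s["B"].volumetric_rate,
        "ac_regen": s["E"].volumetric_rate,
        "iex_regen": s["H"].volumetric_rate,
    }
    baseline_ww = (1.0 - facility.water_reuse_fraction) * facility_water
    ww_change_lph = sum(wastewater.values()) - baseline_ww

    # closure over the recovery block: water in (A + D + G) = water out
    water_in = s["A"]["water"] + s["D"]["water"] + s["G"]["water"]
    water_out = sum(s[k]["water"] for k in ("B", "E", "H", "K", "L", "M"))
    residual = abs(water_in - water_out) / max(water_in, 1e-30)

    to_m3yr = hours / 1000.0
    return WaterBalance(
        recovered_water_lph=recovered,
        regen_water_demand_lph=regen_demand,
        baseline_reuse_lph=baseline_reuse,
        net_water_lpm=net_water_lph / 60.0,
        net_water_m3_per_yr=net_water_lph * to_m3yr,
        wastewater_lph=wastewater,
        baseline_wastewater_lph=baseline_ww,
        net_wastewater_change_lpm=ww_change_lph / 60.0,
        net_wastewater_change_m3_per_yr=ww_change_lph * to_m3yr,
        closure_residual=residual,
    )
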