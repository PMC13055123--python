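"""Bit-stable report writers for every result table.

A :func:`run` call executes the full pipeline for a scenario config and emits
CSV analogues of the stream table and the capital/operating/financial/
allocation/energy/water summaries, plus a JSON manifest.  Output bytes are
deterministic for a fixed config; ``round_like_paper`` applies display
rounding (whole dollars, two-decimal per-kg costs, one-decimal impacts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .flowsheet import COMPONENTS
from .pipeline import PipelineResult, run_bundle
from .scenario import ScenarioBundle, load_scenario

__all__ = ["RunManifest", "run", "write_reports", "scenario_digest"]

# destination of each flow letter in the flowsheet
_DESTINATIONS = {
    "A": "microfiltration feed",
    "B": "wastewater treatment",
    "C": "activated carbon feed",
    "D": "activated carbon regeneration (recycled water)",
    "E": "wastewater treatment",
    "F": "ion exchange feed",
    "G": "ion exchange regeneration (1 M H2SO4)",
    "H": "wastewater treatment",
    "I": "NF/RO feed",
    "J": "evaporator feed",
    "K": "water reuse",
    "L": "water reuse",
    "M": "88% lactic acid product",
}


@dataclass
class RunManifest:
    scenario_digest: str
    package_version: str
    seed: int | None
    timestamp: str
    files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def scenario_digest(bundle: ScenarioBundle) -> str:
    """SHA-256 over the canonical scenario JSON; changes iff any field does."""
    canonical = json.dumps(bundle.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _round(value: float, ndigits: int, enabled: bool) -> float:
    return round(value, ndigits) if enabled else value


def stream_table(res: PipelineResult) -> pd.DataFrame:
    rows = []
    for label in sorted(res.flowsheet.streams):
        s = res.flowsheet.streams[label]
        row = {"flow": label, "volumetric_rate_lph": s.volumetric_rate}
        for comp in COMPONENTS:
            unit = "eq_per_h" if comp == "salts" else "kg_per_h"
            row[f"{comp}_{unit}"] = s.component_mass_rates[comp]
        row["destination"] = _DESTINATIONS[label]
        rows.append(row)
    return pd.DataFrame(rows)


def capex_table(res: PipelineResult, paper_rounding: bool = False) -> pd.DataFrame:
    rows = [
        {
            "unit_operation": op,
            "total_cost_usd": _round(cost, 0, paper_rounding),
            "percent_of_total": _round(pct, 0, paper_rounding),
        }
        for op, cost, pct in res.capex.lines
    ]
    rows.append(
        {
            "unit_operation": "total_capex",
            "total_cost_usd": _round(res.capex.total, 0, paper_rounding),
            "percent_of_total": 100.0,
        }
    )
    return pd.DataFrame(rows)


def opex_table(res: PipelineResult, paper_rounding: bool = False) -> pd.DataFrame:
    rows = [
        {
            "item": item,
            "annual_cost_usd": _round(annual, 0, paper_rounding),
            "cost_per_kg_88pct": _round(per_kg, 2, paper_rounding),
        }
        for item, annual, per_kg in res.opex.lines
    ]
    rows.append(
        {
            "item": "total_opex",
            "annual_cost_usd": _round(res.opex.total_annual, 0, paper_rounding),
            "cost_per_kg_88pct": _round(res.opex.total_per_kg, 2, paper_rounding),
        }
    )
    return pd.DataFrame(rows)


def financial_table(res: PipelineResult, paper_rounding: bool = False) -> pd.DataFrame:
    fin = res.financial
    rows = [
        ("annual_revenue_usd", _round(fin.annual_revenue, 0, paper_rounding)),
        ("annual_cogs_usd", _round(fin.annual_cogs, 0, paper_rounding)),
        ("annual_profit_usd", _round(fin.annual_profit, 0, paper_rounding)),
        ("cogs_per_kg_88pct", _round(fin.cogs_per_kg_88pct, 2, paper_rounding)),
        ("simple_payback_years", _round(fin.simple_payback_years, 1, paper_rounding)),
        ("cm_cogs_offset_per_kg", _round(fin.cm_cogs_offset_per_kg, 2, paper_rounding)),
    ]
    return pd.DataFrame(rows, columns=["metric", "value"])


def allocation_table(res: PipelineResult, paper_rounding: bool = False) -> pd.DataFrame:
    facility = res.bundle.facility
    rows = [
        {
            "method": "baseline_no_recovery",
            "gwp_kg_co2eq_per_kg_cm": facility.cm_baseline_gwp,
            "gwp_pct_change": 0.0,
            "ced_mj_per_kg_cm": facility.cm_baseline_ced,
            "ced_pct_change": 0.0,
        }
    ]
    for method, alloc in res.allocations.items():
        rows.append(
            {
                "method": method,
                "gwp_kg_co2eq_per_kg_cm": _round(alloc.cm_gwp, 1, paper_rounding),
                "gwp_pct_change": _round(alloc.pct_change_gwp, 1, paper_rounding),
                "ced_mj_per_kg_cm": _round(alloc.cm_ced, 1, paper_rounding),
                "ced_pct_change": _round(alloc.pct_change_ced, 1, paper_rounding),
            }
        )
    return pd.DataFrame(rows)


def energy_table(res: PipelineResult) -> pd.DataFrame:
    hours = res.flowsheet.operating_hours
    rows = [
        {
            "unit_operation": r.name,
            "electricity_kwh_per_yr": r.utility_demands.get("electricity_kwh_per_h", 0.0) * hours,
            "steam_mt_per_yr": r.utility_demands.get("steam_kg_per_h", 0.0) * hours / 1000.0,
        }
        for r in res.flowsheet.step_reports
    ]
    return pd.DataFrame(rows)


def water_table(res: PipelineResult) -> pd.DataFrame:
    w = res.water
    rows = [
        ("nf_permeate_recovered_lph", w.recovered_water_lph["nf_permeate"]),
        ("mee_distillate_recovered_lph", w.recovered_water_lph["mee_distillate"]),
        ("regen_water_demand_lph", w.regen_water_demand_lph),
        ("baseline_reuse_lph", w.baseline_reuse_lph),
        ("net_water_lpm", w.net_water_lpm),
        ("net_water_m3_per_yr", w.net_water_m3_per_yr),
        ("wastewater_mf_retentate_lph", w.wastewater_lph["mf_retentate"]),
        ("wastewater_ac_regen_lph", w.wastewater_lph["ac_regen"]),
        ("wastewater_iex_regen_lph", w.wastewater_lph["iex_regen"]),
        ("baseline_wastewater_lph", w.baseline_wastewater_lph),
        ("net_wastewater_change_lpm", w.net_wastewater_change_lpm),
        ("net_wastewater_change_m3_per_yr", w.net_wastewater_change_m3_per_yr),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value"])


def write_reports(
    res: PipelineResult,
    out_dir: str | Path,
    seed: int | None = None,
    round_like_paper: bool = False,
) -> RunManifest:
    """Write all result tables plus a manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "streams.csv": stream_table(res),
        "capital_costs.csv": capex_table(res, round_like_paper),
        "operating_costs.csv": opex_table(res, round_like_paper),
        "financial_summary.csv": financial_table(res, round_like_paper),
        "allocation.csv": allocation_table(res, round_like_paper),
        "energy_by_unit.csv": energy_table(res),
        "water_balance.csv": water_table(res),
    }
    files = []
    for name, frame in tables.items():
        frame.to_csv(out / name, index=False, float_format="%.6f")
        files.append(name)
    manifest = RunManifest(
        scenario_digest=scenario_digest(res.bundle),
        package_version=__version__,
        seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
        files=sorted(files),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def run(
    config: str | Path | ScenarioBundle,
    out_dir: str | Path,
    seed: int | None = None,
    round_like_paper: bool = False,
) -> RunManifest:
    """Execute the full pipeline for a config file and write all reports."""
    bundle = config if isinstance(config, ScenarioBundle) else load_scenario(config)
    res = run_bundle(bundle)
    return write_reports(res, out_dir, seed=seed, round_like_paper=round_like_paper)
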