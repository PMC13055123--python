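"""Capital cost, operating cost, COGS and financial metrics.

Capital costs scale each unit operation's installed-cost anchor by a power law
on its sizing capacity (cost = anchor * (capacity / anchor_capacity) ** n,
default n = 0.7) with an optional CEPCI escalation; at the baseline capacities
the statement reproduces the anchors exactly.

Operating costs price the flowsheet's annual ledger at the cost book's unit
prices.  Avoided wastewater treatment enters as a credit.  Revenue and annual
COGS are computed on contained (100%) lactic acid tonnage while the per-kg
COGS is reported per kg of 88% solution -- the only convention under which the
reference financial summary is internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .flowsheet import FlowsheetResult, WaterBalance
from .scenario import CostBook, FacilityScenario

__all__ = [
    "CapexStatement",
    "OpexStatement",
    "FinancialSummary",
    "cepci_adjust",
    "capital_costs",
    "operating_costs",
    "financial_summary",
]


@dataclass
class CapexStatement:
    lines: list[tuple[str, float, float]]  # (unit op, installed $, % of total)
    total: float


@dataclass
class OpexStatement:
    lines: list[tuple[str, float, float]]  # (item, annual $, $ per kg 88% LA)
    total_annual: float
    total_per_kg: float


@dataclass
class FinancialSummary:
    annual_revenue: float
    annual_cogs: float
    annual_profit: float
    cogs_per_kg_88pct: float
    simple_payback_years: float  # inf when not viable
    cm_cogs_offset_per_kg: float
    viable: bool


def cepci_adjust(cost: float, index_from: float, index_to: float) -> float:
    """Escalate a cost between Chemical Engineering Plant Cost Index years."""
    if index_from <= 0 or index_to <= 0:
        raise ValueError("CEPCI indices must be positive")
    return cost * index_to / index_from


# sizing capacity each capex anchor scales on
_CAPACITY_KEYS = {
    "membrane_filtration": ("feed_lph", None),
    "activated_carbon": ("bed_volume_l", "activated_carbon"),
    "iex": ("bed_volume_l", "iex"),
    "nf_ro": ("membrane_area_m2", "nf_ro"),
    "mee": ("evaporation_kg_per_h", "mee"),
    "product_storage": ("product_rate", None),
}


def _capacities(result: FlowsheetResult) -> dict[str, float]:
    by_name = {r.name: r for r in result.step_reports}
    return {
        "membrane_filtration": result.media_rate_lph,
        "activated_carbon": by_name["activated_carbon"].sizing["bed_volume_l"],
        "iex": by_name["iex"].sizing["bed_volume_l"],
        "nf_ro": by_name["nf_ro"].sizing["membrane_area_m2"],
        "mee": by_name["mee"].sizing["evaporation_kg_per_h"],
        "product_storage": result.product_rate_88pct,
    }


def capital_costs(
    result: FlowsheetResult,
    costbook: CostBook,
    scale_exponent: Optional[float] = None,
) -> CapexStatement:
    """Installed-cost statement for the six unit operations."""
    exponent = costbook.capex_scale_exponent if scale_exponent is None else scale_exponent
    capacities = _capacities(result)
    idx_from, idx_to = costbook.cepci_reference
    lines: list[tuple[str, float, float]] = []
    for op, anchor_cost in costbook.capex_anchor.items():
        if op not in capacities:
            raise KeyError(f"no sizing capacity computed for capex anchor {op!r}")
        anchor_cap = costbook.capex_anchor_capacity.get(op)
        if anchor_cap is None:
            raise KeyError(f"no anchor capacity for capex line {op!r}")
        ratio = capacities[op] / anchor_cap if anchor_cap else 0.0
        cost = cepci_adjust(anchor_cost * ratio**exponent, idx_from, idx_to)
        lines.append((op, cost, 0.0))
    total = sum(cost for _, cost, _ in lines)
    lines = [(op, cost, 100.0 * cost / total if total else 0.0) for op, cost, _ in lines]
    return CapexStatement(lines=lines, total=total)


def operating_costs(
    result: FlowsheetResult, water: WaterBalance, costbook: CostBook
) -> OpexStatement:
    """Annual operating-cost statement (chemicals, consumables, utilities).

    Billed net-water and wastewater-credit quantities come from the cost
    book's pinned ledger values (scaled with media rate) when set, otherwise
    from the physical water balance.
    """
    ledger = result.annual_ledger
    prices = costbook.unit_prices
    scale = result.media_rate_lph / costbook.anchor_media_rate_lph

    def price(key: str) -> float:
        if key not in prices:
            raise KeyError(f"no unit price for inventory item {key!r}")
        return prices[key]

    if costbook.billed_net_water_mt is not None:
        net_water_mt = costbook.billed_net_water_mt * scale
    else:
        net_water_mt = water.net_water_m3_per_yr  # 1 m3 ~ 1 MT
    if costbook.billed_net_wastewater_m3 is not None:
        ww_credit_m3 = costbook.billed_net_wastewater_m3 * scale
    else:
        ww_credit_m3 = max(0.0, -water.net_wastewater_change_m3_per_yr)

    annual: list[tuple[str, float]] = [
        ("sulfuric_acid", ledger["sulfuric_acid_kg"] / 1000.0 * price("sulfuric_acid_per_mt")),
        ("caustic", ledger["caustic_kg"] / 1000.0 * price("caustic_per_mt")),
        ("mf_membrane", ledger["mf_membrane_m2"] * price("mf_membrane_per_m2")),
        ("activated_carbon", ledger["activated_carbon_kg"] * price("activated_carbon_per_kg")),
        ("iex_resins", ledger["iex_resin_ft3"] * price("iex_resin_per_ft3")),
        ("nf_membranes", ledger["nf_membrane_m2"] * price("nf_membrane_per_m2")),
        ("steam", ledger["steam_kg"] / 1000.0 * price("steam_per_mt")),
        ("net_water", net_water_mt * price("water_per_mt")),
        ("electricity", ledger["electricity_kwh"] * price("electricity_per_kwh")),
        ("net_wastewater", -ww_credit_m3 * price("wastewater_per_mt")),
    ]
    product_kg = result.annual_product_kg
    lines = [
        (item, cost, cost / product_kg if product_kg else 0.0) for item, cost in annual
    ]
    total = sum(cost for _, cost in annual)
    return OpexStatement(
        lines=lines,
        total_annual=total,
        total_per_kg=total / product_kg if product_kg else 0.0,
    )


def financial_summary(
    capex: CapexStatement,
    opex: OpexStatement,
    result: FlowsheetResult,
    facility: FacilityScenario,
    costbook: CostBook,
) -> FinancialSummary:
    """COGS, revenue, profit, simple payback and CM COGS offset."""
    product_kg = result.annual_product_kg
    if product_kg <= 0:
        raise ValueError("financial summary requires a positive annual product")
    contained_kg = result.contained_la_rate * result.operating_hours

    capital_charge = capex.total / costbook.depreciation_years
    cogs_per_kg = (capital_charge + opex.total_annual) / product_kg
    revenue = contained_kg * costbook.la_price
    annual_cogs = cogs_per_kg * contained_kg
    profit = revenue - annual_cogs
    viable = profit > 0
    payback = capex.total / profit if viable else float("inf")
    return FinancialSummary(
        annual_revenue=revenue,
        annual_cogs=annual_cogs,
        annual_profit=profit,
        cogs_per_kg_88pct=cogs_per_kg,
        simple_payback_years=payback,
        cm_cogs_offset_per_kg=profit / facility.cm_annual_production,
        viable=viable,
    )
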