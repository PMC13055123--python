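"""End-to-end orchestration: flowsheet -> water -> costs -> LCA -> allocation."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from . import econ, flowsheet, lca
from .scenario import ImpactFactorSet, ScenarioBundle, baseline_bundle

__all__ = ["PipelineResult", "run_bundle", "reference_calibrated_factors"]


@dataclass
class PipelineResult:
    bundle: ScenarioBundle
    flowsheet: flowsheet.FlowsheetResult
    water: flowsheet.WaterBalance
    capex: econ.CapexStatement
    opex: econ.OpexStatement
    financial: econ.FinancialSummary
    inventory: lca.InventoryPerKg
    la_impact: lca.ImpactResult
    allocations: dict[str, lca.AllocationResult]
    fermentation: lca.FermentationComparison
    factors: ImpactFactorSet


@lru_cache(maxsize=1)
def _reference_inventory_cache() -> tuple[ScenarioBundle, lca.InventoryPerKg]:
    bundle = baseline_bundle()
    result = flowsheet.solve_flowsheet(bundle)
    water = flowsheet.water_balance(result, bundle.facility)
    return bundle, lca.build_inventory(result, water)


def reference_calibrated_factors(seed: ImpactFactorSet | None = None) -> ImpactFactorSet:
    """Factor set calibrated against the baseline reference scenario.

    Impact factors are physical properties of the inventory items, so they are
    calibrated once against the baseline process and then held fixed across
    sweeps and alternative scenarios.
    """
    _, inventory = _reference_inventory_cache()
    if seed is None:
        seed = ImpactFactorSet()
    return lca.calibrate_factors(inventory, seed)


def run_bundle(
    bundle: ScenarioBundle, factors: ImpactFactorSet | None = None
) -> PipelineResult:
    """Run every stage of the model for one scenario.

    ``factors`` defaults to the bundle's factor set, calibrated against the
    baseline reference scenario unless it already carries a calibration.
    """
    if factors is None:
        factors = bundle.impact_factors
        if factors.calibration is None:
            factors = reference_calibrated_factors(factors)

    result = flowsheet.solve_flowsheet(bundle)
    water = flowsheet.water_balance(result, bundle.facility)
    capex = econ.capital_costs(result, bundle.costs)
    opex = econ.operating_costs(result, water, bundle.costs)
    financial = econ.financial_summary(capex, opex, result, bundle.facility, bundle.costs)
    inventory = lca.build_inventory(result, water)
    la_impact = lca.impacts(inventory, factors)
    allocations = {
        method: lca.allocate(
            method,
            bundle.facility,
            la_impact,
            result.la_per_kg_cm,
            bundle.costs,
            factors,
            bundle.process.product_mass_fraction,
        )
        for method in lca.ALLOCATION_METHODS
    }
    fermentation = lca.compare_to_fermentation(la_impact, factors)
    return PipelineResult(
        bundle=bundle,
        flowsheet=result,
        water=water,
        capex=capex,
        opex=opex,
        financial=financial,
        inventory=inventory,
        la_impact=la_impact,
        allocations=allocations,
        fermentation=fermentation,
        factors=factors,
    )
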