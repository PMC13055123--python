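"""Sensitivity sweeps and joint Monte Carlo uncertainty analysis.

Two one-at-a-time axes mirror the scenario analysis of the reference study:

* ``lactic_acid_conc`` (1-5 g/L): the spent-media volumetric rate -- and with
  it every volumetric equipment duty (MF/AC/IEX throughput, NF permeate
  removal, regeneration schedules, pump electricity) -- is held at the
  baseline level, because the installed equipment does not change when the
  feed titer does.  The NF train therefore removes its baseline permeate
  volume, so the retentate concentration (and the evaporation duty) moves
  with the feed titer while the product mass scales with it.
* ``media_intensity`` (+/-25%): the whole plant scales volumetrically; per-kg
  quantities are unchanged and only the power-law capital charge moves COGS.

The economic-allocation burden on CM is reported per point, as in the
reference analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .pipeline import PipelineResult, run_bundle, reference_calibrated_factors
from .scenario import ImpactFactorSet, ScenarioBundle, clone_bundle
from .synthetic import ScenarioSampler, sample_scenarios

__all__ = ["SweepPoint", "SweepResult", "sweep", "MonteCarloSummary", "monte_carlo"]

AXES = ("lactic_acid_conc", "media_intensity")


@dataclass
class SweepPoint:
    value: float
    cogs_per_kg: float
    gwp_per_kg_la: float
    ced_per_kg_la: float
    cm_gwp_econ: float
    cm_ced_econ: float
    pct_change_cogs: float
    pct_change_gwp: float
    pct_change_ced: float
    result: PipelineResult = field(repr=False)


@dataclass
class SweepResult:
    axis: str
    baseline: PipelineResult = field(repr=False)
    points: list[SweepPoint] = field(default_factory=list)


def _apply_axis(bundle: ScenarioBundle, axis: str, value: float, baseline: PipelineResult) -> None:
    if axis == "lactic_acid_conc":
        bundle.spent_media.lactic_acid_conc = value
        # installed NF hardware keeps its baseline dewatering duty
        bundle.process.nf_retentate_volume_lph = (
            baseline.flowsheet.streams["J"].volumetric_rate
        )
    elif axis == "media_intensity":
        # value is L media per kg CM; rescale via media_per_batch
        bundle.facility.media_per_batch = value * bundle.facility.batch_mass
    else:
        raise ValueError(f"unknown sweep axis {axis!r}; expected one of {AXES}")


def sweep(
    axis: str,
    values: Sequence[float],
    bundle: ScenarioBundle,
    factors: ImpactFactorSet | None = None,
) -> SweepResult:
    """Re-run the full pipeline along one parameter axis.

    Percent changes are computed against the baseline run's unrounded values.
    The baseline parameter value reproduces the baseline run bit-for-bit.
    """
    if not len(values):
        raise ValueError("sweep requires at least one value")
    if axis not in AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; expected one of {AXES}")
    if factors is None:
        factors = reference_calibrated_factors(bundle.impact_factors)
    base = run_bundle(bundle, factors=factors)

    points: list[SweepPoint] = []
    for value in values:
        scenario = clone_bundle(bundle)
        _apply_axis(scenario, axis, value, base)
        res = run_bundle(scenario, factors=factors)
        econ_alloc = res.allocations["economic"]
        points.append(
            SweepPoint(
                value=value,
                cogs_per_kg=res.financial.cogs_per_kg_88pct,
                gwp_per_kg_la=res.la_impact.gwp,
                ced_per_kg_la=res.la_impact.ced,
                cm_gwp_econ=econ_alloc.cm_gwp,
                cm_ced_econ=econ_alloc.cm_ced,
                pct_change_cogs=_pct(res.financial.cogs_per_kg_88pct, base.financial.cogs_per_kg_88pct),
                pct_change_gwp=_pct(res.la_impact.gwp, base.la_impact.gwp),
                pct_change_ced=_pct(res.la_impact.ced, base.la_impact.ced),
                result=res,
            )
        )
    return SweepResult(axis=axis, baseline=base, points=points)


def _pct(value: float, base: float) -> float:
    return 100.0 * (value - base) / base if base else 0.0


@dataclass
class MonteCarloSummary:
    n: int
    seed: int
    percentiles: dict[str, dict[str, float]]  # metric -> {p5, p25, p50, p75, p95}
    samples: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def monte_carlo(
    bundle: ScenarioBundle,
    n: int,
    seed: int,
    sampler: ScenarioSampler | None = None,
) -> MonteCarloSummary:
    """Joint parameter uncertainty via the synthetic scenario sampler.

    Reproducible for a fixed seed; impact factors are perturbed per sample but
    COGS/GWP/CED are otherwise computed by the same pipeline as the baseline.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sampler is None:
        sampler = ScenarioSampler(seed=seed)
    else:
        sampler = sampler.with_seed(seed)
    bundles = sample_scenarios(sampler, n, base=bundle)

    metrics: dict[str, list[float]] = {"cogs_per_kg": [], "gwp_per_kg": [], "ced_per_kg": []}
    for sample in bundles:
        res = run_bundle(sample)
        metrics["cogs_per_kg"].append(res.financial.cogs_per_kg_88pct)
        metrics["gwp_per_kg"].append(res.la_impact.gwp)
        metrics["ced_per_kg"].append(res.la_impact.ced)

    qs = (5, 25, 50, 75, 95)
    arrays = {k: np.asarray(v) for k, v in metrics.items()}
    percentiles = {
        metric: {f"p{q}": float(np.percentile(arr, q)) for q in qs}
        for metric, arr in arrays.items()
    }
    return MonteCarloSummary(n=n, seed=seed, percentiles=percentiles, samples=arrays)
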