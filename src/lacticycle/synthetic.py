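"""Randomized but structurally faithful scenario generation.

The sampler draws spent-media compositions within the concentration classes
observed in spent media (lactate 1-5 g/L, residual glucose around the 1.8 g/L
average, cations in a DMEM/F12-plausible equivalents band computed from the
packaged salt table), media intensities within +/-25% of the 46.9 L/kg
baseline, triangular price multipliers, and log-normal impact-factor
multipliers around the calibrated reference set.  Every sampled bundle passes
scenario validation and runs through the full pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any

import numpy as np

from .scenario import ImpactFactorSet, ScenarioBundle, baseline_bundle, clone_bundle

__all__ = [
    "ScenarioSampler",
    "sample_scenarios",
    "dmem_f12_cation_equivalents",
    "default_ranges",
]

_BASELINE_MEDIA_INTENSITY = 144_382.0 / 3080.0  # L media per kg CM


def dmem_f12_cation_equivalents() -> float:
    """Total cation charge equivalents of full-strength DMEM/F12, eq/L.

    Computed from the packaged inorganic-salt table (salt, mg/L, molecular
    weight, cations per formula unit, cation charge).
    """
    total_meq = 0.0
    with resources.files("lacticycle.data").joinpath("dmem_f12_salts.csv").open() as fh:
        for row in csv.DictReader(fh):
            mmol = float(row["mg_per_l"]) / float(row["mw_g_per_mol"])
            total_meq += mmol * float(row["cations_per_formula"]) * float(row["cation_charge"])
    return total_meq / 1000.0


def default_ranges() -> dict[str, Any]:
    """Default sampling ranges (uniform bounds unless noted)."""
    return {
        "lactic_acid_conc": (1.0, 5.0),
        "glucose_conc": (0.9, 2.7),
        "media_intensity": (
            0.75 * _BASELINE_MEDIA_INTENSITY,
            1.25 * _BASELINE_MEDIA_INTENSITY,
        ),
        # DMEM/F12-plausible band around the packaged formulation (~0.158 eq/L)
        "cation_equivalents": (0.14, 0.18),
        "protein_conc": (0.25, 1.0),
        # triangular multiplier (low, mode, high) applied to every unit price
        "price_multiplier": (0.8, 1.0, 1.2),
        # sigma of the log-normal multiplier on each calibrated impact factor
        "impact_factor_sigma": 0.2,
    }


@dataclass(frozen=True)
class ScenarioSampler:
    """Deterministic scenario sampler; a fixed seed fixes the sample sequence."""

    seed: int = 0
    ranges: dict[str, Any] = field(default_factory=default_ranges)

    def __post_init__(self) -> None:
        for key, rng in self.ranges.items():
            if isinstance(rng, tuple) and len(rng) >= 2 and rng[0] > rng[-1]:
                raise ValueError(f"invalid range for {key!r}: low {rng[0]} > high {rng[-1]}")

    def with_seed(self, seed: int) -> "ScenarioSampler":
        return replace(self, seed=seed)


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    low, high = bounds
    return low if low == high else float(rng.uniform(low, high))


def _triangular(rng: np.random.Generator, spec: tuple[float, float, float]) -> float:
    low, mode, high = spec
    return mode if low == high else float(rng.triangular(low, mode, high))


def _perturb_factors(
    rng: np.random.Generator, factors: ImpactFactorSet, sigma: float
) -> ImpactFactorSet:
    out = factors.model_copy(deep=True)
    for table in (out.gwp_factors, out.ced_factors):
        for key in table:
            table[key] *= float(rng.lognormal(mean=0.0, sigma=sigma))
    return out


def sample_scenarios(
    sampler: ScenarioSampler,
    n: int,
    base: ScenarioBundle | None = None,
) -> list[ScenarioBundle]:
    """Draw ``n`` validated scenario bundles.

    Sampled fields are recorded as ``"sampled"`` in the bundle provenance.
    Impact-factor perturbations are applied around the *calibrated* reference
    factor set so that perturbed bundles are used as-is downstream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from .pipeline import reference_calibrated_factors  # deferred: avoids cycle

    rng = np.random.default_rng(sampler.seed)
    ranges = sampler.ranges
    sigma = float(ranges.get("impact_factor_sigma", 0.0))
    if base is None:
        base = baseline_bundle()
    calibrated = reference_calibrated_factors(base.impact_factors) if sigma > 0 else None

    bundles: list[ScenarioBundle] = []
    for _ in range(n):
        bundle = clone_bundle(base)
        media = bundle.spent_media
        media.lactic_acid_conc = _uniform(rng, ranges["lactic_acid_conc"])
        media.glucose_conc = _uniform(rng, ranges["glucose_conc"])
        media.cation_equivalents = _uniform(rng, ranges["cation_equivalents"])
        media.protein_conc = _uniform(rng, ranges["protein_conc"])
        intensity = _uniform(rng, ranges["media_intensity"])
        bundle.facility.media_per_batch = intensity * bundle.facility.batch_mass

        if "price_multiplier" in ranges:
            mult = {
                key: _triangular(rng, ranges["price_multiplier"])
                for key in bundle.costs.unit_prices
            }
            bundle.costs.unit_prices = {
                key: value * mult[key] for key, value in bundle.costs.unit_prices.items()
            }
        if sigma > 0 and calibrated is not None:
            bundle.impact_factors = _perturb_factors(rng, calibrated, sigma)

        sampled = {
            "spent_media": ["lactic_acid_conc", "glucose_conc", "cation_equivalents", "protein_conc"],
            "facility": ["media_per_batch"],
            "costs": ["unit_prices"],
        }
        if sigma > 0:
            sampled["impact_factors"] = ["gwp_factors", "ced_factors"]
        for section, fields_ in sampled.items():
            bundle.provenance.setdefault(section, {})
            for name in fields_:
                bundle.provenance[section][name] = "sampled"
        bundles.append(bundle)
    return bundles
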