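"""Monte Carlo simulation of how many pupae the site's host biomass supports.

Each iteration draws one realization of the site:

    leaf area present [m²] = area sampled [m²]
                             × violets per m²
                             × leaves per plant
                             × leaf area per leaf [mm² → m²]
    pupae supported        = leaf area present ÷ leaf area consumed [m²]

The violet density term is the mean of ``n_density_draws`` draws from the
fitted zero/exponential mixture (averaging sidesteps iterations with zero
violets while keeping density stochastic); the other three terms are
single draws from their fitted families. Leaf areas enter in mm² and
larval consumption in m² (0.027 m² ≈ 270 cm² Weibull scale); the mm² → m²
conversion happens here and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .distfit import FitResult, sample_from_fit
from .errors import DomainError, EmptyInputError
from .zimix import ZIExpFit, ziexp_ppf

logger = logging.getLogger(__name__)

MM2_PER_M2 = 1e6
CM2_PER_M2 = 1e4

#: quantile levels (percent) reported in every summary
SUMMARY_QUANTILES = (2.5, 25.0, 50.0, 75.0, 95.0, 97.5)

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the Monte Carlo run.

    ``reference_area_m2`` is the "area sampled" the per-m² density is
    scaled up by — the total study area for the headline run.
    """

    reference_area_m2: float
    n_iterations: int = 10_000
    n_density_draws: int = 1_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.reference_area_m2 <= 0.0:
            raise DomainError("reference_area_m2 must be positive")
        if self.n_iterations < 1:
            raise DomainError("n_iterations must be >= 1")
        if self.n_density_draws < 1:
            raise DomainError("n_density_draws must be >= 1")


@dataclass(frozen=True)
class PupaeSample:
    """All per-iteration pupae values from one simulation run."""

    values: np.ndarray
    mean_density: np.ndarray = field(repr=False, default=None)
    n_consumption_redraws: int = 0

    @property
    def summary(self) -> dict[str, float]:
        return summarize(self)


def leaf_area_present(
    area_m2: float, density: float, leaves: float, leaf_area_mm2: float
) -> float:
    """Total host leaf area on ``area_m2`` ground, in m²."""
    if area_m2 <= 0.0:
        raise DomainError("area_m2 must be positive")
    if density < 0.0 or leaves < 0.0 or leaf_area_mm2 < 0.0:
        raise DomainError("density, leaves and leaf area must be non-negative")
    return area_m2 * density * leaves * leaf_area_mm2 / MM2_PER_M2


def pupae_supported(leaf_area_present_m2: float, consumption_m2: float) -> float:
    """Number of larvae the leaf area feeds to pupation (continuous)."""
    if consumption_m2 <= 0.0:
        raise DomainError("consumption must be positive")
    if leaf_area_present_m2 < 0.0:
        raise DomainError("leaf area present must be non-negative")
    return leaf_area_present_m2 / consumption_m2


def _draw_mean_density(
    density: Union[ZIExpFit, float],
    n_iterations: int,
    n_density_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if isinstance(density, ZIExpFit):
        u = rng.random((n_iterations, n_density_draws))
        draws = ziexp_ppf(u, density.zero_weight, density.rate)
        return draws.mean(axis=1)
    dens = float(density)
    if dens < 0.0:
        raise DomainError("fixed density must be non-negative")
    return np.full(n_iterations, dens)


def _draw_consumption(
    fit: FitResult, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    draws = sample_from_fit(fit, n, rng)
    redraws = 0
    for _ in range(_MAX_REDRAWS):
        bad = draws <= 0.0
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        redraws += n_bad
        draws[bad] = sample_from_fit(fit, n_bad, rng)
    else:
        raise DomainError("consumption fit keeps producing non-positive draws")
    if redraws:
        logger.info("redrew %d non-positive consumption values", redraws)
    return draws, redraws


def run_simulation(
    config: SimConfig,
    density: Union[ZIExpFit, float],
    leaves_fit: FitResult,
    leafarea_fit: FitResult,
    consumption_fit: FitResult,
    rng: np.random.Generator | None = None,
) -> PupaeSample:
    """Run the full Monte Carlo and return all per-iteration pupae values.

    ``density`` is either a fitted zero/exponential mixture (headline run:
    per-iteration mean of ``n_density_draws`` draws) or a fixed density in
    plants per m² (the density-sweep mode, which bypasses the draw stage).
    ``leafarea_fit`` must be parameterized in mm² and ``consumption_fit``
    in m². Non-positive consumption draws (possible only for the normal
    family) are rejected and redrawn, with the count recorded on the
    returned sample. Deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_iterations
    mean_density = _draw_mean_density(density, n, config.n_density_draws, rng)
    leaves = sample_from_fit(leaves_fit, n, rng)
    leaf_area_mm2 = sample_from_fit(leafarea_fit, n, rng)
    consumption_m2, redraws = _draw_consumption(consumption_fit, n, rng)
    present = (
        config.reference_area_m2 * mean_density * leaves * leaf_area_mm2 / MM2_PER_M2
    )
    pupae = present / consumption_m2
    return PupaeSample(
        values=pupae, mean_density=mean_density, n_consumption_redraws=redraws
    )


def _values(sample) -> np.ndarray:
    arr = sample.values if isinstance(sample, PupaeSample) else np.asarray(sample, float)
    if arr.size == 0:
        raise EmptyInputError("empty sample")
    return arr


def summarize(sample) -> dict[str, float]:
    """Mean, median and the standard quantiles of a simulated sample.

    Quantiles use linear interpolation (type 7), matching R's default.
    """
    arr = _values(sample)
    out = {"n": int(arr.size), "mean": float(arr.mean()), "median": float(np.median(arr))}
    for q in SUMMARY_QUANTILES:
        out[f"q{q:g}"] = float(np.quantile(arr, q / 100.0))
    return out


def percentile_rank(sample, value: float) -> float:
    """Percent of simulated values strictly below ``value`` (0–100)."""
    arr = _values(sample)
    return 100.0 * float(np.mean(arr < value))
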