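"""Reported constants and fitted parameters for the 2013 Chews Ridge survey.

The raw field tables were never deposited, but the study-site constants
and the maximum-likelihood parameters of the selected families were
reported, which is enough to rerun every simulation stage. These helpers
build those objects so the headline analysis is a few lines.
"""

from __future__ import annotations

from .distfit import FitResult
from .field_data import SiteConfig
from .zimix import ZIExpFit, from_mean

TOTAL_AREA_M2 = 243_206.5
SAMPLED_TRANSECT_AREA_M2 = 24_883.0
TOTAL_VIOLETS = 1258
MEAN_TRANSECT_DENSITY = 0.037  # plants per m², per-transect average

ADULT_ESTIMATE = 227.0
ADULT_CI = (146.0, 392.0)

MEAN_LEAVES_PER_PLANT = 10.3
MEAN_LEAF_AREA_CM2 = 1.99
MEAN_CONSUMPTION_CM2 = 253.9
FEMALE_CONSUMPTION_CM2 = 290.6
MALE_CONSUMPTION_CM2 = 196.7

#: segments with >= 10 plants and the area they cover
SUPPORTING_SEGMENTS = 34
SUPPORTING_SAMPLED_AREA_M2 = 22_260.0

DEFAULT_ZERO_WEIGHT = 0.55


def site_config() -> SiteConfig:
    return SiteConfig(
        total_area_m2=TOTAL_AREA_M2,
        adult_estimate=ADULT_ESTIMATE,
        adult_ci_low=ADULT_CI[0],
        adult_ci_high=ADULT_CI[1],
    )


def leaves_fit() -> FitResult:
    """Leaves per plant: log-normal(meanlog 2.05, sdlog 0.792)."""
    return FitResult(
        family="lognormal",
        params={"meanlog": 2.05, "sdlog": 0.792},
        loglik=float("nan"),
        aic=float("nan"),
        n=241,
    )


def leafarea_fit() -> FitResult:
    """Leaf area per leaf in mm²: gamma(shape 3.00, rate 0.0151)."""
    return FitResult(
        family="gamma",
        params={"shape": 3.00, "rate": 0.0151},
        loglik=float("nan"),
        aic=float("nan"),
        n=349,
    )


def consumption_fit() -> FitResult:
    """Leaf area consumed to pupation in m²: Weibull(shape 6.53, scale 0.027)."""
    return FitResult(
        family="weibull",
        params={"shape": 6.53, "scale": 0.027},
        loglik=float("nan"),
        aic=float("nan"),
        n=10,
    )


def density_mixture(zero_weight: float = DEFAULT_ZERO_WEIGHT) -> ZIExpFit:
    """Zero/exponential density model with the reported 0.037/m² mean.

    The fitted mixture parameters were not reported, only the average
    transect density; because the simulation averages 1,000 draws per
    iteration, any zero weight with the right mean yields the same
    distribution of per-iteration means to first order.
    """
    return from_mean(zero_weight, MEAN_TRANSECT_DENSITY)
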