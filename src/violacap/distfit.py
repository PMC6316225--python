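"""Maximum-likelihood fitting of candidate families and AIC model selection.

Five continuous families compete for each positive-valued dataset (leaves
per plant, leaf area per leaf, leaf area consumed): normal, log-normal,
left-truncated normal, gamma, and Weibull; the exponential is also
available (it is the reduced model in the zero-inflation test). Fitting is
pure MLE — the normal variance uses the n denominator — so that AIC values
(2k − 2·loglik) are comparable across families.

Parameter conventions follow the usual ecology-stats naming: lognormal
(meanlog, sdlog), gamma (shape, rate), Weibull (shape, scale), truncated
normal (mu, sigma of the parent normal, lower bound fixed at 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .errors import DomainError, FitFailureError

FAMILIES = ("normal", "lognormal", "truncated_normal", "gamma", "weibull")
ALL_FAMILIES = FAMILIES + ("exponential",)

_POSITIVE_SUPPORT = {"lognormal", "gamma", "weibull"}

_N_PARAMS = {
    "normal": 2,
    "lognormal": 2,
    "truncated_normal": 2,
    "gamma": 2,
    "weibull": 2,
    "exponential": 1,
    "point": 1,
}

_AIC_TIE_TOL = 1e-9
_OPT_TOL = 1e-8


@dataclass(frozen=True)
class FitResult:
    """A fitted parametric family with its log-likelihood and AIC."""

    family: str
    params: dict[str, float]
    loglik: float
    aic: float
    n: int

    @classmethod
    def point(cls, value: float) -> "FitResult":
        """A degenerate point mass, usable as a simulation input only."""
        return cls(family="point", params={"value": float(value)},
                   loglik=float("nan"), aic=float("nan"), n=1)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
        }


def _as_array(data) -> np.ndarray:
    arr = np.asarray(data, dtype=float).ravel()
    if arr.size < 2:
        raise DomainError(f"need at least 2 observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise DomainError("data contain non-finite values")
    if arr.max() == arr.min():
        raise FitFailureError("data are constant; no family has a finite MLE")
    return arr


def frozen_distribution(fit: FitResult):
    """The scipy frozen distribution corresponding to a FitResult."""
    p = fit.params
    if fit.family == "normal":
        return stats.norm(loc=p["mean"], scale=p["sd"])
    if fit.family == "lognormal":
        return stats.lognorm(s=p["sdlog"], scale=np.exp(p["meanlog"]))
    if fit.family == "truncated_normal":
        a = (0.0 - p["mu"]) / p["sigma"]
        return stats.truncnorm(a=a, b=np.inf, loc=p["mu"], scale=p["sigma"])
    if fit.family == "gamma":
        return stats.gamma(a=p["shape"], scale=1.0 / p["rate"])
    if fit.family == "weibull":
        return stats.weibull_min(c=p["shape"], scale=p["scale"])
    if fit.family == "exponential":
        return stats.expon(scale=1.0 / p["rate"])
    raise DomainError(f"no frozen distribution for family {fit.family!r}")


def distribution_mean(fit: FitResult) -> float:
    """Mean of the fitted distribution (point masses return their value)."""
    if fit.family == "point":
        return fit.params["value"]
    return float(frozen_distribution(fit).mean())


def truncated_normal_loglik(mu: float, sigma: float, data) -> float:
    """Log-likelihood of a normal(mu, sigma) left-truncated at 0.

    Density f(x) = phi((x-mu)/sigma) / (sigma * Phi(mu/sigma)) on x >= 0,
    where Phi(mu/sigma) = 1 - Phi(-mu/sigma) is the truncation mass.
    ``log_ndtr`` keeps the normalizer stable for mu far below 0.
    """
    if sigma <= 0.0:
        raise DomainError(f"sigma must be positive, got {sigma}")
    arr = np.asarray(data, dtype=float).ravel()
    if np.any(arr < 0.0):
        raise DomainError("truncated-normal data must be non-negative")
    z = (arr - mu) / sigma
    return float(
        np.sum(stats.norm.logpdf(z) - np.log(sigma) - special.log_ndtr(mu / sigma))
    )


def _fit_truncated_normal(arr: np.ndarray) -> tuple[dict[str, float], float]:
    # method-of-moments start: parent normal moments approximate the
    # truncated ones well away from the boundary
    start = np.array([arr.mean(), max(arr.std(), 1e-6)])

    def neg_loglik(theta):
        mu, sigma = theta
        if sigma <= 0.0:
            return np.inf
        return -truncated_normal_loglik(mu, sigma, arr)

    res = optimize.minimize(
        neg_loglik,
        start,
        method="L-BFGS-B",
        bounds=[(None, None), (1e-9, None)],
        options={"ftol": _OPT_TOL, "gtol": 1e-10},
    )
    if not res.success:
        raise FitFailureError(f"truncated-normal fit did not converge: {res.message}")
    mu, sigma = res.x
    return {"mu": float(mu), "sigma": float(sigma)}, -float(res.fun)


def fit_family(data, family: str) -> FitResult:
    """Maximum-likelihood fit of one family.

    Closed forms are used where they exist (normal, lognormal,
    exponential); gamma and Weibull use scipy's numerical MLE with the
    location pinned at 0; the truncated normal uses this module's own
    likelihood.
    """
    if family not in ALL_FAMILIES:
        raise DomainError(f"unknown family {family!r}; expected one of {ALL_FAMILIES}")
    arr = _as_array(data)
    if family in _POSITIVE_SUPPORT and np.any(arr <= 0.0):
        raise DomainError(f"{family} requires strictly positive data")
    if family == "truncated_normal" and np.any(arr < 0.0):
        raise DomainError("truncated_normal requires non-negative data")
    if family == "exponential" and np.any(arr < 0.0):
        raise DomainError("exponential requires non-negative data")

    n = arr.size
    if family == "normal":
        mean = float(arr.mean())
        sd = float(np.sqrt(np.mean((arr - mean) ** 2)))
        params = {"mean": mean, "sd": sd}
        loglik = float(np.sum(stats.norm.logpdf(arr, loc=mean, scale=sd)))
    elif family == "lognormal":
        logs = np.log(arr)
        meanlog = float(logs.mean())
        sdlog = float(np.sqrt(np.mean((logs - meanlog) ** 2)))
        params = {"meanlog": meanlog, "sdlog": sdlog}
        loglik = float(
            np.sum(stats.lognorm.logpdf(arr, s=sdlog, scale=np.exp(meanlog)))
        )
    elif family == "exponential":
        mean = float(arr.mean())
        if mean <= 0.0:
            raise DomainError("exponential requires a positive mean")
        rate = 1.0 / mean
        params = {"rate": rate}
        loglik = float(n * np.log(rate) - rate * arr.sum())
    elif family == "gamma":
        try:
            shape, _, scale = stats.gamma.fit(arr, floc=0.0)
        except Exception as exc:  # scipy raises bare exceptions on bad data
            raise FitFailureError(f"gamma fit failed: {exc}") from exc
        params = {"shape": float(shape), "rate": float(1.0 / scale)}
        loglik = float(np.sum(stats.gamma.logpdf(arr, a=shape, scale=scale)))
    elif family == "weibull":
        try:
            shape, _, scale = stats.weibull_min.fit(arr, floc=0.0)
        except Exception as exc:
            raise FitFailureError(f"weibull fit failed: {exc}") from exc
        params = {"shape": float(shape), "scale": float(scale)}
        loglik = float(np.sum(stats.weibull_min.logpdf(arr, c=shape, scale=scale)))
    else:  # truncated_normal
        params, loglik = _fit_truncated_normal(arr)

    k = _N_PARAMS[family]
    return FitResult(family=family, params=params, loglik=loglik,
                     aic=2 * k - 2 * loglik, n=n)


def compare_families(data, families=FAMILIES) -> list[FitResult]:
    """Fit every family that converges; the AIC competition table.

    Raises FitFailureError only if *all* families fail.
    """
    results: list[FitResult] = []
    failures: list[str] = []
    for family in families:
        try:
            results.append(fit_family(data, family))
        except (FitFailureError, DomainError) as exc:
            failures.append(f"{family}: {exc}")
    if not results:
        raise FitFailureError("all candidate fits failed: " + "; ".join(failures))
    return results


def select_best_model(data, families=FAMILIES) -> FitResult:
    """The fitted family with the lowest AIC.

    AIC ties within 1e-9 break by position in ``families`` so output is
    deterministic.
    """
    results = compare_families(data, families)
    best = results[0]
    for candidate in results[1:]:
        if candidate.aic < best.aic - _AIC_TIE_TOL:
            best = candidate
    return best


def sample_from_fit(fit: FitResult, n: int, rng: np.random.Generator) -> np.ndarray:
    """n inverse-CDF draws from a fitted family.

    Inverse-transform sampling makes draws a monotone function of the
    underlying uniforms, so re-running with the same generator state and a
    stochastically larger fit yields element-wise larger samples.
    """
    if n <= 0:
        raise DomainError(f"n must be positive, got {n}")
    if fit.family == "point":
        rng.random(n)  # consume the stream like any other family
        return np.full(n, fit.params["value"])
    return frozen_distribution(fit).ppf(rng.random(n))
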