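"""Shared test utilities: independent log-likelihoods and Fisher SEs.

These are deliberately written against scipy's logpdfs directly (not the
package's fit paths) so parameter-recovery checks compare the
implementation with an independent oracle.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def loglik_fn(family: str):
    """Sum log-likelihood as a function of a raw parameter vector."""

    def normal(theta, x):
        return np.sum(stats.norm.logpdf(x, loc=theta[0], scale=theta[1]))

    def lognormal(theta, x):
        return np.sum(stats.lognorm.logpdf(x, s=theta[1], scale=np.exp(theta[0])))

    def truncated_normal(theta, x):
        mu, sigma = theta
        a = (0.0 - mu) / sigma
        return np.sum(stats.truncnorm.logpdf(x, a=a, b=np.inf, loc=mu, scale=sigma))

    def gamma(theta, x):
        return np.sum(stats.gamma.logpdf(x, a=theta[0], scale=1.0 / theta[1]))

    def weibull(theta, x):
        return np.sum(stats.weibull_min.logpdf(x, c=theta[0], scale=theta[1]))

    def exponential(theta, x):
        return np.sum(stats.expon.logpdf(x, scale=1.0 / theta[0]))

    return {
        "normal": normal,
        "lognormal": lognormal,
        "truncated_normal": truncated_normal,
        "gamma": gamma,
        "weibull": weibull,
        "exponential": exponential,
    }[family]


PARAM_ORDER = {
    "normal": ("mean", "sd"),
    "lognormal": ("meanlog", "sdlog"),
    "truncated_normal": ("mu", "sigma"),
    "gamma": ("shape", "rate"),
    "weibull": ("shape", "scale"),
    "exponential": ("rate",),
}


def params_vector(fit) -> np.ndarray:
    return np.array([fit.params[name] for name in PARAM_ORDER[fit.family]])


def fisher_se(family: str, theta: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Standard errors from the observed information (finite-diff Hessian)."""
    fn = loglik_fn(family)
    k = theta.size
    h = np.maximum(np.abs(theta) * 1e-4, 1e-8)
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            hess[i, j] = (
                fn(theta + ei + ej, data)
                - fn(theta + ei - ej, data)
                - fn(theta - ei + ej, data)
                + fn(theta - ei - ej, data)
            ) / (4.0 * h[i] * h[j])
    info = -hess
    cov = np.linalg.inv(info)
    return np.sqrt(np.diag(cov))


def true_theta(family: str) -> np.ndarray:
    """Representative generating parameters per family, on field-data scales."""
    return {
        "normal": np.array([10.0, 3.0]),
        "lognormal": np.array([2.05, 0.792]),
        "truncated_normal": np.array([5.0, 4.0]),
        "gamma": np.array([3.00, 0.0151]),
        "weibull": np.array([6.53, 0.027]),
        "exponential": np.array([12.16]),
    }[family]


def sample_true(family: str, n: int, rng: np.random.Generator) -> np.ndarray:
    theta = true_theta(family)
    if family == "normal":
        return rng.normal(theta[0], theta[1], n)
    if family == "lognormal":
        return rng.lognormal(theta[0], theta[1], n)
    if family == "truncated_normal":
        a = (0.0 - theta[0]) / theta[1]
        return stats.truncnorm.rvs(a=a, b=np.inf, loc=theta[0], scale=theta[1],
                                   size=n, random_state=rng)
    if family == "gamma":
        return rng.gamma(theta[0], 1.0 / theta[1], n)
    if family == "weibull":
        return rng.weibull(theta[0], n) * theta[1]
    if family == "exponential":
        return rng.exponential(1.0 / theta[0], n)
    raise ValueError(family)
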