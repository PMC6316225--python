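import numpy as np
import pytest
from scipy import integrate, stats

from violacap import (
    FitResult,
    fit_family,
    sample_from_fit,
    select_best_model,
    truncated_normal_loglik,
)
from violacap.distfit import FAMILIES, compare_families, frozen_distribution
from violacap.errors import DomainError

from helpers import fisher_se, loglik_fn, params_vector, sample_true, true_theta


class TestFitFamily:
    def test_normal_two_points(self):
        fit = fit_family([1.0, 3.0], "normal")
        assert fit.params["mean"] == pytest.approx(2.0)
        assert fit.params["sd"] == pytest.approx(1.0)  # MLE n-denominator

    def test_lognormal_recovery(self, rng):
        data = rng.lognormal(2.05, 0.792, 10_000)
        fit = fit_family(data, "lognormal")
        assert fit.params["meanlog"] == pytest.approx(2.05, abs=0.03)
        assert fit.params["sdlog"] == pytest.approx(0.792, abs=0.02)

    def test_weibull_recovery(self, rng):
        data = rng.weibull(6.53, 10_000) * 0.027
        fit = fit_family(data, "weibull")
        assert fit.params["shape"] == pytest.approx(6.53, rel=0.05)
        assert fit.params["scale"] == pytest.approx(0.027, rel=0.01)

    def test_positive_support_rejects_nonpositive(self):
        for family in ("lognormal", "gamma", "weibull"):
            with pytest.raises(DomainError):
                fit_family([1.0, 0.0, 2.0], family)

    def test_too_few_points(self):
        with pytest.raises(DomainError):
            fit_family([1.0], "normal")

    @pytest.mark.parametrize("family", FAMILIES + ("exponential",))
    def test_aic_identity(self, family, rng):
        """AIC = 2k - 2 loglik exactly, k = 1 for exponential else 2."""
        data = sample_true(family, 500, rng)
        fit = fit_family(data, family)
        k = 1 if family == "exponential" else 2
        assert fit.aic == 2 * k - 2 * fit.loglik

    @pytest.mark.parametrize("family", FAMILIES + ("exponential",))
    def test_parameter_recovery_within_3_se(self, family):
        """n = 10,000 fits land within 3 Fisher SEs of the truth."""
        rng = np.random.default_rng(sum(map(ord, family)))
        data = sample_true(family, 10_000, rng)
        fit = fit_family(data, family)
        theta_hat = params_vector(fit)
        se = fisher_se(family, theta_hat, data)
        np.testing.assert_array_less(np.abs(theta_hat - true_theta(family)), 3 * se)

    @pytest.mark.parametrize("family", FAMILIES + ("exponential",))
    def test_local_optimality(self, family, rng):
        """Perturbing the MLE on a small grid never raises the loglik."""
        data = sample_true(family, 2_000, rng)
        fit = fit_family(data, family)
        theta = params_vector(fit)
        fn = loglik_fn(family)
        at_mle = fn(theta, data)
        for i in range(theta.size):
            for eps in (-0.02, 0.02):
                perturbed = theta.copy()
                perturbed[i] *= 1 + eps
                assert fn(perturbed, data) <= at_mle + 1e-6


class TestTruncatedNormal:
    def test_matches_untruncated_far_from_bound(self, rng):
        data = rng.normal(100.0, 1.0, 50)
        expected = float(np.sum(stats.norm.logpdf(data, 100.0, 1.0)))
        assert truncated_normal_loglik(100.0, 1.0, data) == pytest.approx(
            expected, abs=1e-9
        )

    def test_single_datum_at_mode(self):
        mu, sigma = 3.0, 2.0
        expected = (
            stats.norm.logpdf(0.0) - np.log(sigma)
            - np.log(1 - stats.norm.cdf(-mu / sigma))
        )
        assert truncated_normal_loglik(mu, sigma, [mu]) == pytest.approx(expected)

    @pytest.mark.parametrize("mu,sigma", [(5.0, 4.0), (0.0, 1.0), (-2.0, 3.0)])
    def test_density_integrates_to_one(self, mu, sigma):
        """The left-truncated normal density has unit mass on [0, inf)."""
        pdf = lambda x: np.exp(truncated_normal_loglik(mu, sigma, [x]))
        total, _ = integrate.quad(pdf, 0.0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            truncated_normal_loglik(1.0, -1.0, [1.0])
        with pytest.raises(DomainError):
            truncated_normal_loglik(1.0, 1.0, [-0.5])


class TestModelSelection:
    def test_gamma_recovered_across_seeds(self):
        """Gamma data at n = 5,000 wins the AIC competition almost always."""
        hits = 0
        for seed in range(20):
            data = np.random.default_rng(seed).gamma(3.00, 1 / 0.0151, 5_000)
            if select_best_model(data).family == "gamma":
                hits += 1
        assert hits >= 18

    def test_lognormal_selected_for_leaf_count_regime(self):
        data = np.random.default_rng(42).lognormal(2.05, 0.792, 5_000)
        assert select_best_model(data).family == "lognormal"

    def test_single_family_competition(self, rng):
        data = rng.normal(10, 2, 100)
        fit = select_best_model(data, families=("normal",))
        assert fit.family == "normal"

    def test_table_has_all_converged_families(self, rng):
        data = rng.gamma(3.0, 100.0, 500)
        table = compare_families(data)
        assert {r.family for r in table} == set(FAMILIES)
        best = select_best_model(data)
        assert best.aic == min(r.aic for r in table)


class TestSampling:
    def test_gamma_sample_mean_closed_form(self):
        rng = np.random.default_rng(9)
        fit = FitResult("gamma", {"shape": 3.00, "rate": 0.0151},
                        float("nan"), float("nan"), 1)
        draws = sample_from_fit(fit, 1_000_000, rng)
        assert draws.mean() == pytest.approx(3.00 / 0.0151, rel=0.005)

    def test_determinism(self):
        fit = FitResult("weibull", {"shape": 6.53, "scale": 0.027},
                        float("nan"), float("nan"), 1)
        a = sample_from_fit(fit, 1_000, np.random.default_rng(3))
        b = sample_from_fit(fit, 1_000, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_n_rejected(self, rng):
        fit = FitResult.point(5.0)
        with pytest.raises(DomainError):
            sample_from_fit(fit, 0, rng)

    def test_point_mass_sampling(self, rng):
        draws = sample_from_fit(FitResult.point(2.5), 10, rng)
        np.testing.assert_array_equal(draws, np.full(10, 2.5))

    def test_fitted_distribution_roundtrip(self, rng):
        """sample_from_fit draws follow the fitted frozen distribution."""
        fit = fit_family(rng.gamma(3.0, 50.0, 2_000), "gamma")
        draws = sample_from_fit(fit, 20_000, rng)
        ks = stats.kstest(draws, frozen_distribution(fit).cdf)
        assert ks.pvalue > 0.01
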