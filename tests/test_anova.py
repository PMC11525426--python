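"""Tests for the JZS one-way ANOVA Bayes factor: design construction, the
g-conditional closed form against a brute-force integration oracle, the
g-quadrature against Monte-Carlo integration, and the prior-predictive
generators."""

import math

import numpy as np
import pytest
from scipy import integrate

from bfcheck import (
    AnovaData,
    AnovaGenConfig,
    JZSPrior,
    conditional_bf10,
    effect_design,
    jzs_bf10,
    jzs_bf10_batch,
    log_jzs_bf10,
    log_jzs_bf10_batch,
    mc_jzs_bf10,
    simulate_anova_h0,
    simulate_anova_h1,
)
from bfcheck.anova import _contrast_basis
from bfcheck.exceptions import DegenerateDataError, ParameterError


class TestEffectDesign:
    def test_balanced_three_groups(self):
        group = np.repeat(["a", "b", "c"], 50)
        X = effect_design(group)
        assert X.shape == (150, 2)
        # columns orthogonal to the intercept and to each other, with the
        # group-size scaling that puts the g prior on group-mean contrasts
        assert np.allclose(X.sum(axis=0), 0.0, atol=1e-10)
        assert np.allclose(X.T @ X, 50.0 * np.eye(2), atol=1e-10)

    def test_two_groups_single_contrast(self):
        X = effect_design(["a", "a", "b", "b"])
        assert X.shape == (4, 1)
        direction = X[:, 0] / np.abs(X[:, 0])
        assert np.allclose(direction, [1, 1, -1, -1]) or np.allclose(direction, [-1, -1, 1, 1])

    def test_single_level_rejected(self):
        with pytest.raises(DegenerateDataError):
            effect_design(["a", "a", "a"])

    def test_anova_data_validation(self):
        with pytest.raises(ParameterError):
            AnovaData([1.0, 2.0, 3.0], ["a", "b", "a"])  # N < J + 2


class TestConditionalBF:
    def test_g_zero_returns_one(self, toy_anova):
        assert conditional_bf10(toy_anova, 0.0) == 1.0

    def test_location_scale_invariance(self, toy_anova_j3):
        base = log_jzs_bf10(toy_anova_j3, JZSPrior(0.5))
        for c, s in ((3.7, 1.0), (0.0, 12.5), (-2.2, 0.04)):
            shifted = AnovaData(s * toy_anova_j3.y + c, toy_anova_j3.group)
            assert log_jzs_bf10(shifted, JZSPrior(0.5)) == pytest.approx(base, abs=1e-10)
            assert conditional_bf10(shifted, 1.3) == pytest.approx(
                conditional_bf10(toy_anova_j3, 1.3), rel=1e-10
            )

    def test_constant_response_rejected(self):
        data = AnovaData(np.ones(8), np.repeat(["a", "b"], 4))
        with pytest.raises(DegenerateDataError):
            conditional_bf10(data, 1.0)

    def test_monotone_in_g(self, toy_anova):
        gs = np.linspace(0.0, 5.0, 30)
        # visible between-group separation: more prior spread helps H1
        strong = AnovaData(
            np.r_[np.zeros(5), 5.0 + np.zeros(5)] + 0.1 * np.sin(np.arange(10)),
            np.repeat(["a", "b"], 5),
        )
        vals = [conditional_bf10(strong, g) for g in gs]
        assert np.all(np.diff(vals) > 0)
        # exactly-null group means: extra spread is pure penalty
        null = AnovaData(np.tile([-1.0, 0.0, 1.0], 2), np.repeat(["a", "b"], 3))
        vals = [conditional_bf10(null, g) for g in gs]
        assert np.all(np.diff(vals) < 0)

    def test_matches_brute_force_integration(self, toy_anova):
        """Direct numerical integration of both marginals over (alpha, tau,
        log sigma^2) reproduces the analytic g-conditional Bayes factor."""
        g = 1.0
        X = effect_design(toy_anova.group)
        y = toy_anova.y
        N = y.size

        def log_like(alpha, tau, s):
            sigma2 = math.exp(s)
            resid = y - alpha - X[:, 0] * tau
            return -0.5 * N * math.log(2 * math.pi * sigma2) - float(resid @ resid) / (2 * sigma2)

        def m1():
            def inner_tau(alpha, s):
                sigma2 = math.exp(s)
                sd = math.sqrt(g * sigma2)

                def f(tau):
                    prior = math.exp(-(tau**2) / (2 * g * sigma2)) / (math.sqrt(2 * math.pi) * sd)
                    return math.exp(log_like(alpha, tau, s)) * prior

                val, _ = integrate.quad(f, -16 * sd, 16 * sd, epsabs=1e-14, epsrel=1e-11)
                return val

            def inner_alpha(s):
                val, _ = integrate.quad(
                    lambda a: inner_tau(a, s), -20, 20, epsabs=1e-14, epsrel=1e-11
                )
                return val

            # Jeffreys 1/sigma^2 with jacobian d sigma^2 = sigma^2 ds -> ds
            val, _ = integrate.quad(inner_alpha, -9, 6, epsabs=1e-15, epsrel=1e-10, limit=300)
            return val

        def m0():
            def inner_alpha(s):
                val, _ = integrate.quad(
                    lambda a: math.exp(log_like(a, 0.0, s)), -20, 20, epsabs=1e-14, epsrel=1e-11
                )
                return val

            val, _ = integrate.quad(inner_alpha, -9, 6, epsabs=1e-15, epsrel=1e-10, limit=300)
            return val

        oracle = m1() / m0()
        assert conditional_bf10(toy_anova, g) == pytest.approx(oracle, rel=1e-6)


class TestGIntegration:
    def test_tiny_scale_collapses_to_null(self, toy_anova_j3):
        assert jzs_bf10(toy_anova_j3, JZSPrior(1e-8)) == pytest.approx(1.0, abs=1e-4)

    def test_quadrature_matches_monte_carlo(self, toy_anova_j3):
        est = jzs_bf10(toy_anova_j3, JZSPrior(0.5))
        mc, se = mc_jzs_bf10(toy_anova_j3, JZSPrior(0.5), draws=400_000, seed=11)
        assert abs(est - mc) <= 3 * se

    def test_batch_grid_matches_adaptive_quadrature(self, gen_cfg):
        datasets = simulate_anova_h1(gen_cfg, 40) + simulate_anova_h0(gen_cfg, 10)
        prior = JZSPrior(0.5)
        grid = log_jzs_bf10_batch(datasets[:40], prior)
        for d, lg in zip(datasets[:40], grid):
            assert lg == pytest.approx(log_jzs_bf10(d, prior), abs=1e-7)
        # mixed layouts share the design, so the H0 tail works too
        grid0 = log_jzs_bf10_batch(datasets[40:], prior)
        for d, lg in zip(datasets[40:], grid0):
            assert lg == pytest.approx(log_jzs_bf10(d, prior), abs=1e-7)

    def test_null_like_data_favor_null(self):
        rng = np.random.default_rng(0)
        group = np.repeat(["a", "b", "c"], 200)
        y = rng.standard_normal(600)
        y -= np.repeat([y[:200].mean(), y[200:400].mean(), y[400:].mean()], 200)  # exact-null means
        assert jzs_bf10(AnovaData(y, group), JZSPrior(0.5)) < 1.0


class TestGenerators:
    def test_seeded_reproducibility(self, gen_cfg):
        a = simulate_anova_h1(gen_cfg, 3)
        b = simulate_anova_h1(gen_cfg, 3)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.y, db.y)

    def test_vanishing_effects_reduce_to_null_generator(self):
        cfg1 = AnovaGenConfig(J=3, per_group_n=10, sigma2=0.5, r_gen=1e-12, seed=5)
        cfg0 = AnovaGenConfig(J=3, per_group_n=10, sigma2=0.5, r_gen=0.5, seed=5)
        h1 = simulate_anova_h1(cfg1, 4)
        h0 = simulate_anova_h0(cfg0, 4)
        for da, db in zip(h1, h0):
            np.testing.assert_allclose(da.y, db.y, atol=1e-4)

    def test_null_bf_distribution_invariant_to_location_scale(self):
        """H0-generated Bayes factors depend only on the standardized noise,
        not on the intercept or error variance."""
        base = AnovaGenConfig(J=3, per_group_n=20, sigma2=0.5, seed=77)
        moved = AnovaGenConfig(J=3, per_group_n=20, sigma2=7.3, alpha0=-4.0, seed=77)
        prior = JZSPrior(0.5)
        bf_a = log_jzs_bf10_batch(simulate_anova_h0(base, 50), prior)
        bf_b = log_jzs_bf10_batch(simulate_anova_h0(moved, 50), prior)
        np.testing.assert_allclose(bf_a, bf_b, atol=1e-9)

    def test_effect_prior_inflates_group_mean_variance(self, gen_cfg):
        """Across H1 replicates the group means vary more than noise alone
        allows (law of total variance under the effect prior)."""
        datasets = simulate_anova_h1(gen_cfg, 2000)
        ng = gen_cfg.per_group_n
        var_means = np.mean(
            [np.var([d.y[d.group_index == j].mean() for j in range(3)], ddof=1) for d in datasets]
        )
        assert var_means > gen_cfg.sigma2 / ng

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            AnovaGenConfig(J=1)
        with pytest.raises(ParameterError):
            AnovaGenConfig(sigma2=0.0)


class TestTuringIdentityStochastic:
    def test_mean_inverse_bf_near_one_under_matched_prior(self, gen_cfg):
        """With generation and analysis priors matched, the mean BF01 over
        H1 prior-predictive datasets sits within Monte-Carlo error of 1."""
        m = 4000
        datasets = simulate_anova_h1(gen_cfg, m)
        bf01 = np.exp(np.maximum(-log_jzs_bf10_batch(datasets, JZSPrior(gen_cfg.r_gen)), -700))
        mean, se = bf01.mean(), bf01.std(ddof=1) / math.sqrt(m)
        assert abs(mean - 1.0) <= 4 * se

    def test_contrast_basis_orthonormal(self):
        for J in (2, 3, 6):
            Q = _contrast_basis(J)
            assert np.allclose(Q.T @ Q, np.eye(J - 1), atol=1e-12)
            assert np.allclose(Q.sum(axis=0), 0.0, atol=1e-12)
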