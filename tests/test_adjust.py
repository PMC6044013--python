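"""Empirical Bayes estimation, shrinkage, and the three adjustment modes."""

import numpy as np
import pytest
from scipy import stats

from combatkit import (
    DegeneratePriorError,
    DimensionError,
    SingleBatchError,
    SingletonBatchError,
    StudyDesign,
    combat,
    estimate_batch_effects,
    fit_hyperpriors,
    fit_location_scale,
    simulate_standardized_batches,
    solve_posteriors,
)
from combatkit.adjust import HyperPriors
from combatkit.model import StandardizedFit

from conftest import make_matrix, two_batch_design


def fit_from_z(Z, batch):
    """Wrap a raw standardized matrix for the EB layer."""
    Z = np.asarray(Z, dtype=float)
    n_g, n_s = Z.shape
    return (
        StandardizedFit(
            alpha=np.zeros(n_g),
            beta=np.empty((n_g, 0)),
            sigma=np.ones(n_g),
            Z=Z,
            mode="pooled",
            gene_ids=[f"g{i}" for i in range(n_g)],
            sample_ids=[f"s{j}" for j in range(n_s)],
        ),
        StudyDesign(batch),
    )


class TestEstimateBatchEffects:
    def test_two_point_batch(self):
        fit, design = fit_from_z([[-1.0, 1.0, 0.0, 0.0], [0.0, 2.0, 1.0, 3.0]], ["A"] * 2 + ["B"] * 2)
        gamma, delta2 = estimate_batch_effects(fit, design)
        assert gamma[0, 0] == pytest.approx(0.0)
        assert delta2[0, 0] == pytest.approx(2.0)   # ((-1)^2 + 1^2) / (2 - 1)
        assert gamma[1, 1] == pytest.approx(2.0)

    def test_matches_bruteforce_loops(self, rng):
        Z = rng.normal(0, 1, (50, 12))
        batch = ["A"] * 5 + ["B"] * 7
        fit, design = fit_from_z(Z, batch)
        gamma, delta2 = estimate_batch_effects(fit, design)
        for i, b in enumerate(["A", "B"]):
            cols = [j for j, lab in enumerate(batch) if lab == b]
            for g in range(50):
                vals = [Z[g, j] for j in cols]
                m = sum(vals) / len(vals)
                v = sum((x - m) ** 2 for x in vals) / (len(vals) - 1)
                assert gamma[i, g] == pytest.approx(m, abs=1e-12)
                assert delta2[i, g] == pytest.approx(v, abs=1e-12)

    def test_singleton_batch_rejected_in_variance_mode(self):
        fit, design = fit_from_z(np.random.default_rng(0).normal(size=(3, 3)), ["A", "A", "B"])
        with pytest.raises(SingletonBatchError):
            estimate_batch_effects(fit, design, with_variance=True)
        gamma, delta2 = estimate_batch_effects(fit, design, with_variance=False)
        assert delta2 is None and gamma.shape == (2, 3)

    def test_constant_gene_floored_not_zero(self, rng):
        Z = rng.normal(0, 1, (4, 6))
        Z[0, :3] = 1.0   # constant within batch A
        fit, design = fit_from_z(Z, ["A"] * 3 + ["B"] * 3)
        _, delta2 = estimate_batch_effects(fit, design)
        assert delta2[0, 0] > 0.0


class TestHyperPriors:
    def test_inverse_gamma_moment_match(self):
        # Vbar = 1, S2 = 1 -> lambda = 3, theta = 2; InvGamma(3, 2) has
        # mean theta/(lambda-1) = 1 and variance theta^2/((lambda-1)^2 (lambda-2)) = 1
        gamma_hat = np.array([[-1.0, 0.0, 1.0]])
        delta2_hat = np.array([[0.0, 1.0, 2.0]])
        assert delta2_hat.mean() == pytest.approx(1.0)
        assert delta2_hat.var(ddof=1) == pytest.approx(1.0)
        hyper = fit_hyperpriors(gamma_hat, delta2_hat)
        assert hyper.gamma_bar[0] == pytest.approx(0.0)
        assert hyper.tau2_bar[0] == pytest.approx(1.0)
        assert hyper.lam[0] == pytest.approx(3.0)
        assert hyper.theta[0] == pytest.approx(2.0)
        dist = stats.invgamma(hyper.lam[0], scale=hyper.theta[0])
        assert dist.mean() == pytest.approx(1.0)
        assert dist.var() == pytest.approx(1.0)

    def test_degenerate_prior_raises_then_falls_back(self):
        gamma_hat = np.array([[0.1, 0.2, 0.3]])
        delta2_hat = np.full((1, 3), 2.5)
        with pytest.raises(DegeneratePriorError):
            fit_hyperpriors(gamma_hat, delta2_hat)
        hyper = fit_hyperpriors(gamma_hat, delta2_hat, on_degenerate="fallback")
        assert hyper.degenerate[0]


class TestSolvePosteriors:
    def _setup(self, rng, n_genes=3, n=4):
        Z = rng.normal(0.5, 1.0, (n_genes, 2 * n))
        fit, design = fit_from_z(Z, ["A"] * n + ["B"] * n)
        gamma, delta2 = estimate_batch_effects(fit, design)
        hyper = fit_hyperpriors(gamma, delta2, design.batch_levels)
        return fit, design, gamma, delta2, hyper

    def test_no_shrinkage_in_flat_prior_limit(self, rng):
        # tau2 -> infinity: the prior carries no weight and gamma* -> gamma_hat
        fit, design, gamma, delta2, hyper = self._setup(rng)
        flat = HyperPriors(
            hyper.batches, hyper.gamma_bar, np.full_like(hyper.tau2_bar, 1e12),
            hyper.lam, hyper.theta,
        )
        gamma_star, _, _ = solve_posteriors(
            gamma, delta2, flat, fit, design, mode="original"
        )
        np.testing.assert_allclose(gamma_star, gamma, rtol=1e-6, atol=1e-8)

    def test_flat_prior_limit_mean_only(self, rng):
        fit, design, gamma, delta2, hyper = self._setup(rng)
        flat = HyperPriors(
            hyper.batches, hyper.gamma_bar, np.full_like(hyper.tau2_bar, 1e12),
            hyper.lam, hyper.theta,
        )
        gamma_star, delta2_star, _ = solve_posteriors(
            gamma, None, flat, fit, design, mode="mean_only"
        )
        np.testing.assert_allclose(gamma_star, gamma, rtol=1e-6)
        np.testing.assert_array_equal(delta2_star, 1.0)

    def test_equal_weights_give_midpoint_mean_only(self):
        # mean_only posterior: gamma* = (n tau2 g_hat + g_bar)/(n tau2 + 1);
        # with n tau2 = 1 it is the midpoint of g_hat and g_bar
        gamma_hat = np.array([[0.0, 1.0]])
        hyper = HyperPriors(["A"], np.array([0.5]), np.array([0.5]), np.array([np.nan]), np.array([np.nan]))
        Z = np.zeros((2, 2))
        fit, design = fit_from_z(Z, ["A", "A"])
        gamma_star, _, _ = solve_posteriors(gamma_hat, None, hyper, fit, design, mode="mean_only")
        np.testing.assert_allclose(gamma_star[0], [(0.0 + 0.5) / 2, (1.0 + 0.5) / 2])

    def test_fixed_point_matches_longrun_bruteforce(self, rng):
        fit, design, gamma, delta2, hyper = self._setup(rng)
        gamma_star, delta2_star, _ = solve_posteriors(
            gamma, delta2, hyper, fit, design, mode="original", tol=1e-13, max_iter=20000
        )
        # independent long-run iteration, plain python loops
        for i, b in enumerate(design.batch_levels):
            cols = np.where(design.batch_mask(b))[0]
            n = len(cols)
            for g in range(fit.n_genes):
                g_old, d_old = gamma[i, g], delta2[i, g]
                for _ in range(10000):
                    g_new = (n * hyper.tau2_bar[i] * gamma[i, g] + d_old * hyper.gamma_bar[i]) / (
                        n * hyper.tau2_bar[i] + d_old
                    )
                    s2 = sum((fit.Z[g, c] - g_new) ** 2 for c in cols)
                    d_old = (hyper.theta[i] + 0.5 * s2) / (n / 2 + hyper.lam[i] - 1)
                    g_old = g_new
                assert gamma_star[i, g] == pytest.approx(g_old, abs=1e-8)
                assert delta2_star[i, g] == pytest.approx(d_old, abs=1e-8)

    def test_shrinkage_is_toward_prior_mean(self, rng):
        fit, design, gamma, delta2, hyper = self._setup(rng, n_genes=30, n=6)
        gamma_star, _, _ = solve_posteriors(gamma, delta2, hyper, fit, design, mode="original")
        for i in range(2):
            lo = np.minimum(gamma[i], hyper.gamma_bar[i]) - 1e-9
            hi = np.maximum(gamma[i], hyper.gamma_bar[i]) + 1e-9
            assert np.all((gamma_star[i] >= lo) & (gamma_star[i] <= hi))


class TestCombat:
    def test_single_batch_rejected(self, rng):
        Y = make_matrix(rng.normal(0, 1, (5, 6)))
        with pytest.raises(SingleBatchError):
            combat(Y, StudyDesign(np.array(["A"] * 6)))

    def test_reference_mode_requires_reference(self, rng):
        Y = make_matrix(rng.normal(0, 1, (5, 6)))
        with pytest.raises(DimensionError):
            combat(Y, two_batch_design(3, 3), mode="reference")

    def test_reference_batch_bit_identical(self, random_study):
        Y, design = random_study
        design.reference_batch = "A"
        result = combat(Y, design, mode="reference")
        mask = design.batch_mask("A")
        assert np.array_equal(result.adjusted.values[:, mask], Y.values[:, mask])
        # and the non-reference batch did change
        assert not np.allclose(result.adjusted.values[:, ~mask], Y.values[:, ~mask])

    def test_mean_only_preserves_within_batch_variance(self, random_study):
        Y, design = random_study
        result = combat(Y, design, mode="mean_only")
        for b in design.batch_levels:
            mask = design.batch_mask(b)
            before = Y.values[:, mask].var(axis=1, ddof=1)
            after = result.adjusted.values[:, mask].var(axis=1, ddof=1)
            np.testing.assert_allclose(after, before, atol=1e-10)

    def test_identical_batches_nearly_unchanged(self, rng):
        # same generating distribution in both batches, large n: the
        # adjustment should be a near-no-op (mean shift < 3 standard errors)
        n = 500
        Y = make_matrix(rng.normal(3.0, 1.0, (40, 2 * n)))
        result = combat(Y, two_batch_design(n, n), mode="original")
        shift = np.abs(
            result.adjusted.values.mean(axis=1) - Y.values.mean(axis=1)
        )
        se = Y.values.std(axis=1, ddof=1) / np.sqrt(2 * n)
        assert np.all(shift < 3 * se)

    def test_original_mode_removes_batch_mean_differences(self, rng):
        seeds = range(20)
        ratios = []
        for seed in seeds:
            r = np.random.default_rng(seed)
            n_genes, n_i = 100, 10
            gamma = r.normal(0.5, np.sqrt(0.2), (2, n_genes))
            delta2 = stats.invgamma.rvs(3, scale=2, size=(2, n_genes), random_state=r)
            sigma_g = 1.0
            cols = []
            for i in range(2):
                eps = r.normal(0, sigma_g, (n_genes, n_i))
                cols.append(5.0 + gamma[i][:, None] + np.sqrt(delta2[i])[:, None] * eps)
            Y = make_matrix(np.hstack(cols))
            design = two_batch_design(n_i, n_i)
            adjusted = combat(Y, design, mode="original").adjusted.values
            def mean_absdiff(vals):
                return np.mean(
                    np.abs(vals[:, :n_i].mean(axis=1) - vals[:, n_i:].mean(axis=1))
                )
            ratios.append(mean_absdiff(Y.values) / mean_absdiff(adjusted))
        assert np.mean(ratios) >= 2.0, f"mean reduction only {np.mean(ratios):.2f}-fold"

    def test_approximate_idempotence(self, random_study):
        # a second pass only re-shrinks the sampling noise of the variance
        # estimates, so it moves the data an order of magnitude less than the
        # first pass (the residual decays ~1/n_i; exact idempotence would
        # need noiseless delta estimates)
        Y, design = random_study
        once = combat(Y, design, mode="original").adjusted
        twice = combat(once, design, mode="original").adjusted
        rms_first = np.sqrt(np.mean((once.values - Y.values) ** 2))
        rms_second = np.sqrt(np.mean((twice.values - once.values) ** 2))
        assert rms_second < 0.1 * rms_first

    def test_order_invariance(self, random_study, rng):
        Y, design = random_study
        order = rng.permutation(Y.n_samples)
        adjusted = combat(Y, design, mode="original").adjusted.values
        Y_p = make_matrix(Y.values[:, order])
        adjusted_p = combat(Y_p, design.permuted(order), mode="original").adjusted.values
        np.testing.assert_allclose(adjusted[:, order], adjusted_p, atol=1e-9)

    def test_shrinkage_dominance_on_hierarchical_draws(self):
        # posterior (gamma*, delta2*) beats raw (gamma_hat, delta2_hat) in MSE
        wins_g, wins_d = 0, 0
        for seed in range(10):
            Z, batch, gamma_true, delta2_true = simulate_standardized_batches(seed)
            fit, design = fit_from_z(Z, batch)
            gamma, delta2 = estimate_batch_effects(fit, design)
            hyper = fit_hyperpriors(gamma, delta2, design.batch_levels)
            gamma_star, delta2_star, _ = solve_posteriors(
                gamma, delta2, hyper, fit, design, mode="original"
            )
            wins_g += np.mean((gamma_star - gamma_true) ** 2) <= np.mean((gamma - gamma_true) ** 2)
            wins_d += np.mean((delta2_star - delta2_true) ** 2) <= np.mean((delta2 - delta2_true) ** 2)
        assert wins_g >= 8 and wins_d >= 8
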