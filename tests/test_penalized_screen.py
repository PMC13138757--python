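"""Gehan loss, MCP, and the penalized screening fits (Step 1)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smahp.data_io import SurvivalOutcome
from smahp.penalized_screen import (
    PenaltySpec,
    fit_penalized_aft,
    fit_penalized_mediator,
    gehan_loss,
    mcp_penalty,
    step1,
)


def brute_force_gehan(beta, X, y, delta):
    n = len(y)
    e = y - X @ np.asarray(beta)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if delta[i] > 0:
                total += max(0.0, e[j] - e[i])
    return total / n**2


class TestGehanLoss:
    def test_hand_example(self):
        # two events, log-times (1, 2), null feature: (1/4)[max(0,1)+max(0,-1)]
        out = SurvivalOutcome(np.exp([1.0, 2.0]), [1, 1])
        assert gehan_loss([0.0], np.zeros((2, 1)), out) == pytest.approx(0.25)

    def test_equal_residuals_zero_loss(self, rng):
        X = rng.normal(size=(6, 2))
        beta = np.array([1.5, -0.7])
        y = X @ beta  # residuals identically zero
        out = SurvivalOutcome(np.exp(y), np.ones(6))
        assert gehan_loss(beta, X, out) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 9)
        X = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        delta = rng.binomial(1, 0.7, size=n).astype(float)
        if delta.sum() == 0:
            delta[0] = 1.0
        beta = rng.normal(size=3)
        out = SurvivalOutcome(np.exp(y), delta)
        assert gehan_loss(beta, X, out) == pytest.approx(
            brute_force_gehan(beta, X, y, delta), abs=1e-12
        )

    @given(st.integers(0, 10_000), st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_convexity(self, seed, t):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(7, 2))
        y = rng.normal(size=7)
        out = SurvivalOutcome(np.exp(y), np.r_[1.0, rng.binomial(1, 0.5, 6)])
        b1, b2 = rng.normal(size=2), rng.normal(size=2)
        mix = t * b1 + (1 - t) * b2
        lhs = gehan_loss(mix, X, out)
        rhs = t * gehan_loss(b1, X, out) + (1 - t) * gehan_loss(b2, X, out)
        assert lhs <= rhs + 1e-10

    def test_invariant_to_log_time_shift(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        beta = rng.normal(size=2)
        a = gehan_loss(beta, X, SurvivalOutcome(np.exp(y), np.ones(10)))
        b = gehan_loss(beta, X, SurvivalOutcome(np.exp(y + 3.7), np.ones(10)))
        assert a == pytest.approx(b, abs=1e-12)

    def test_no_events_error(self):
        out = SurvivalOutcome([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="Gehan loss undefined"):
            gehan_loss([0.0], np.zeros((2, 1)), out)


class TestMCP:
    def test_values(self):
        assert mcp_penalty(0.0, 1.0, 3.0) == 0.0
        assert mcp_penalty(5.0, 1.0, 3.0) == pytest.approx(1.5)  # gamma*lam^2/2
        assert mcp_penalty(1.0, 1.0, 3.0) == pytest.approx(1.0 - 1.0 / 6.0)

    def test_constant_beyond_kink_and_monotone(self):
        b = np.linspace(0, 10, 500)
        vals = mcp_penalty(b, 0.7, 3.0)
        assert np.all(np.diff(vals) >= -1e-12)  # nondecreasing in |beta|
        beyond = b >= 3.0 * 0.7
        np.testing.assert_allclose(vals[beyond], 0.5 * 3.0 * 0.7**2)

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcp_penalty(1.0, 1.0, 0.9)


class TestPenalizedAFT:
    def test_full_shrinkage_at_large_lambda(self, censored_outcome):
        X, outcome = censored_outcome
        fit = fit_penalized_aft(X, outcome, PenaltySpec(family="lasso", lam=1e6))
        assert fit.active_set == []
        np.testing.assert_array_equal(fit.coefficients, 0.0)

    def test_lambda_zero_matches_generic_convex_solver(self, rng):
        from scipy.optimize import minimize

        from smahp._solvers import smoothed_gehan_loss

        n = 80
        X = rng.normal(size=(n, 2))
        y = X @ np.array([1.0, -0.5]) + 0.5 * rng.normal(size=n)
        out = SurvivalOutcome(np.exp(y), np.ones(n))
        fit = fit_penalized_aft(X, out, PenaltySpec(family="lasso", lam=0.0))
        h = max(np.std(y) / np.sqrt(n), 1e-6)
        Xs = (X - X.mean(0)) / X.std(0)
        res = minimize(
            lambda b: smoothed_gehan_loss(y - Xs @ b, np.ones(n), h, n),
            np.zeros(2),
            method="Nelder-Mead",
            options=dict(xatol=1e-9, fatol=1e-13),
        )
        np.testing.assert_allclose(fit.coefficients, res.x / X.std(0), atol=1e-3)

    def test_cv_recovers_strong_signal(self, rng):
        hits = 0
        for seed in range(8):
            local = np.random.default_rng(seed)
            X = local.normal(size=(150, 10))
            y = 2.0 * X[:, 3] + 0.5 * local.normal(size=150)
            out = SurvivalOutcome(np.exp(y), np.ones(150))
            fit = fit_penalized_aft(X, out, seed=seed)
            hits += 3 in fit.active_set
        assert hits >= 7

    def test_monotone_sparsity_along_path(self, censored_outcome):
        X, outcome = censored_outcome
        sizes = []
        for lam_scale in (0.8, 0.3, 0.1, 0.02):
            fit = fit_penalized_aft(
                X, outcome, PenaltySpec(family="lasso", lam=lam_scale)
            )
            sizes.append(len(fit.active_set))
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))


class TestPenalizedMediator:
    def test_mcp_limits_to_lasso_at_huge_gamma(self, rng):
        X = rng.normal(size=(200, 20))
        mk = 0.8 * X[:, 2] + 0.8 * X[:, 7] + 0.5 * rng.normal(size=200)
        m1 = fit_penalized_mediator(X, mk, PenaltySpec(family="mcp", gamma=1e6, lam=0.1))
        m2 = fit_penalized_mediator(X, mk, PenaltySpec(family="lasso", lam=0.1))
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-4)

    def test_lasso_matches_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X = rng.normal(size=(100, 8))
        y = X[:, 1] - 0.6 * X[:, 4] + 0.3 * rng.normal(size=100)
        lam = 0.05
        fit = fit_penalized_mediator(X, y, PenaltySpec(family="lasso", lam=lam))
        Xs = (X - X.mean(0)) / X.std(0)
        ref = sklearn.Lasso(alpha=lam, fit_intercept=True, tol=1e-10)
        ref.fit(Xs, y - y.mean())
        np.testing.assert_allclose(fit.coefficients * X.std(0), ref.coef_, atol=1e-4)

    def test_soft_threshold_bound_gives_empty_set(self, rng):
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        Xs = (X - X.mean(0)) / X.std(0)
        lam_max = np.abs(Xs.T @ (y - y.mean())).max() / 50
        fit = fit_penalized_mediator(X, y, PenaltySpec(family="lasso", lam=lam_max * 1.01))
        assert fit.active_set == []

    def test_cv_selects_true_exposures(self):
        hits = 0
        for seed in range(8):
            local = np.random.default_rng(seed)
            X = local.normal(size=(200, 20))
            mk = 0.8 * (X[:, 2] + X[:, 7]) + 0.5 * local.normal(size=200)
            fit = fit_penalized_mediator(X, mk, seed=seed)
            hits += {2, 7} <= set(fit.active_set)
        assert hits >= 7


class TestStep1:
    def test_noiseless_strong_mediator_selected(self, rng, single_pathway_dataset):
        active = step1(single_pathway_dataset, seed=5)
        assert 0 in active.S1
        assert 0 in active.J1.get(0, [])

    def test_pure_noise_rarely_selects_mediators(self):
        empty = 0
        for seed in range(5):
            local = np.random.default_rng(seed + 100)
            M = local.normal(size=(150, 20))
            y = local.normal(size=150)
            out = SurvivalOutcome(np.exp(y), np.ones(150))
            fit = fit_penalized_aft(M, out, seed=seed)
            empty += len(fit.active_set) == 0
        assert empty >= 3

    def test_constant_mediators_are_handled(self, censored_outcome):
        X, outcome = censored_outcome
        M = np.column_stack([np.full(outcome.n, 2.0), X[:, :1]])
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_penalized_aft(M, outcome)
        assert fit.coefficients[0] == 0.0


class TestSolverInternals:
    def test_sorted_gradient_matches_pairwise_reference(self):
        """The O(n log n) loss/gradient equals the literal pairwise double loop."""
        from smahp._solvers import (
            _smoothed_gehan_loss_grad,
            _smoothed_gehan_loss_grad_ref,
        )

        for seed in range(10):
            local = np.random.default_rng(seed)
            n = int(local.integers(5, 200))
            d = int(local.integers(1, 6))
            X = local.normal(size=(n, d))
            y = local.normal(size=n) * local.uniform(0.5, 4)
            delta = local.binomial(1, local.uniform(0.3, 1.0), n).astype(float)
            beta = local.normal(size=d)
            h = local.uniform(1e-4, 1.0)
            ridge = local.uniform(0, 0.3)
            l1, g1 = _smoothed_gehan_loss_grad(X, beta, y, delta, h, ridge)
            l2, g2 = _smoothed_gehan_loss_grad_ref(X, beta, y, delta, h, ridge)
            assert l1 == pytest.approx(l2, rel=1e-10, abs=1e-12)
            np.testing.assert_allclose(g1, g2, rtol=1e-9, atol=1e-12)
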