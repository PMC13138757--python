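"""Step 3: joint-significance testing, BH adjustment and effect estimates."""

import numpy as np
import pytest

from conftest import make_dataset
from smahp.data_io import SurvivalOutcome
from smahp.js_inference import (
    SmahpConfig,
    bh_adjust,
    estimate_effects,
    fit_final_models,
    pmax_combine,
    run_smahp,
    wald_pvalue,
)
from smahp.penalized_screen import ActiveSets
from smahp.sis_screen import ScreenedPairs


class TestWaldPvalue:
    def test_null_estimate_gives_one(self):
        assert wald_pvalue(0.0, 1.0) == 1.0

    def test_quantile_values(self):
        assert wald_pvalue(1.959964, 1.0) == pytest.approx(0.05, abs=5e-5)
        assert wald_pvalue(3.0, 1.0) == pytest.approx(0.002700, abs=5e-7)

    def test_nonpositive_se_errors(self):
        with pytest.raises(ValueError):
            wald_pvalue(1.0, 0.0)


class TestPmaxCombine:
    def test_elementwise_max(self):
        out = pmax_combine(np.array([[0.001]]), np.array([0.04]))
        assert out[0, 0] == 0.04

    def test_unit_p_beta_floods_column(self, rng):
        p_alpha = rng.uniform(size=(4, 2))
        p_beta = np.array([1.0, 0.2])
        out = pmax_combine(p_alpha, p_beta)
        np.testing.assert_array_equal(out[:, 0], 1.0)

    def test_matches_brute_force(self, rng):
        p_alpha = rng.uniform(size=(3, 2))
        p_beta = rng.uniform(size=2)
        out = pmax_combine(p_alpha, p_beta)
        for i in range(3):
            for j in range(2):
                assert out[i, j] == max(p_alpha[i, j], p_beta[j])

    def test_range_check(self):
        with pytest.raises(ValueError):
            pmax_combine(np.array([[1.5]]), np.array([0.5]))


class TestBHAdjust:
    def test_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_singleton(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_array_equal(bh_adjust([0.37]), [0.37])

    def test_raising_raw_p_never_lowers_adjusted(self, rng):
        p = rng.uniform(size=10)
        adj = bh_adjust(p)
        p2 = p.copy()
        p2[3] = min(1.0, p2[3] + 0.2)
        adj2 = bh_adjust(p2)
        assert np.all(adj2 >= adj - 1e-12)


class TestEffects:
    def _screened(self):
        return ScreenedPairs(S2=[0], J2={0: [0]}, scores={(0, 0): 1.0}, threshold_d=5)

    def test_delta_method_example(self):
        # alpha = 2 +- 0.1, beta = 3 +- 0.2 -> IIE 6 +- 0.5, CI (5.02, 6.98)
        from smahp.aft import AFTFit
        from smahp.sis_screen import MediatorOLSFit

        outcome_fit = AFTFit(
            names=["m0"], coefficients=np.array([3.0]),
            standard_errors=np.array([0.2]), scale=1.0, log_likelihood=0.0,
            error_family="log_normal",
        )
        med_fit = MediatorOLSFit([0], np.array([2.0]), np.array([0.1]))
        eff = estimate_effects(
            outcome_fit, {0: med_fit}, self._screened(),
            ActiveSets(S1=[0], A_T=[], J1={}), effect_scale="unit",
        )
        row = eff.iie.iloc[0]
        assert row["iie"] == pytest.approx(6.0)
        assert row["iie_se"] == pytest.approx(0.5)
        assert row["ci_lo"] == pytest.approx(5.02, abs=0.001)
        assert row["ci_hi"] == pytest.approx(6.98, abs=0.001)

    def test_zero_alpha_gives_zero_iie(self):
        from smahp.aft import AFTFit
        from smahp.sis_screen import MediatorOLSFit

        outcome_fit = AFTFit(["m0"], np.array([3.0]), np.array([0.2]), 1.0, 0.0,
                             "log_normal")
        med_fit = MediatorOLSFit([0], np.array([0.0]), np.array([0.5]))
        eff = estimate_effects(outcome_fit, {0: med_fit}, self._screened(),
                               ActiveSets(), effect_scale="unit")
        assert eff.iie.iloc[0]["iie"] == 0.0

    def test_delta_method_ci_coverage(self):
        """95% delta-method CI for alpha*beta covers the truth at the right rate."""
        n, reps = 2000, 300
        alpha_true, beta_true = 0.8, 1.5
        covered = 0
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=n)
            m = alpha_true * x + rng.normal(size=n)
            y = beta_true * m + rng.normal(size=n)
            # closed-form OLS for both regressions
            a_hat = (x @ m) / (x @ x)
            se_a = np.sqrt(np.sum((m - a_hat * x) ** 2) / (n - 1) / (x @ x))
            D = np.column_stack([m, x])
            coef, *_ = np.linalg.lstsq(D, y, rcond=None)
            resid = y - D @ coef
            cov = np.linalg.inv(D.T @ D) * (resid @ resid) / (n - 2)
            b_hat, se_b = coef[0], np.sqrt(cov[0, 0])
            est = a_hat * b_hat
            se = np.sqrt(a_hat**2 * se_b**2 + b_hat**2 * se_a**2)
            covered += abs(est - alpha_true * beta_true) < 1.96 * se
        assert 0.93 * reps <= covered <= 0.97 * reps


class TestFinalModels:
    def test_no_censoring_matches_ols(self, single_pathway_dataset):
        ds = single_pathway_dataset
        ds.outcome.event[:] = 1.0
        screened = ScreenedPairs(S2=[0], J2={0: [0]}, scores={(0, 0): 1.0})
        active = ActiveSets(S1=[0], A_T=[0, 1], J1={0: [0]})
        outcome_fit, med_fits = fit_final_models(ds, screened, active)
        D = np.column_stack(
            [ds.X.values[:, [0, 1]], ds.M.values[:, [0]], ds.Z, np.ones(ds.n)]
        )
        ols = np.linalg.lstsq(D, ds.outcome.log_time, rcond=None)[0]
        assert outcome_fit.coef("m0") == pytest.approx(ols[2], abs=1e-4)

    def test_empty_s2_errors(self, single_pathway_dataset):
        with pytest.raises(ValueError, match="nothing to test"):
            fit_final_models(single_pathway_dataset, ScreenedPairs(), ActiveSets())


class TestRunSmahp:
    def test_dominant_pathway_is_unique_discovery(self, single_pathway_dataset):
        res = run_smahp(single_pathway_dataset, SmahpConfig(seed=3))
        assert res.stage == "complete"
        assert res.discoveries == [(0, 0)]

    def test_end_to_end_determinism(self, single_pathway_dataset):
        r1 = run_smahp(single_pathway_dataset, SmahpConfig(seed=11))
        r2 = run_smahp(single_pathway_dataset, SmahpConfig(seed=11))
        t1 = r1.pair_table(single_pathway_dataset).to_csv()
        t2 = r2.pair_table(single_pathway_dataset).to_csv()
        assert t1 == t2
        assert r1.discoveries == r2.discoveries

    def test_null_dataset_returns_empty_result(self, rng):
        n = 150
        X = rng.normal(size=(n, 10))
        M = rng.normal(size=(n, 12))
        out = SurvivalOutcome(np.exp(rng.normal(size=n)), np.ones(n))
        ds = make_dataset(X, M, rng.normal(size=(n, 2)), out)
        res = run_smahp(ds, SmahpConfig(seed=1))
        if res.empty:
            assert res.stage in ("step1_empty", "step2_empty")
            assert res.pair_table(ds).empty
        else:
            assert len(res.discoveries) == 0

    def test_pmax_dominates_components(self, single_pathway_dataset):
        res = run_smahp(single_pathway_dataset, SmahpConfig(seed=3))
        pm = res.pmax
        for (r, c) in np.argwhere(pm.tested):
            s = pm.mediator_idx[c]
            fit = res.outcome_fit
            p_beta = wald_pvalue(fit.coef(f"m{s}"), fit.se(f"m{s}"))
            assert pm.values[r, c] >= p_beta - 1e-12
            assert pm.adjusted[r, c] >= pm.values[r, c] - 1e-12


class TestBootstrapIIE:
    def test_percentile_interval_brackets_dominant_effect(self, single_pathway_dataset):
        from smahp.js_inference import bootstrap_iie
        from smahp.penalized_screen import ActiveSets
        from smahp.sis_screen import ScreenedPairs

        ds = single_pathway_dataset
        screened = ScreenedPairs(S2=[0], J2={0: [0]}, scores={(0, 0): 1.0})
        active = ActiveSets(S1=[0], A_T=[1], J1={0: [0]})
        ci = bootstrap_iie(ds, screened, active, n_boot=80, seed=4)
        row = ci.iloc[0]
        # planted pathway: alpha = 1.2, beta = 2 -> product 2.4
        assert row["ci_lo"] < 2.4 < row["ci_hi"]
        assert row["n_boot_ok"] >= 70
        # seeded rerun is identical
        ci2 = bootstrap_iie(ds, screened, active, n_boot=80, seed=4)
        assert ci.equals(ci2)
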