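"""Screen statistics: mixed models, BH, radius-wise tests, NMF, ANOVA."""

import warnings

import numpy as np
import pandas as pd
import pytest

from morphoscreen.metrics import ShollProfile
from morphoscreen.stats import (bh_adjust, differential_morphometry, fit_lmm,
                                nmf_metric_modules, reml_random_intercept,
                                sholl_radius_tests, spine_group_tests)


def _simulate_screen(rng, n_brains=12, per_brain=10, effect=0.0,
                     brain_sd=0.3, resid_sd=0.95):
    brains = np.repeat([f"b{i}" for i in range(n_brains)], per_brain)
    group = np.repeat(["control"] * (n_brains // 2) + ["pert"] * (n_brains // 2),
                      per_brain)
    b = rng.normal(0, brain_sd, n_brains)
    y = (effect * (group == "pert")
         + b[np.repeat(np.arange(n_brains), per_brain)]
         + rng.normal(0, resid_sd, n_brains * per_brain))
    return y, group, brains


class TestREML:
    def test_matches_statsmodels_mixedlm(self):
        """The profiled solver must agree with (or beat, in restricted
        likelihood) the general-purpose REML optimizer."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        for _ in range(5):
            y, group, brains = _simulate_screen(rng, effect=0.5)
            X = np.column_stack([np.ones(len(y)), (group == "pert").astype(float)])
            beta, cov, vb, ve, lam = reml_random_intercept(y, X, brains)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = sm.MixedLM(y, X, groups=brains).fit(reml=True,
                                                        method="powell")
            assert beta[1] == pytest.approx(f.fe_params[1], abs=1e-6)
            assert np.sqrt(cov[1, 1]) == pytest.approx(f.bse_fe[1], abs=1e-4)
            assert vb == pytest.approx(float(np.asarray(f.cov_re)[0, 0]),
                                       abs=1e-3)

    def test_zero_brain_variance_collapses_to_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        y, group, brains = _simulate_screen(rng, brain_sd=0.0)
        fit = fit_lmm(y, group, brains, "control")
        X = np.column_stack([np.ones(len(y)), (group == "pert").astype(float)])
        ols = sm.OLS(y, X).fit()
        assert fit.table.loc["pert", "effect"] == pytest.approx(
            ols.params[1], abs=0.02)

    def test_confounded_design_falls_back_to_ols(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=20)
        group = ["control"] * 10 + ["pert"] * 10
        brains = ["b1"] * 10 + ["b2"] * 10   # group == brain
        with pytest.warns(UserWarning, match="falling back to OLS"):
            fit = fit_lmm(y, group, brains, "control")
        assert fit.method == "ols"

    def test_missing_values_dropped(self):
        rng = np.random.default_rng(3)
        y, group, brains = _simulate_screen(rng)
        y[:5] = np.nan
        fit = fit_lmm(y, group, brains, "control")
        assert fit.table.loc["pert", "n_ref"] == 55

    def test_input_validation(self):
        with pytest.raises(ValueError, match="reference"):
            fit_lmm([1, 2], ["a", "a"], ["b1", "b2"], "zzz")
        with pytest.raises(ValueError, match="2 brains"):
            fit_lmm([1, 2, 3, 4], ["a", "a", "b", "b"],
                    ["b1", "b1", "b1", "b1"], "a")


class TestEffectRecovery:
    def test_type_one_error_calibrated(self):
        """Null screens: per-test rejection rate at alpha=0.05 stays near
        nominal (pooled over simulations)."""
        rng = np.random.default_rng(4)
        rejections = []
        for _ in range(120):
            y, group, brains = _simulate_screen(rng, effect=0.0)
            fit = fit_lmm(y, group, brains, "control")
            rejections.append(fit.table.loc["pert", "p"] < 0.05)
        rate = np.mean(rejections)
        assert 0.01 < rate < 0.10

    def test_effect_estimate_unbiased(self):
        rng = np.random.default_rng(5)
        est = []
        for _ in range(60):
            y, group, brains = _simulate_screen(rng, effect=1.0)
            fit = fit_lmm(y, group, brains, "control")
            est.append(fit.table.loc["pert", "effect"])
        assert abs(np.mean(est) - 1.0) < 0.1


class TestDifferentialMorphometry:
    def test_single_metric_padj_equals_p(self):
        rng = np.random.default_rng(6)
        y, group, brains = _simulate_screen(rng)
        table = pd.DataFrame({"m1": y}, index=[f"n{i}" for i in range(len(y))])
        meta = pd.DataFrame({"perturbation": group, "brain_id": brains},
                            index=table.index)
        out = differential_morphometry(table, meta, "control")
        assert out["p_adj"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_injected_metric_flagged_among_nulls(self):
        rng = np.random.default_rng(7)
        n = 120
        cols = {}
        y, group, brains = _simulate_screen(rng, effect=1.5)
        cols["hit"] = y
        for j in range(11):
            cols[f"null{j}"] = _simulate_screen(rng, effect=0.0)[0]
        table = pd.DataFrame(cols, index=[f"n{i}" for i in range(n)])
        meta = pd.DataFrame({"perturbation": group, "brain_id": brains},
                            index=table.index)
        out = differential_morphometry(table, meta, "control").set_index("feature")
        assert out.loc["hit", "p_adj"] < 0.05


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_monotone_in_discoveries(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=30)
        base = (bh_adjust(p) < 0.05).sum()
        p2 = p.copy()
        p2[0] = p2[0] / 10
        assert (bh_adjust(p2) < 0.05).sum() >= base

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        np.testing.assert_allclose(bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1])


class TestShollRadiusTests:
    @staticmethod
    def _profiles(values_per_neuron):
        return [ShollProfile(10.0 * np.arange(1, len(v) + 1), np.array(v))
                for v in values_per_neuron]

    def test_identical_groups_p_one(self):
        a = self._profiles([[3, 2, 1]] * 4)
        b = self._profiles([[3, 2, 1]] * 4)
        out = sholl_radius_tests({"a": a, "b": b})
        assert (out["p"] == 1.0).all()

    def test_extreme_ranks_exact_p(self):
        # one radius; counts (1,2,3) vs (10,11,12): exact two-sided p = 0.1
        a = self._profiles([[1], [2], [3]])
        b = self._profiles([[10], [11], [12]])
        out = sholl_radius_tests({"a": a, "b": b})
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_shifted_radius_survives_bh(self):
        rng = np.random.default_rng(10)
        base = lambda: list(rng.poisson(5, 10))
        a = self._profiles([base() for _ in range(12)])
        b_vals = []
        for _ in range(12):
            v = base()
            v[4] += 12          # strong shift at radius 50 only
            b_vals.append(v)
        b = self._profiles(b_vals)
        out = sholl_radius_tests({"a": a, "b": b}).set_index("radius")
        assert out.loc[50.0, "p_adj"] < 0.05
        assert (out.drop(index=50.0)["p_adj"] > 0.05).all()


class TestNMF:
    @staticmethod
    def _planted(rng, n=80, m=30, k=3):
        W = rng.uniform(0.5, 2.0, (n, k))
        H = rng.uniform(0.0, 1.0, (k, m))
        return W, H, W @ H

    def test_planted_rank3_recovery(self):
        rng = np.random.default_rng(11)
        W0, H0, V = self._planted(rng)
        model = nmf_metric_modules(pd.DataFrame(V), k=3, seed=0,
                                   preprocess=False)
        rel = model.reconstruction_error / np.linalg.norm(V)
        assert rel < 1e-3
        # best-match cosine between recovered and true loadings
        Hn = model.H / np.linalg.norm(model.H, axis=1, keepdims=True)
        H0n = H0 / np.linalg.norm(H0, axis=1, keepdims=True)
        sim = Hn @ H0n.T
        assert all(sim.max(axis=0) > 0.95)

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(12)
        _, _, V = self._planted(rng)
        model = nmf_metric_modules(pd.DataFrame(V), k=3, seed=1,
                                   preprocess=False, n_init=1)
        diffs = np.diff(model.error_trace)
        assert (diffs <= 1e-9).all()

    def test_rank1_matches_svd_residual(self):
        rng = np.random.default_rng(13)
        V = rng.uniform(0.1, 1.0, (40, 15))
        model = nmf_metric_modules(pd.DataFrame(V), k=1, seed=2,
                                   preprocess=False)
        s = np.linalg.svd(V, compute_uv=False)
        rank1_resid = np.sqrt((s[1:] ** 2).sum())
        assert model.reconstruction_error == pytest.approx(rank1_resid,
                                                           rel=1e-3)

    def test_seed_determinism(self):
        rng = np.random.default_rng(14)
        _, _, V = self._planted(rng)
        m1 = nmf_metric_modules(pd.DataFrame(V), k=3, seed=5, preprocess=False)
        m2 = nmf_metric_modules(pd.DataFrame(V), k=3, seed=5, preprocess=False)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.H, m2.H)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            nmf_metric_modules(pd.DataFrame(np.ones((4, 3))), k=5)

    def test_preprocessing_shifts_nonnegative(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(50, 8))
        model = nmf_metric_modules(pd.DataFrame(X), k=2, seed=0)
        assert (model.W >= 0).all() and (model.H >= 0).all()
        assert model.offsets.shape == (8,)


class TestSpineGroupTests:
    def test_two_groups_f_equals_t_squared(self):
        from scipy import stats as sps

        rng = np.random.default_rng(16)
        a = rng.normal(0.3, 0.05, 12)
        b = rng.normal(0.4, 0.05, 12)
        F, p, _ = spine_group_tests(np.r_[a, b], ["a"] * 12 + ["b"] * 12)
        t = sps.ttest_ind(a, b).statistic
        assert F == pytest.approx(t ** 2, rel=1e-9)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(50):
            d = rng.normal(0.3, 0.05, 30)
            F, p, _ = spine_group_tests(d, ["a", "b", "c"] * 10)
            ps.append(p)
        assert 0.3 < np.mean(ps) < 0.7

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            spine_group_tests([1.0, 2.0], ["a", "a"])

    def test_tukey_flags_separated_group(self):
        rng = np.random.default_rng(18)
        d = np.r_[rng.normal(0.3, 0.02, 10), rng.normal(0.3, 0.02, 10),
                  rng.normal(0.6, 0.02, 10)]
        _, _, tk = spine_group_tests(d, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        tk = tk.set_index(["group1", "group2"])
        assert float(tk.loc[("a", "c"), "p_adj"]) < 0.05
        assert float(tk.loc[("a", "b"), "p_adj"]) > 0.05
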