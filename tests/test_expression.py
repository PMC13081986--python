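"""Expression screen: QC, guide assignment, DE, signatures, concordance."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from morphoscreen.expression import (CountMatrix, assign_guides,
                                     classify_signatures, fisher_enrichment,
                                     filter_genes, nb_glm_de, pairing_stats,
                                     pseudobulk, qc_cells, scale_to_reference,
                                     sign_concordance, size_factors,
                                     smooth_trajectory)
from morphoscreen.synth import (CountSimParams, GuideSimParams, gen_counts,
                                gen_guide_assignments, guide_library)


def _toy_matrix(meta_rows, n_genes=3):
    meta = pd.DataFrame(meta_rows).set_index("unit_id")
    counts = pd.DataFrame(
        np.ones((n_genes, len(meta)), dtype=int),
        index=[f"g{i}" for i in range(n_genes)], columns=meta.index)
    return CountMatrix(counts=counts, unit_meta=meta)


class TestQCCells:
    def _cells(self):
        base = dict(n_genes_detected=1000, n_umi=5000, mito_fraction=0.01,
                    doublet_score=0.2)
        rows = []
        for i, override in enumerate([
                {}, {"n_genes_detected": 100}, {"doublet_score": 2.0},
                {"n_umi": 50_000}, {"mito_fraction": 0.05}, {}, {}, {}, {}, {}]):
            rows.append({"unit_id": f"c{i}", **base, **override})
        return rows

    def test_one_violation_per_filter(self):
        m = _toy_matrix(self._cells())
        mask, counts = qc_cells(m, multiplet_cells=["c5"])
        assert counts == {"low_genes": 1, "doublet_score": 1, "high_umi": 1,
                          "high_mito": 1, "multiplet": 1, "retained": 5}

    def test_all_clean_identity(self):
        rows = self._cells()[:1] * 1
        m = _toy_matrix([{**rows[0], "unit_id": f"c{i}"} for i in range(4)])
        mask, counts = qc_cells(m)
        assert mask.all()

    def test_boundary_values_retained(self):
        base = dict(n_genes_detected=250, n_umi=30_000, mito_fraction=0.02,
                    doublet_score=1.2)
        m = _toy_matrix([{"unit_id": "c0", **base}])
        mask, _ = qc_cells(m)
        assert mask.all()   # exclusions are strict inequalities


class TestAssignGuides:
    lib = guide_library(3)

    def _calls(self, guide_sets):
        return pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(guide_sets))],
                             "guides": guide_sets})

    def test_single_guide_maps_to_vector(self):
        out = assign_guides(self._calls([["vec1_a"]]), self.lib)
        assert out.loc[0, "status"] == "singlet"
        assert out.loc[0, "perturbation"] == "gene1"

    def test_matched_pair_reclassified_singlet(self):
        out = assign_guides(self._calls([["vec1_a", "vec1_b"]]), self.lib)
        assert out.loc[0, "status"] == "singlet"
        assert out.loc[0, "perturbation"] == "gene1"

    def test_unmatched_pair_is_multiplet(self):
        out = assign_guides(self._calls([["vec1_a", "vec2_a"]]), self.lib)
        assert out.loc[0, "status"] == "multiplet"
        assert out.loc[0, "perturbation"] is None

    def test_empty_is_unassigned(self):
        out = assign_guides(self._calls([[]]), self.lib)
        assert out.loc[0, "status"] == "unassigned"

    def test_unknown_guide_errors(self):
        with pytest.raises(ValueError, match="not in library"):
            assign_guides(self._calls([["bogus"]]), self.lib)

    def test_idempotent_and_no_excess_singlets(self):
        calls, lib, _ = gen_guide_assignments(GuideSimParams(seed=3, n_cells=200))
        out1 = assign_guides(calls, lib)
        assert (out1["status"] == "singlet").sum() <= len(calls)
        out2 = assign_guides(out1.rename(columns={"guides": "guides"}), lib)
        pd.testing.assert_frame_equal(out1, out2)


class TestPairingStats:
    def test_uniform_chance_closed_form(self):
        # G guides with uniform frequencies: chance = 1/(G-1)
        for n_pairs in (2, 4, 8):
            lib = guide_library(n_pairs)
            calls = pd.DataFrame({"cell_id": ["c0"],
                                  "guides": [[lib["guide"][0], lib["guide"][1]]]})
            st = pairing_stats(calls, lib, freq_mode="uniform")
            assert st["chance"] == pytest.approx(1.0 / (2 * n_pairs - 1))

    def test_all_matched_observed_one(self):
        calls, lib, _ = gen_guide_assignments(GuideSimParams(
            n_pairs=3, n_cells=100, co_detection_rate=1.0,
            cross_contamination_rate=0.0, seed=4))
        st = pairing_stats(calls, lib)
        assert st["observed"] == 1.0

    def test_chance_formula_matches_monte_carlo(self):
        rng = np.random.default_rng(5)
        n_pairs = 4
        lib = guide_library(n_pairs)
        f = rng.dirichlet(np.ones(2 * n_pairs))
        # two-guide cells made of two independent draws (conditioned on
        # being distinct): matched fraction should equal the chance formula
        n = 40_000
        draws = rng.choice(2 * n_pairs, size=(n, 2), p=f)
        distinct = draws[draws[:, 0] != draws[:, 1]]
        vec = lib["vector"].to_numpy()
        matched = vec[distinct[:, 0]] == vec[distinct[:, 1]]
        mc = matched.mean()
        mc_se = math.sqrt(mc * (1 - mc) / len(distinct))
        calls = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(3000)],
            "guides": [[lib["guide"][int(i)]] for i in
                       rng.choice(2 * n_pairs, size=3000, p=f)]})
        st = pairing_stats(calls, lib)
        assert abs(st["chance"] - mc) < max(3 * mc_se, 0.02)


class TestAggregation:
    def test_pseudobulk_sums(self):
        meta = pd.DataFrame({"unit_id": ["c1", "c2"], "sample_id": ["s1", "s1"]}
                            ).set_index("unit_id")
        counts = pd.DataFrame([[1, 3], [2, 4]], index=["g1", "g2"],
                              columns=["c1", "c2"])
        m = CountMatrix(counts=counts, unit_meta=meta)
        pb = pseudobulk(m, by="sample_id")
        assert list(pb.counts["s1"]) == [4, 6]
        assert pb.unit_meta.loc["s1", "n_cells"] == 2

    def test_pseudobulk_identity_when_one_cell_per_sample(self):
        meta = pd.DataFrame({"unit_id": ["c1", "c2"],
                             "sample_id": ["s1", "s2"]}).set_index("unit_id")
        counts = pd.DataFrame([[1, 3]], index=["g1"], columns=["c1", "c2"])
        pb = pseudobulk(CountMatrix(counts=counts, unit_meta=meta), "sample_id")
        assert list(pb.counts.loc["g1"]) == [1, 3]

    def test_filter_genes_rules(self):
        meta = pd.DataFrame({"unit_id": list("abc")}).set_index("unit_id")
        counts = pd.DataFrame([[10, 10, 0], [9, 100, 0], [1, 1, 1]],
                              index=["keep", "drop", "low"],
                              columns=list("abc"))
        m = CountMatrix(counts=counts, unit_meta=meta)
        out = filter_genes(m, min_count=10, min_units=2)
        assert list(out.counts.index) == ["keep"]
        assert out.counts.attrs["n_removed"] == 2

    def test_filter_min_count_zero_identity(self):
        meta = pd.DataFrame({"unit_id": list("ab")}).set_index("unit_id")
        counts = pd.DataFrame([[0, 0]], index=["g"], columns=list("ab"))
        out = filter_genes(CountMatrix(counts=counts, unit_meta=meta),
                           min_count=0, min_units=1)
        assert len(out.counts) == 1

    def test_size_factors_scaling(self):
        meta = pd.DataFrame({"unit_id": ["a", "b"]}).set_index("unit_id")
        rng = np.random.default_rng(6)
        base = rng.integers(5, 50, size=30)
        counts = pd.DataFrame({"a": base, "b": 2 * base},
                              index=[f"g{i}" for i in range(30)])
        sf = size_factors(CountMatrix(counts=counts, unit_meta=meta))
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_size_factors_identical_units_equal(self):
        meta = pd.DataFrame({"unit_id": ["a", "b", "c"]}).set_index("unit_id")
        counts = pd.DataFrame(np.tile([[5], [10], [7]], 3),
                              index=["g1", "g2", "g3"], columns=list("abc"))
        sf = size_factors(CountMatrix(counts=counts, unit_meta=meta))
        assert sf.nunique() == 1

    def test_size_factors_single_unit_is_one(self):
        meta = pd.DataFrame({"unit_id": ["a"]}).set_index("unit_id")
        counts = pd.DataFrame({"a": [3, 6, 9]}, index=["g1", "g2", "g3"])
        sf = size_factors(CountMatrix(counts=counts, unit_meta=meta))
        assert sf["a"] == pytest.approx(1.0)

    def test_size_factors_no_common_gene_errors(self):
        meta = pd.DataFrame({"unit_id": ["a", "b"]}).set_index("unit_id")
        counts = pd.DataFrame([[1, 0], [0, 1]], index=["g1", "g2"],
                              columns=list("ab"))
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(CountMatrix(counts=counts, unit_meta=meta))

    def test_mtx_round_trip(self, tmp_path):
        cm, _ = gen_counts(CountSimParams(n_genes=20, groups={"a": 3}, seed=7))
        cm.write_mtx(str(tmp_path / "m"))
        back = CountMatrix.read_mtx(str(tmp_path / "m"))
        np.testing.assert_array_equal(back.counts.to_numpy(),
                                      cm.counts.to_numpy())


class TestNBGLMDE:
    def test_lfc_recovery(self):
        lfc = np.zeros((200, 2))
        lfc[:10, 1] = 1.0
        cm, _ = gen_counts(CountSimParams(
            n_genes=200, groups={"control": 6, "pert": 6}, true_log2fc=lfc,
            dispersion=0.05, baseline_mean=100.0, seed=8))
        de = nb_glm_de(cm, ref_level="control").set_index("gene")
        hits = de.iloc[:10]
        assert abs(hits["log2fc"].mean() - 1.0) < 0.2
        assert (hits["p"] < 0.05).mean() > 0.8
        assert (de.iloc[10:]["p"] < 0.05).mean() < 0.15

    def test_constant_perturbation_errors(self):
        cm, _ = gen_counts(CountSimParams(n_genes=5, groups={"only": 4}, seed=9))
        with pytest.raises(ValueError, match="contrast not estimable"):
            nb_glm_de(cm, ref_level="only")

    def test_dispersion_estimated_near_truth(self):
        cm, _ = gen_counts(CountSimParams(
            n_genes=50, groups={"control": 30, "pert": 30}, dispersion=0.2,
            baseline_mean=200.0, seed=10))
        de = nb_glm_de(cm, ref_level="control")
        assert np.nanmedian(de["dispersion"]) == pytest.approx(0.2, abs=0.08)

    def test_matches_statsmodels_negative_binomial(self):
        """Single-gene cross-check against an independent NB2 MLE route."""
        import statsmodels.api as sm

        cm, _ = gen_counts(CountSimParams(
            n_genes=1, groups={"control": 40, "pert": 40},
            true_log2fc=np.array([[0.0, 0.7]]), dispersion=0.15,
            baseline_mean=80.0, seed=11))
        # unit size factors: with one gene the offset would absorb the effect
        ones = pd.Series(1.0, index=cm.counts.columns)
        de = nb_glm_de(cm, ref_level="control", factors=ones)
        y = cm.counts.to_numpy(float)[0]
        X = np.column_stack([np.ones(80),
                             (cm.unit_meta["group"] == "pert").to_numpy(float)])
        nb = sm.NegativeBinomial(y, X).fit(disp=0)
        assert de["log2fc"].iloc[0] * math.log(2) == pytest.approx(
            nb.params[1], abs=0.02)

    def test_min_cells_gate(self):
        cm, _ = gen_counts(CountSimParams(
            n_genes=10, groups={"control": 30, "big": 30, "small": 5},
            level="cell", seed=12))
        de = nb_glm_de(cm, ref_level="control", min_cells_per_pert=10)
        assert set(de["contrast"]) == {"big vs control"}


class TestSignatures:
    def _tables(self, rows):
        early = pd.DataFrame(
            {"effect": [r[0] for r in rows], "p_adj": [r[1] for r in rows],
             "p": [r[1] for r in rows]},
            index=[f"g{i}" for i in range(len(rows))])
        late = pd.DataFrame(
            {"effect": [r[2] for r in rows], "p_adj": 1.0, "p": 1.0},
            index=early.index)
        return early, late

    def test_threshold_classes(self):
        early, late = self._tables([
            (0.5, 0.01, 0.4),    # Progressing
            (0.5, 0.2, 0.4),     # ineligible (p_adj)
            (0.5, 0.01, -0.5),   # Transient
            (0.5, 0.01, 0.0),    # Stabilizing
            (0.2, 0.01, 0.4),    # ineligible (early lfc)
            (0.5, 0.01, 0.3),    # exact boundary -> no class
        ])
        out = classify_signatures(early, late)
        assert list(out["class"]) == ["Progressing", "Ineligible", "Transient",
                                      "Stabilizing", "Ineligible", "Boundary"]

    def test_eligible_classes_partition(self):
        rng = np.random.default_rng(13)
        early, late = self._tables(
            [(0.6, 0.01, float(rng.normal(0, 0.5))) for _ in range(50)])
        out = classify_signatures(early, late)
        eligible = out[out["eligible"]]
        assert set(eligible["class"]) <= {"Progressing", "Stabilizing",
                                          "Transient", "Boundary"}
        assert len(eligible) == 50


class TestTrajectories:
    def test_scale_to_reference_arithmetic(self):
        expr = pd.DataFrame({"P10_s": [2.0], "P14_s": [4.0], "P28_s": [6.0]},
                            index=["g"])
        ages = pd.Series({"P10_s": "P10", "P14_s": "P14", "P28_s": "P28"})
        out = scale_to_reference(expr, ages)
        np.testing.assert_allclose(out.loc["g"], [-1.0, 0.0, 1.0])

    def test_zero_sd_missing_with_warning(self):
        expr = pd.DataFrame({"a": [1.0], "b": [1.0]}, index=["g"])
        ages = pd.Series({"a": "P14", "b": "P28"})
        with pytest.warns(UserWarning, match="zero SD"):
            out = scale_to_reference(expr, ages)
        assert out.isna().all().all()

    def test_per_gene_sds_used(self):
        expr = pd.DataFrame({"a": [0.0, 0.0], "b": [2.0, 20.0]},
                            index=["g1", "g2"])
        ages = pd.Series({"a": "P14", "b": "P28"})
        out = scale_to_reference(expr, ages)
        assert out.loc["g1", "b"] == pytest.approx(out.loc["g2", "b"])

    def test_loess_exact_on_line(self):
        x = np.linspace(0, 10, 20)
        y = 2.0 * x + 1.0
        fit = smooth_trajectory(x, y, span=0.3, grid=x)
        np.testing.assert_allclose(fit["fitted"], y, atol=1e-8)

    def test_loess_constant_data(self):
        x = np.arange(10.0)
        fit = smooth_trajectory(x, np.full(10, 3.0), span=0.5)
        np.testing.assert_allclose(fit["fitted"], 3.0, atol=1e-10)

    def test_large_span_approaches_ols(self):
        rng = np.random.default_rng(14)
        x = np.arange(12.0)
        y = 0.5 * x + rng.normal(0, 0.3, 12)
        b, a = np.polyfit(x, y, 1)
        fit = smooth_trajectory(x, y, span=200.0, grid=x)
        np.testing.assert_allclose(fit["fitted"], a + b * x, atol=1e-3)


class TestEnrichment:
    def test_matches_hypergeometric_enumeration(self):
        # 2x2 table a=5 b=5 c=5 d=85: one-sided tail by explicit enumeration
        universe = {f"g{i}" for i in range(100)}
        sig = {f"g{i}" for i in range(10)}
        risk = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        out = fisher_enrichment({"s": sig}, {"r": risk}, universe)
        a = out.loc[0, "a"]
        # hypergeometric: draw |sig| from universe, count >= a overlaps
        p_manual = sum(sps.hypergeom.pmf(k, 100, len(risk), len(sig))
                       for k in range(a, min(len(risk), len(sig)) + 1))
        assert out.loc[0, "p"] == pytest.approx(p_manual, rel=1e-9)

    def test_risk_set_equals_universe_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        out = fisher_enrichment({"s": set(list(universe)[:5])},
                                {"r": universe}, universe)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_overlap_near_one(self):
        universe = {f"g{i}" for i in range(100)}
        sig = {f"g{i}" for i in range(30)}
        risk = {f"g{i}" for i in range(60, 90)}
        out = fisher_enrichment({"s": sig}, {"r": risk}, universe)
        assert out.loc[0, "p"] > 0.99


class TestSignConcordance:
    def _table(self, effects, p=0.001):
        return pd.DataFrame({"effect": effects, "p": p, "p_adj": p},
                            index=[f"g{i}" for i in range(len(effects))])

    def test_identical_tables(self):
        t = self._table([1.0, -2.0, 0.5, 3.0])
        res = sign_concordance(t, t)
        assert res.concordance == 1.0
        assert res.pearson_r == pytest.approx(1.0)

    def test_sign_flipped_tables(self):
        t = self._table([1.0, -2.0, 0.5, 3.0])
        t2 = t.copy()
        t2["effect"] *= -1
        res = sign_concordance(t, t2)
        assert res.concordance == 0.0
        assert res.pearson_r == pytest.approx(-1.0)

    def test_hand_counted_fraction(self):
        rng = np.random.default_rng(15)
        e = rng.normal(size=10) + 2.0        # all positive signs
        a = self._table(list(e))
        b = self._table(list(e))
        b.iloc[0, b.columns.get_loc("effect")] = -1.0   # one mismatch
        res = sign_concordance(a, b)
        assert res.concordance == pytest.approx(0.9)

    def test_shared_sets_respect_thresholds(self):
        a = self._table([1.0, 1.0, 1.0])
        b = self._table([1.0, 1.0, 1.0])
        a.loc["g0", "p_adj"] = 0.5           # drops g0 from shared-FDR only
        res = sign_concordance(a, b)
        assert "g0" in res.shared_nominal
        assert "g0" not in res.shared_fdr
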