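"""Regression gating, below/above-line selection, set summaries."""
import numpy as np
import pandas as pd
import pytest

from sofdex import diffexpr
from sofdex.classify import (RegressionLine, assemble_labels,
                             fold_change_pairs, mann_whitney, mcd_outliers,
                             regression_fit, select_constitutive_sets,
                             select_sof_3h_rep, select_sof_dexdep,
                             zscore_abundance)


def _pairs(x, y, padj_sof=0.01, padj_ctrl=0.01):
    n = len(x)
    as_arr = lambda v: np.full(n, v) if np.isscalar(v) else np.asarray(v)
    return pd.DataFrame({
        "log2FC_sof": x, "padj_sof": as_arr(padj_sof),
        "log2FC_ctrl": y, "padj_ctrl": as_arr(padj_ctrl),
    }, index=[f"g{i}" for i in range(n)])


class TestRegressionFit:
    def test_exact_line_recovered(self):
        x = np.linspace(-2, 3, 20)
        line = regression_fit(_pairs(x, 2 * x + 1))
        assert line.slope == pytest.approx(2.0, abs=1e-10)
        assert line.intercept == pytest.approx(1.0, abs=1e-10)
        assert line.n_genes_used == 20

    def test_gating_excludes_nonsignificant_points(self):
        x = np.linspace(0, 4, 10)
        pairs = _pairs(np.concatenate([x, [10.0]]),
                       np.concatenate([2 * x + 1, [-50.0]]),
                       padj_sof=np.r_[np.full(10, 0.01), 0.9],
                       padj_ctrl=np.r_[np.full(10, 0.01), 0.9])
        line = regression_fit(pairs)
        assert line.slope == pytest.approx(2.0, abs=1e-10)
        assert line.n_genes_used == 10

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = 1.3 * x - 0.4 + rng.normal(0, 0.3, 200)
        line = regression_fit(_pairs(x, y))
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert line.slope == pytest.approx(beta[0], abs=1e-10)
        assert line.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_too_few_gated_genes_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            regression_fit(_pairs([1, 2], [1, 2]))


class TestSelectionRules:
    line = RegressionLine(slope=1.0, intercept=0.0, n_genes_used=10)

    def test_outlier_above_line_excluded_from_dexdep(self):
        pairs = _pairs([2.0, 2.0], [0.5, 3.5])   # below, above
        got = select_sof_dexdep(pairs, self.line, [True, True], 0.05)
        assert got == ["g0"]

    def test_nonsignificant_outlier_excluded(self):
        pairs = _pairs([2.0], [0.5], padj_sof=0.2, padj_ctrl=0.2)
        assert select_sof_dexdep(pairs, self.line, [True], 0.05) == []

    def test_non_outlier_excluded(self):
        pairs = _pairs([2.0], [0.5])
        assert select_sof_dexdep(pairs, self.line, [False], 0.05) == []

    def test_3h_rep_mirrors_dexdep(self):
        pairs = _pairs([2.0, 2.0], [0.5, 3.5])
        got = select_sof_3h_rep(pairs, self.line, [True, True], 0.05)
        assert got == ["g1"]

    def test_3h_rep_threshold_mode_drops_outlier_requirement(self):
        pairs = _pairs([2.0], [3.5])
        assert select_sof_3h_rep(pairs, self.line, [False], 0.05) == []
        assert select_sof_3h_rep(pairs, self.line, [False], 0.05,
                                 method="threshold") == ["g0"]

    def test_mirrored_planted_set_recovered_by_3h_rep(self, default_sim,
                                                      default_params):
        """Swapping the SoF/Ctrl axes turns the planted amplified set into
        an above-line set that select_sof_3h_rep recovers."""
        genome, truth, counts, design = default_sim
        sf = diffexpr.median_of_ratios(counts)
        disp = diffexpr.estimate_dispersion(counts, design, size_factors=sf)
        de = {g: diffexpr.nb_wald_test(
            counts, design, diffexpr.time_contrast(design, g, 3),
            size_factors=sf, dispersions=disp) for g in ("SoF", "Ctrl")}
        pairs = fold_change_pairs(de["SoF"], de["Ctrl"])
        mirrored = pairs.rename(columns={
            "log2FC_sof": "log2FC_ctrl", "log2FC_ctrl": "log2FC_sof",
            "padj_sof": "padj_ctrl", "padj_ctrl": "padj_sof"})
        gate = (mirrored["padj_sof"] < 0.05).fillna(False) | \
               (mirrored["padj_ctrl"] < 0.05).fillna(False)
        gated = mirrored.loc[gate]
        line = regression_fit(mirrored)
        mcd = mcd_outliers(gated[["log2FC_sof", "log2FC_ctrl"]].to_numpy(),
                           random_state=0)
        got = select_sof_3h_rep(gated, line, mcd.outliers, 0.05)
        planted = set(truth.genes_in_class("sof_dexdep"))
        sens = len(set(got) & planted) / len(planted)
        assert sens >= 0.8


class TestConstitutiveSets:
    def _deres(self, gene_ids, lfc, padj):
        table = pd.DataFrame({
            "baseMean": 100.0, "log2FoldChange": lfc, "lfcSE": 0.1,
            "pvalue": padj, "padj": padj, "excluded": False,
        }, index=gene_ids)
        return diffexpr.DEResult("SoF_vs_wt", table)

    def test_up_and_down_split(self):
        res = self._deres(["a", "b", "c"], [1.5, -1.5, 0.2],
                          [0.001, 0.001, 0.8])
        dexind, const_rep = select_constitutive_sets(res, 0.05)
        assert dexind == ["a"] and const_rep == ["b"]

    def test_dexdep_claim_takes_priority(self):
        res = self._deres(["a", "b"], [1.5, 1.5], [0.001, 0.001])
        dexind, _ = select_constitutive_sets(res, 0.05, exclude=["a"])
        assert dexind == ["b"]

    def test_strictness_flag_requires_quiet_wt_response(self):
        res = self._deres(["a", "b"], [1.5, 1.5], [0.001, 0.001])
        wt = self._deres(["a", "b"], [2.0, 0.0], [0.001, 0.9])
        dexind, _ = select_constitutive_sets(res, 0.05, wt_dex_response=wt)
        assert dexind == ["b"]   # "a" responds to dex in wt

    def test_planted_dexind_recovered(self, default_sim):
        genome, truth, counts, design = default_sim
        sf = diffexpr.median_of_ratios(counts)
        res = diffexpr.nb_wald_test(
            counts, design, diffexpr.genotype_contrast(design, "SoF"),
            size_factors=sf, name="SoF_vs_wt")
        dexind, const_rep = select_constitutive_sets(res, 0.05)
        planted = set(truth.genes_in_class("sof_dexind"))
        sens = len(set(dexind) & planted) / len(planted)
        assert sens >= 0.8
        planted_rep = set(truth.genes_in_class("sof_const_rep"))
        assert len(set(const_rep) & planted_rep) / len(planted_rep) >= 0.8

    def test_assembled_labels_are_exclusive(self):
        labels = assemble_labels(["a", "b", "c", "d"], ["a"], ["a", "b"],
                                 ["b", "c"], ["c", "d"])
        assert labels.tolist() == ["sof_dexdep", "sof_3h_rep", "sof_dexind",
                                   "sof_const_rep"]


class TestZscoreAbundance:
    def test_constant_gene_gets_zero_by_convention(self):
        counts = pd.DataFrame(
            {f"wt_t{t}_r1": [10] for t in range(4)} |
            {f"wt_t{t}_r2": [10] for t in range(4)},
            index=["g0"])
        design = pd.DataFrame([
            {"sample_id": f"wt_t{t}_r{r}", "genotype": "wt",
             "treatment": "dex", "time": t, "replicate": r}
            for t in range(4) for r in (1, 2)])
        z = zscore_abundance(counts, design, ["g0"],
                             size_factors=pd.Series(1.0, index=counts.columns))
        assert (z.to_numpy() == 0).all()

    def test_two_point_series_gives_plus_minus_sqrt_half(self):
        counts = pd.DataFrame({"wt_t0_r1": [4], "wt_t1_r1": [8]}, index=["g0"])
        design = pd.DataFrame([
            {"sample_id": "wt_t0_r1", "genotype": "wt", "treatment": "ethanol",
             "time": 0, "replicate": 1},
            {"sample_id": "wt_t1_r1", "genotype": "wt", "treatment": "dex",
             "time": 1, "replicate": 1}])
        z = zscore_abundance(counts, design, ["g0"],
                             size_factors=pd.Series(1.0, index=counts.columns))
        np.testing.assert_allclose(z.to_numpy().ravel(),
                                   [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12)

    def test_zscores_sum_to_zero_per_genotype(self, default_sim):
        genome, truth, counts, design = default_sim
        genes = truth.genes_in_class("sof_dexdep")[:10]
        z = zscore_abundance(counts, design, genes)
        for geno in ("wt", "SoF", "Ctrl"):
            np.testing.assert_allclose(z[geno].sum(axis=1), 0.0, atol=1e-9)


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([5, 5, 5], [5, 5, 5])
        assert p == pytest.approx(1.0)

    def test_asymptotic_close_to_exact_at_moderate_n(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.8, 1, 15)
        from scipy import stats
        exact = stats.mannwhitneyu(a, b, method="exact").pvalue
        asym = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
        _, ours = mann_whitney(a, b)   # n <= 20, tie-free -> exact path
        assert ours == pytest.approx(exact, abs=1e-12)
        assert abs(asym - exact) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
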