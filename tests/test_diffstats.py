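"""Differential statistics: moderated t, BH-FDR, summary ANOVA, chi-square."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import salivamics as sm
from conftest import make_imputed


def null_matrix(n_features=500, n1=40, n2=40, seed=42):
    rng = np.random.default_rng(seed)
    mat = make_imputed(rng.standard_normal((n_features, n1 + n2)))
    labels = pd.Series(["CN"] * n1 + ["AD"] * n2, index=mat.sample_ids)
    return mat, labels


class TestModeratedTTest:
    def test_no_moderation_limit_equals_pooled_t(self):
        mat, labels = null_matrix(200, seed=1)
        de = sm.moderated_ttest(mat, labels, ("CN", "AD"), d0_override=0)
        values = mat.values.to_numpy()
        t, p = stats.ttest_ind(values[:, 40:], values[:, :40], axis=1)
        assert np.allclose(de["t_mod"], t, atol=1e-12)
        assert np.allclose(de["p"], p, atol=1e-12)

    def test_null_pvalues_uniform(self):
        mat, labels = null_matrix(seed=42)
        de = sm.moderated_ttest(mat, labels, ("CN", "AD"))
        assert stats.kstest(de["p"], "uniform").pvalue > 0.01
        assert abs((de["p"] < 0.05).mean() - 0.05) <= 0.02

    def test_planted_feature_attains_smallest_p(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((200, 80))
            x[0, 40:] += 1.0
            mat = make_imputed(x)
            labels = pd.Series(["CN"] * 40 + ["AD"] * 40, index=mat.sample_ids)
            de = sm.moderated_ttest(mat, labels, ("CN", "AD"))
            hits += de.loc[de["p"].idxmin(), "feature_id"] == "F000"
        # a 1-SD shift gives t ~ 4.5 while the null max-|t| over 199
        # features is ~3.5, so the planted feature wins in ~92% of runs
        assert hits >= 90

    def test_one_vs_all_contrast_combines_cases(self, imputed_protein):
        mat, metadata = imputed_protein
        de = sm.moderated_ttest(mat, metadata["diagnosis"], ("CN", "MCI+AD"))
        assert (de["contrast"] == "CN-MCI+AD").all()
        assert len(de) == mat.n_features
        assert ((de["fdr"] >= de["p"] - 1e-12)).all()

    def test_sign_convention_higher_in_second_group(self):
        x = np.zeros((1, 20))
        x[0, 10:] = 1.0
        x += np.random.default_rng(0).normal(0, 0.01, x.shape)
        mat = make_imputed(x)
        labels = pd.Series(["CN"] * 10 + ["AD"] * 10, index=mat.sample_ids)
        de = sm.moderated_ttest(mat, labels, ("CN", "AD"))
        assert de["log2fc"].iloc[0] > 0
        flipped = sm.moderated_ttest(mat, labels, ("AD", "CN"))
        assert np.allclose(flipped["log2fc"], -de["log2fc"])

    def test_missing_group_errors(self):
        mat, labels = null_matrix(10, seed=0)
        with pytest.raises(ValueError, match="MCI"):
            sm.moderated_ttest(mat, labels, ("CN", "MCI"))

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_matches_limma_reference(self, tmp_path):
        """Independent oracle: Bioconductor limma on the same fixture."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((50, 16)) * rng.uniform(0.5, 2, size=(50, 1))
        x[:5, 8:] += 1.5
        mat = make_imputed(x)
        labels = pd.Series(["CN"] * 8 + ["AD"] * 8, index=mat.sample_ids)
        de = sm.moderated_ttest(mat, labels, ("CN", "AD"))
        mat.values.to_csv(tmp_path / "mat.tsv", sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{tmp_path}/mat.tsv", row.names=1))\n'
            'design <- cbind(Intercept=1, AD=c(rep(0,8), rep(1,8)))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'write.csv(data.frame(t=fit$t[,"AD"], p=fit$p.value[,"AD"]),'
            f' "{tmp_path}/limma.csv")\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        assert np.allclose(de["t_mod"], ref["t"], atol=1e-8)
        assert np.allclose(de["p"], ref["p"], atol=1e-8)


class TestBHAdjust:
    def test_hand_computed_example(self):
        assert np.allclose(sm.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        assert sm.bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(sm.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sm.bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariant_and_matches_statsmodels(self, pvals, rnd):
        from statsmodels.stats.multitest import multipletests
        p = np.array(pvals)
        adjusted = sm.bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adjusted, ref, atol=1e-12)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        assert np.allclose(sm.bh_adjust(p[perm]), adjusted[perm], atol=1e-12)


class TestAnovaFromSummary:
    def test_serum_b12_row_reproduces(self):
        summary = sm.GroupSummary(("CN", "MCI", "AD"),
                                  (303.1, 392.9, 395.6),
                                  (91.3, 186.0, 120.5), (40, 20, 20))
        _, p = sm.anova_from_summary(summary)
        assert round(p, 3) == 0.008

    def test_equal_means_give_f_zero(self):
        summary = sm.GroupSummary(("a", "b"), (5.0, 5.0), (1.0, 2.0), (10, 12))
        f, p = sm.anova_from_summary(summary)
        assert f == 0.0 and p == 1.0

    def test_two_groups_equals_t_squared(self):
        summary = sm.GroupSummary(("a", "b"), (1.0, 2.5), (1.1, 0.9), (12, 15))
        f, p_f = sm.anova_from_summary(summary)
        # pooled-variance t from the same summaries
        sp2 = (11 * 1.1**2 + 14 * 0.9**2) / 25
        t = (2.5 - 1.0) / np.sqrt(sp2 * (1 / 12 + 1 / 15))
        assert f == pytest.approx(t**2, rel=1e-12)
        assert p_f == pytest.approx(2 * stats.t.sf(abs(t), 25), rel=1e-12)

    def test_agrees_with_raw_data_anova(self):
        # construct data realizing the summaries exactly, compare to scipy
        rng = np.random.default_rng(8)
        groups, means, sds, ns = ("x", "y", "z"), (3.0, 4.5, 2.2), (1.0, 2.0, 0.7), (9, 14, 11)
        data = []
        for m, s, n in zip(means, sds, ns):
            v = rng.standard_normal(n)
            v = (v - v.mean()) / v.std(ddof=1) * s + m
            data.append(v)
        f_ref, p_ref = stats.f_oneway(*data)
        f, p = sm.anova_from_summary(sm.GroupSummary(groups, means, sds, ns))
        assert f == pytest.approx(f_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            sm.anova_from_summary(
                sm.GroupSummary(("a", "b"), (1.0, 2.0), (1.0, 1.0), (1, 5)))


class TestChisqFromCounts:
    def test_sex_row_reproduces(self):
        table = [[21, 9, 12], [19, 11, 8]]
        _, p = sm.chisq_from_counts(table)
        assert round(p, 3) == 0.637

    def test_apoe4_row_reproduces(self):
        table = [[6, 11, 10], [34, 9, 10]]
        _, p = sm.chisq_from_counts(table)
        assert round(p, 3) == 0.002

    def test_two_df_closed_form(self):
        chi2, p = sm.chisq_from_counts([[10, 20, 30], [15, 12, 9]])
        assert p == pytest.approx(np.exp(-chi2 / 2), abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sm.chisq_from_counts([[0, 5], [0, 7]])
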