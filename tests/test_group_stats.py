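import subprocess
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tmephenotyper.group_stats import (
    bh_adjust,
    chi_squared,
    cn_burden,
    kruskal_wallis,
    moderated_ttest,
    spearman_corr,
    tmb_per_sample,
    wilcoxon_ranksum,
)
from tmephenotyper.io_formats import (
    CopyNumberTable,
    ExpressionMatrix,
    MutationTable,
)


def _em(arr):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        ),
        scale="log2",
    )


class TestModeratedT:
    def test_d0_zero_is_ordinary_pooled_t(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(50, 12))
        groups = ["a"] * 6 + ["b"] * 6
        res = moderated_ttest(_em(arr), groups, d0s0=(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind(arr[:, :6], arr[:, 6:], axis=1)
        np.testing.assert_allclose(res.table["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res.table["p"], p_ref, atol=1e-10)

    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(30, 10))
        groups = ["a"] * 5 + ["b"] * 5
        s0 = 1.7
        res = moderated_ttest(_em(arr), groups, d0s0=(np.inf, s0))
        logfc = arr[:, :5].mean(axis=1) - arr[:, 5:].mean(axis=1)
        expected = logfc / (np.sqrt(s0) * np.sqrt(2 / 5))
        np.testing.assert_allclose(res.table["t"], expected, atol=1e-10)

    def test_moderation_continuous_in_d0(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(40, 10))
        groups = ["a"] * 5 + ["b"] * 5
        t_tiny = moderated_ttest(_em(arr), groups, d0s0=(1e-9, 1.0)).table["t"]
        t_zero = moderated_ttest(_em(arr), groups, d0s0=(0.0, 1.0)).table["t"]
        np.testing.assert_allclose(t_tiny, t_zero, rtol=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            moderated_ttest(_em(np.ones((3, 3))), ["a", "b", "b"])

    def test_matches_limma_reference(self, tmp_path):
        """Estimated prior (d0, s0^2) and moderated t/p agree with
        Bioconductor limma lmFit+eBayes on a small fixture."""
        rng = np.random.default_rng(7)
        arr = rng.normal(8, 1, size=(120, 14)) * rng.uniform(0.5, 2, (120, 1))
        arr[:15, :6] += 2
        m = _em(arr)
        (tmp_path / "in.tsv").write_text(m.values.to_csv(sep="\t"))
        script = tmp_path / "limma.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"x <- as.matrix(read.table('{tmp_path}/in.tsv', sep='\\t', "
            "header=TRUE, row.names=1))\n"
            "grp <- factor(c(rep('a',6), rep('b',8)), levels=c('b','a'))\n"
            "fit <- eBayes(lmFit(x, model.matrix(~grp)))\n"
            "out <- topTable(fit, coef=2, number=Inf, sort.by='none')\n"
            f"write.table(out[,c('logFC','t','P.Value')], "
            f"'{tmp_path}/out.tsv', sep='\\t', quote=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        res = moderated_ttest(m, ["a"] * 6 + ["b"] * 8)
        np.testing.assert_allclose(res.table["logfc"], ref["logFC"], atol=1e-10)
        np.testing.assert_allclose(res.table["t"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(res.table["p"], ref["P.Value"], atol=1e-10)

    def test_de_flag_applies_both_filters(self):
        rng = np.random.default_rng(8)
        arr = rng.normal(size=(100, 20))
        arr[0, :10] += 3.0  # big shift, significant
        arr[1, :10] += 0.5  # sub-threshold logFC
        res = moderated_ttest(_em(arr), ["a"] * 10 + ["b"] * 10)
        assert res.table.loc["g0", "significant"]
        assert not res.table.loc["g1", "significant"]
        assert (res.table["p_adj"] >= res.table["p"] - 1e-15).all()


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_inputs_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(bh_adjust([0.07]), [0.07])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    def test_matches_statsmodels_oracle(self, p):
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestRankTests:
    def test_kruskal_matches_scipy_and_guards(self):
        h, p = kruskal_wallis(
            np.array([1.0, 2, 3, 4, 5, 6]), np.array(["a"] * 3 + ["b"] * 3)
        )
        h_ref, p_ref = stats.kruskal([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(h_ref) and p == pytest.approx(p_ref)
        h0, p0 = kruskal_wallis(np.ones(6), np.array(["a"] * 3 + ["b"] * 3))
        assert h0 == 0.0 and p0 == 1.0
        with pytest.raises(ValueError):
            kruskal_wallis(np.array([1.0, 2.0]), np.array(["a", "a"]))

    def test_wilcoxon_extreme_separation(self):
        u, p = wilcoxon_ranksum(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert u == 0.0

    def test_wilcoxon_identical_groups_exact_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        u, p = wilcoxon_ranksum(a, a.copy())
        assert p == pytest.approx(1.0)

    def test_wilcoxon_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            u_obs, p_obs = wilcoxon_ranksum(a, b)
            pooled = np.concatenate([a, b])
            ranks = stats.rankdata(pooled)
            mu = len(a) * len(b) / 2
            dev = abs(u_obs - mu)
            hits = total = 0
            for idx in combinations(range(11), 5):
                u = ranks[list(idx)].sum() - 5 * 6 / 2
                total += 1
                hits += abs(u - mu) >= dev - 1e-12
            assert p_obs == pytest.approx(hits / total)

    def test_wilcoxon_large_sample_normal_approx(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=40), rng.normal(0.8, 1, size=40)
        u, p = wilcoxon_ranksum(a, b)
        ref = stats.mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum(np.array([]), np.array([1.0]))


class TestChiSquaredAndSpearman:
    def test_balanced_table_null(self):
        stat, df, p = chi_squared(np.array([[10, 10], [10, 10]]))
        assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_hand_formula(self):
        table = np.array([[20, 5], [5, 20]])
        expected = table.sum(axis=1)[:, None] * table.sum(axis=0) / table.sum()
        stat_hand = ((table - expected) ** 2 / expected).sum()
        stat, df, p = chi_squared(table)
        assert stat == pytest.approx(stat_hand)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared(np.array([[0, 0], [5, 5]]))

    def test_spearman_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_corr(x, x**3)[0] == pytest.approx(1.0)
        assert spearman_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_spearman_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr(np.ones(5), np.arange(5.0))

    def test_rank_tests_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=20), rng.normal(size=25)
        u1, p1 = wilcoxon_ranksum(a, b)
        u2, p2 = wilcoxon_ranksum(np.exp(a), np.exp(b))
        assert u1 == u2 and p1 == pytest.approx(p2)
        rho1, _ = spearman_corr(a, b[:20])
        rho2, _ = spearman_corr(np.exp(a), b[:20] ** 3)
        assert rho1 == pytest.approx(rho2)


class TestBurdens:
    def test_tmb_counts_nonsynonymous_only(self):
        rec = pd.DataFrame(
            {
                "sample_id": ["s1"] * 5,
                "gene_id": list("abcde"),
                "variant_class": [
                    "Missense_Mutation", "Nonsense_Mutation",
                    "Frame_Shift_Del", "Silent", "Silent",
                ],
            }
        )
        tmb = tmb_per_sample(MutationTable(rec), ["s1", "s2"])
        assert tmb["s1"] == 3 and tmb["s2"] == 0

    def test_tmb_empty_table(self):
        empty = MutationTable(
            pd.DataFrame(columns=["sample_id", "gene_id", "variant_class"])
        )
        assert (tmb_per_sample(empty, ["s1", "s2"]) == 0).all()

    def test_unknown_class_excluded_with_warning(self, caplog):
        rec = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "gene_id": ["a", "b"],
                "variant_class": ["Missense_Mutation", "MadeUp"],
            }
        )
        with caplog.at_level("WARNING", logger="tmephenotyper"):
            tmb = tmb_per_sample(MutationTable(rec), ["s1"])
        assert tmb["s1"] == 1
        assert "unknown variant classes" in caplog.text

    def test_cn_burden_definitional(self):
        calls = pd.DataFrame(
            {"s1": [-2, -1, 0, 1, 2]}, index=[f"g{i}" for i in range(5)]
        )
        level = pd.Series(["focal"] * 3 + ["arm"] * 2, index=calls.index)
        b = cn_burden(CopyNumberTable(calls, level))
        assert b.loc["s1", "gain_total"] == 2
        assert b.loc["s1", "loss_total"] == 2
        assert b.loc["s1", "gain_focal"] == 0 and b.loc["s1", "gain_arm"] == 2
        assert b.loc["s1", "loss_focal"] == 2 and b.loc["s1", "loss_arm"] == 0

    def test_cn_burden_all_zero(self):
        calls = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        level = pd.Series(["focal", "arm"], index=calls.index)
        b = cn_burden(CopyNumberTable(calls, level))
        assert b.loc["s1"].sum() == 0
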