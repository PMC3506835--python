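"""Statistics kernel vs independent references and exhaustive oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crossde import de_stats as ds
from crossde.errors import FormatError
from crossde.io_config import GeneMatrix, StudyDesign


class TestWelch:
    def test_identical_groups(self):
        t, df, p = ds.welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_df_collapses_for_equal_n_and_variance(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 5.0  # same sample variance, same n
        _, df, _ = ds.welch_t(a, b)
        assert df == pytest.approx(len(a) + len(b) - 2)

    def test_fixed_example_matches_reference(self):
        a, b = (0.9, 1.1, 1.0), (2.0, 2.2, 1.8)
        t, df, p = ds.welch_t(a, b)
        ref = sps.ttest_ind(b, a, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
        assert df == pytest.approx(ref.df, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matches_reference(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 9))
        b = rng.normal(0.5, 2.0, size=rng.integers(2, 9))
        t, df, p = ds.welch_t(a, b)
        ref = sps.ttest_ind(b, a, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_label_swap_flips_t_keeps_p(self):
        a, b = [0.1, 0.4, 0.2], [1.0, 1.4, 0.9]
        ra = ds.welch_t(a, b)
        rb = ds.welch_t(b, a)
        assert ra.t_stat == pytest.approx(-rb.t_stat)
        assert ra.p == pytest.approx(rb.p)

    def test_zero_variance_branches(self):
        assert ds.welch_t([1, 1], [1, 1]).p == 1
        res = ds.welch_t([1, 1], [2, 2])
        assert 0 < res.p <= ds.TINY_P

    def test_too_few_values(self):
        with pytest.raises(FormatError):
            ds.welch_t([1.0], [1.0, 2.0])


class TestPairedT:
    def test_zero_mean_differences(self):
        t, df, p = ds.paired_t([0.5, -0.5])
        assert t == 0 and p == 1

    def test_constant_nonzero_differences_degenerate(self):
        res = ds.paired_t([1, 1, 1, 1])
        assert res.p == ds.TINY_P

    def test_fixed_example_matches_reference(self):
        d = (0.8, 1.2, 1.0, 0.6)
        t, df, p = ds.paired_t(d)
        ref = sps.ttest_1samp(d, 0.0)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
        assert df == len(d) - 1


class TestAnova:
    def test_identical_groups(self):
        f, p = ds.anova_oneway([[1, 2], [1, 2], [1, 2]])
        assert f == 0 and p == 1

    def test_two_groups_equals_pooled_t_squared(self):
        a, b = [0.2, 0.5, 0.3], [1.1, 0.8, 1.3]
        f, p = ds.anova_oneway([a, b])
        tref = sps.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(tref.statistic**2)
        assert p == pytest.approx(tref.pvalue)

    def test_fixed_example_matches_reference(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        f, p = ds.anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert ds.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_worked_triple(self):
        np.testing.assert_allclose(
            ds.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matches_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 200))
        mine = ds.bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=100)
        adj = ds.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(FormatError):
            ds.bh_adjust([0.5, 1.2])


class TestStoreyQ:
    def test_all_ones(self):
        q, pi0 = ds.storey_qvalues(np.ones(500))
        assert pi0 == pytest.approx(1.0)
        np.testing.assert_allclose(q, 1.0)

    def test_small_m_reduces_to_bh(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)  # below the smoother threshold: pi0 = 1
        q, pi0 = ds.storey_qvalues(p)
        assert pi0 == 1.0
        np.testing.assert_allclose(q, ds.bh_adjust(p), atol=1e-12)

    def test_q_never_exceeds_bh(self):
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.uniform(size=900), rng.beta(0.5, 8, size=100)])
        q, pi0 = ds.storey_qvalues(p)
        assert pi0 <= 1.0
        assert (q <= ds.bh_adjust(p) + 1e-12).all()

    def test_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=300)
        q, _ = ds.storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert ((0 <= q) & (q <= 1)).all()


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert ds.pearson_r(x, x)[0] == pytest.approx(1.0)
        assert ds.pearson_r(x, -2 * x)[0] == pytest.approx(-1.0)

    def test_fixed_instance_matches_reference(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, p = ds.pearson_r(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(FormatError):
            ds.pearson_r([1, 1, 1], [1, 2, 3])


def enumerate_fisher_p(a, b, c, d):
    """Exact two-sided Fisher p by integer hypergeometric enumeration."""
    n, r1, r2, c1 = a + b + c + d, a + b, c + d, a + c
    if 0 in (r1, r2, c1, b + d):
        return 1.0
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(kmin, kmax + 1)}
    obs = weights[a]
    total = sum(weights.values())
    return sum(w for w in weights.values() if w <= obs) / total


class TestFisherExact:
    def test_tiny_table(self):
        assert ds.fisher_exact_2x2(ds.ContingencyTable2x2(1, 0, 0, 1)) == 1.0

    def test_three_three_diagonal(self):
        p = ds.fisher_exact_2x2(ds.ContingencyTable2x2(3, 0, 0, 3))
        assert p == pytest.approx(0.1, rel=1e-7)

    def test_zero_margin_degenerate(self):
        assert ds.fisher_exact_2x2(ds.ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_exhaustive_small_tables(self):
        for n in range(1, 16):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        mine = ds.fisher_exact_2x2(ds.ContingencyTable2x2(a, b, c, d))
                        ref = enumerate_fisher_p(a, b, c, d)
                        assert mine == pytest.approx(ref, rel=1e-7), (a, b, c, d)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            a, b, c, d = rng.integers(0, 30, size=4)
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            p1 = ds.fisher_exact_2x2(ds.ContingencyTable2x2(a, b, c, d))
            p2 = ds.fisher_exact_2x2(ds.ContingencyTable2x2(a, c, b, d))
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_large_counts_stable(self):
        p = ds.fisher_exact_2x2(ds.ContingencyTable2x2(392, 87, 64, 300))
        ref = sps.fisher_exact([[392, 87], [64, 300]])[1]
        assert p == pytest.approx(ref, rel=1e-6)


def permutation_ranksum_p(in_ranks, out_ranks):
    """Two-sided rank-sum p by full subset enumeration (itertools)."""
    allr = list(in_ranks) + list(out_ranks)
    n1 = len(in_ranks)
    mu = n1 * sum(allr) / len(allr)
    obs = abs(sum(in_ranks) - mu)
    devs = [abs(sum(s) - mu) for s in itertools.combinations(allr, n1)]
    return sum(1 for v in devs if v >= obs - 1e-9) / len(devs)


class TestWilcoxonRank:
    def test_top_two_of_five(self):
        res = ds.wilcoxon_rank([1, 2], [3, 4, 5])
        assert res.tail == pytest.approx(0.1)
        assert res.p == pytest.approx(0.2)
        assert res.sign == 1

    def test_perfect_interleave_symmetric(self):
        res = ds.wilcoxon_rank([1, 4], [2, 3])
        assert res.p == pytest.approx(1.0)
        assert res.sign == 1  # mean-rank tie broken toward +1

    def test_exhaustive_small_lists(self):
        for n_tot in range(3, 9):
            ranks = list(range(1, n_tot + 1))
            for k in range(1, n_tot):
                for combo in itertools.combinations(range(n_tot), k):
                    rin = [ranks[i] for i in combo]
                    rout = [ranks[i] for i in range(n_tot) if i not in combo]
                    res = ds.wilcoxon_rank(rin, rout)
                    ref = permutation_ranksum_p(rin, rout)
                    assert res.p == pytest.approx(ref, abs=1e-12), (rin, rout)

    def test_tied_ranks_exact(self):
        # average ranks with ties: list (1.5, 1.5, 3, 4.5, 4.5, 6)
        rin, rout = [1.5, 1.5], [3.0, 4.5, 4.5, 6.0]
        res = ds.wilcoxon_rank(rin, rout)
        ref = permutation_ranksum_p(rin, rout)
        assert res.p == pytest.approx(ref, abs=1e-12)

    def test_reversal_flips_sign_keeps_p(self):
        rng = np.random.default_rng(10)
        ranks = np.arange(1, 15, dtype=float)
        sel = rng.choice(14, size=5, replace=False)
        rin = ranks[sel]
        rout = np.delete(ranks, sel)
        fwd = ds.wilcoxon_rank(rin, rout)
        rev = ds.wilcoxon_rank(15 - rin, 15 - rout)
        assert fwd.p == pytest.approx(rev.p, abs=1e-12)
        assert fwd.sign == -rev.sign

    def test_normal_approximation_reasonable(self):
        # large list: compare against scipy's Mann-Whitney normal path
        rng = np.random.default_rng(11)
        ranks = sps.rankdata(rng.normal(size=60))
        rin, rout = ranks[:20], ranks[20:]
        res = ds.wilcoxon_rank(rin, rout)
        ref = sps.mannwhitneyu(rin, rout, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(FormatError):
            ds.wilcoxon_rank([], [1, 2])


class TestGeneTables:
    @pytest.fixture
    def matrix_and_design(self):
        rng = np.random.default_rng(12)
        x = pd.DataFrame(
            rng.normal(8, 1, size=(30, 9)),
            index=[f"g{i:02d}" for i in range(30)],
            columns=["S1", "S2", "S3", "M1", "M2", "M3", "F1", "F2", "F3"],
        )
        design = StudyDesign(
            pd.DataFrame(
                {
                    "sample_id": x.columns,
                    "experiment": "invivo",
                    "condition": ["S"] * 3 + ["M"] * 3 + ["F"] * 3,
                    "pair_id": "",
                }
            )
        )
        return GeneMatrix(x=x), design

    def test_welch_table_matches_scalar_kernel(self, matrix_and_design):
        gm, design = matrix_and_design
        table = ds.welch_table(gm, design, "S", "M").set_index("gene_id")
        for g in ["g00", "g07", "g29"]:
            a = gm.x.loc[g, ["S1", "S2", "S3"]]
            b = gm.x.loc[g, ["M1", "M2", "M3"]]
            ref = ds.welch_t(a, b)
            assert table.loc[g, "t_stat"] == pytest.approx(ref.t_stat, abs=1e-12)
            assert table.loc[g, "p"] == pytest.approx(ref.p, abs=1e-12)
            assert table.loc[g, "delta"] == pytest.approx(b.mean() - a.mean())

    def test_table_sorted_by_p_then_gene(self, matrix_and_design):
        gm, design = matrix_and_design
        table = ds.welch_table(gm, design, "S", "M")
        assert (table["p"].diff().dropna() >= 0).all()
        assert table["contrast"].unique().tolist() == ["M-S"]

    def test_anova_table_matches_scalar_kernel(self, matrix_and_design):
        gm, design = matrix_and_design
        table = ds.anova_table(gm, design, ["S", "M", "F"]).set_index("gene_id")
        g = "g13"
        groups = [
            gm.x.loc[g, ["S1", "S2", "S3"]],
            gm.x.loc[g, ["M1", "M2", "M3"]],
            gm.x.loc[g, ["F1", "F2", "F3"]],
        ]
        f, p = ds.anova_oneway(groups)
        assert table.loc[g, "f_stat"] == pytest.approx(f, abs=1e-12)
        assert table.loc[g, "p"] == pytest.approx(p, abs=1e-12)

    def test_paired_table_matches_scalar_kernel(self):
        rng = np.random.default_rng(13)
        x = pd.DataFrame(
            rng.normal(8, 1, size=(10, 8)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"c{i}" for i in range(4)] + [f"l{i}" for i in range(4)],
        )
        design = StudyDesign(
            pd.DataFrame(
                {
                    "sample_id": x.columns,
                    "experiment": "invitro",
                    "condition": ["control"] * 4 + ["LPS"] * 4,
                    "pair_id": [f"p{i}" for i in range(4)] * 2,
                }
            )
        )
        table = ds.paired_table(GeneMatrix(x=x), design, "control", "LPS")
        table = table.set_index("gene_id")
        g = "g3"
        diffs = x.loc[g, [f"l{i}" for i in range(4)]].to_numpy() - x.loc[
            g, [f"c{i}" for i in range(4)]
        ].to_numpy()
        ref = ds.paired_t(diffs)
        assert table.loc[g, "t_stat"] == pytest.approx(ref.t_stat, abs=1e-12)
        assert table.loc[g, "p"] == pytest.approx(ref.p, abs=1e-12)
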