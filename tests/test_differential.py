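import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest, mannwhitneyu, rankdata

from adipomem import differential as diff


class TestQCFilter:
    def _matrix(self, features_per_cell, umi_per_cell):
        """Craft a genes x cells matrix with exact feature/UMI totals."""
        n_genes = max(features_per_cell)
        X = np.zeros((n_genes, len(features_per_cell)), dtype=int)
        for j, (f, u) in enumerate(zip(features_per_cell, umi_per_cell)):
            X[:f, j] = 1
            X[0, j] += u - f
        return X

    def test_toy_matrix_rule_application(self):
        X = self._matrix([400, 500, 2000, 3500, 1000], [1000] * 5)
        keep, report = diff.qc_filter_cells(X, min_features=500,
                                            max_features=3000, max_umi=40000)
        assert keep.tolist() == [False, True, True, False, True]
        assert report["n_kept"] == 3

    def test_boundaries_inclusive(self):
        X = self._matrix([500, 3000], [40000, 40000])
        keep, _ = diff.qc_filter_cells(X)
        assert keep.all()

    def test_cell_above_umi_limit_removed(self):
        X = self._matrix([600, 600], [40001, 100])
        keep, _ = diff.qc_filter_cells(X)
        assert keep.tolist() == [False, True]

    def test_all_cells_removed_warns_not_raises(self):
        X = self._matrix([10, 10], [10, 10])
        with pytest.warns(UserWarning):
            keep, _ = diff.qc_filter_cells(X)
        assert not keep.any()


class TestLogNormalize:
    def test_zero_count_maps_to_zero(self):
        X = np.array([[0, 5], [10, 5]])
        assert diff.lognormalize(X)[0, 0] == 0.0

    def test_single_gene_cell_closed_form(self):
        X = np.array([[7.0], [0.0]])
        assert diff.lognormalize(X, scale=10000)[0, 0] == pytest.approx(
            np.log(1 + 10000))

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(3, size=(20, 6)) + 1
        perm = rng.permutation(6)
        assert np.allclose(diff.lognormalize(X)[:, perm],
                           diff.lognormalize(X[:, perm]))

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError):
            diff.lognormalize(np.array([[0, 1], [0, 2]]))

    def test_matches_scanpy(self):
        sc = pytest.importorskip("scanpy")
        import anndata as ad
        rng = np.random.default_rng(1)
        X = rng.poisson(2, size=(30, 10)).astype(float) + 1
        adata = ad.AnnData(X.T.copy())
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        assert np.allclose(diff.lognormalize(X), adata.X.T)


class TestLog2FC:
    def test_identity_and_antisymmetry(self):
        rng = np.random.default_rng(2)
        norm = np.log1p(rng.uniform(0, 5, size=(10, 8)))
        a, b = np.arange(4), np.arange(4, 8)
        assert np.allclose(diff.log2fc(norm, a, a), 0.0)
        assert np.allclose(diff.log2fc(norm, a, b), -diff.log2fc(norm, b, a))

    def test_hand_arithmetic(self):
        # de-logged means 3 and 1, pseudocount 1 -> log2(4/2) = 1
        norm = np.log1p(np.array([[3.0, 3.0, 1.0, 1.0]]))
        assert diff.log2fc(norm, [0, 1], [2, 3], pseudocount=1)[0] == pytest.approx(1.0)


def brute_force_ranksum_p(x, y):
    """Exhaustive two-sided permutation p-value on midranks."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, n1 = len(pooled), len(x)
    mu = n1 * (n + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mu)
    devs = [abs(ranks[list(c)].sum() - mu)
            for c in itertools.combinations(range(n), n1)]
    return np.mean([d >= obs - 1e-9 for d in devs])


class TestWilcoxon:
    def test_identical_groups_give_p_one(self):
        v = [1.0, 2.0, 3.0]
        assert diff.wilcoxon_rank_sum(v, v, method="exact") == 1.0
        assert diff.wilcoxon_rank_sum(v * 4, v * 4, method="normal") == 1.0

    def test_separated_triplets_exact_p(self):
        # all 20 assignments of {1,2,3 | 10,11,12}: the two extreme rank sums
        assert diff.wilcoxon_rank_sum([1, 2, 3], [10, 11, 12],
                                      method="exact") == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 5), (6, 6), (4, 6)])
    def test_exact_equals_exhaustive_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.integers(0, 4, size=n1).astype(float)  # ties likely
            y = rng.integers(0, 4, size=n2).astype(float)
            assert diff.wilcoxon_rank_sum(x, y, method="exact") == pytest.approx(
                brute_force_ranksum_p(x, y), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=6), rng.normal(size=5)
        expected = mannwhitneyu(x, y, method="exact",
                                alternative="two-sided").pvalue
        assert diff.wilcoxon_rank_sum(x, y, method="exact") == pytest.approx(
            expected, abs=1e-12)

    @pytest.mark.parametrize("n", [8, 10, 12])
    def test_normal_approximation_close_to_exact(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        y = rng.normal(0.5, size=n)
        p_exact = diff.wilcoxon_rank_sum(x, y, method="exact")
        p_norm = diff.wilcoxon_rank_sum(x, y, method="normal")
        assert abs(p_exact - p_norm) < 0.01

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            diff.wilcoxon_rank_sum([1.0], [2.0, 3.0])

    def test_deg_table_threshold_rule(self):
        # significant p but |log2fc| below threshold stays ns
        call = diff.make_calls(np.array([0.4, 0.6, -0.7]),
                               np.array([1e-6, 1e-6, 0.5]),
                               lfc_threshold=0.5, alpha=0.01)
        assert call.tolist() == ["ns", "up", "ns"]

    def test_deg_table_row_order_invariance(self):
        rng = np.random.default_rng(8)
        norm = np.log1p(rng.poisson(3.0, size=(15, 30)).astype(float))
        a, b = np.arange(15), np.arange(15, 30)
        t1 = diff.wilcoxon_deg(norm, a, b)
        perm = rng.permutation(15)
        t2 = diff.wilcoxon_deg(norm[perm], a, b)
        assert np.allclose(t1["p"].to_numpy()[perm], t2["p"])


def brute_force_bh(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    out = np.empty(m)
    for i, pi in enumerate(p):
        rank = (p <= pi).sum()
        candidates = [p[j] * m / (p <= p[j]).sum()
                      for j in range(m) if p[j] >= pi]
        out[i] = min(1.0, min(candidates))
        del rank
    return out


class TestAdjustPvalues:
    def test_bonferroni_closed_form(self):
        assert diff.adjust_pvalues([0.001] * 10, "bonferroni")[0] == pytest.approx(0.01)

    def test_equal_pvalues_unchanged_by_bh(self):
        p = np.full(6, 0.03)
        assert np.allclose(diff.adjust_pvalues(p, "bh"), p)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_bh_matches_brute_force_definition(self, p):
        assert np.allclose(diff.adjust_pvalues(p, "bh"), brute_force_bh(p))

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        for ours, theirs in (("bh", "fdr_bh"), ("bonferroni", "bonferroni")):
            assert np.allclose(diff.adjust_pvalues(p, ours),
                               sm.multipletests(p, method=theirs)[1])

    def test_bonferroni_dominates_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        assert (diff.adjust_pvalues(p, "bonferroni") >= p).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diff.adjust_pvalues([0.5, 1.5], "bh")


class TestDispersion:
    def test_poisson_data_gives_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(40, size=(5000, 6))
        groups = ["a"] * 3 + ["b"] * 3
        assert diff.estimate_common_dispersion(X, groups) < 0.02

    def test_recovers_true_dispersion(self):
        rng = np.random.default_rng(1)
        phi, mu = 0.2, 50.0
        r = 1 / phi
        X = rng.negative_binomial(r, r / (r + mu), size=(2000, 6))
        groups = ["a"] * 3 + ["b"] * 3
        assert 0.1 <= diff.estimate_common_dispersion(X, groups) <= 0.3

    def test_constant_matrix_gives_zero(self):
        X = np.full((100, 4), 7)
        assert diff.estimate_common_dispersion(X, ["a", "a", "b", "b"]) == 0.0

    def test_single_sample_groups_rejected(self):
        with pytest.raises(ValueError):
            diff.estimate_common_dispersion(np.ones((10, 2)), ["a", "b"])


class TestNBExactTest:
    def test_identical_groups_give_p_one(self):
        X = np.tile(np.array([[5], [9], [40]]), (1, 6))
        t = diff.nb_exact_test(X, ["a"] * 3 + ["b"] * 3, "a", "b", dispersion=0.1)
        assert (t["p"] == 1.0).all() and (t["call"] == "ns").all()

    def test_zero_dispersion_reduces_to_binomial(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(30, size=(200, 5))
        cond = np.array(["a", "a", "b", "b", "b"])
        t = diff.nb_exact_test(X, cond, "a", "b", dispersion=0.0)
        sf = diff.size_factors_median_of_ratios(X)
        pseudo = np.rint(X / sf).astype(int)
        for i in range(len(t)):
            ya = int(pseudo[i, :2].sum())
            tot = int(pseudo[i].sum())
            expected = binomtest(ya, tot, 2 / 5).pvalue
            assert abs(t.loc[i, "p"] - expected) < 1e-9

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(3)
        X = rng.negative_binomial(10, 0.3, size=(50, 6))
        cond = ["a"] * 3 + ["b"] * 3
        t1 = diff.nb_exact_test(X, cond, "a", "b", dispersion=0.1)
        t2 = diff.nb_exact_test(X, cond, "b", "a", dispersion=0.1)
        assert np.allclose(t1["p"], t2["p"])
        assert np.allclose(t1["log2fc"], -t2["log2fc"])

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            diff.nb_exact_test(np.ones((5, 4)), ["a", "a", "b", "b"],
                               "a", "b", dispersion=-0.1)

    def test_detects_planted_fourfold_change(self):
        rng = np.random.default_rng(4)
        mu = np.full((100, 6), 50.0)
        mu[:10, :3] *= 4  # first ten features shifted in condition a
        r = 10.0
        X = rng.negative_binomial(r, r / (r + mu))
        t = diff.nb_exact_test(X, ["a"] * 3 + ["b"] * 3, "a", "b",
                               dispersion=0.1, alpha=0.01, alpha_on="p")
        assert (t.loc[:9, "call"] == "up").mean() >= 0.8
        assert (t.loc[10:, "call"] == "ns").mean() >= 0.95


class TestCorrelationToReference:
    def test_query_equal_to_control_profile(self):
        rng = np.random.default_rng(5)
        col = rng.poisson(20, size=200) + 1.0
        X = np.column_stack([col, col, col])
        assert diff.correlation_to_reference(X, [0, 1], 2) == pytest.approx(1.0)

    def test_negated_centred_control_gives_minus_one(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=100)
        query = -(ref - ref.mean()) + ref.mean()
        X = np.column_stack([ref, query])
        r = diff.correlation_to_reference(X, [0], 1, lognorm=False)
        assert r == pytest.approx(-1.0)

    def test_independent_profiles_uncorrelated(self):
        rng = np.random.default_rng(6)
        X = rng.poisson(10, size=(10000, 3)) + 1.0
        assert abs(diff.correlation_to_reference(X, [0, 1], 2)) < 0.05

    def test_zero_variance_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError):
            diff.correlation_to_reference(X, [0], 1)
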