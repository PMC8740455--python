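"""Cluster profiles, correlation statistics and FDR control."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metacorr import (
    ExpressionMatrix,
    cluster_profile,
    compare_cluster_vs_cell,
    correlate_pair,
    correlate_pairs,
    partition,
    stability_scan,
)
from metacorr.graph import Clustering

from .oracles import bh_stepup, pearson_t_pvalue


def _clustering(labels, n=None):
    labels = np.asarray(labels)
    coords = np.zeros((len(labels), 2))
    return Clustering.from_labels(labels, coords, sort_by_size=False)


class TestClusterProfile:
    def test_forced_two_cluster_means(self):
        expr = ExpressionMatrix(np.array([[2.0, 0.0, 0.0, 4.0]]), ["g"], list("abcd"))
        prof = cluster_profile(expr, _clustering([0, 0, 1, 1]))
        assert prof.values[:, 0].tolist() == [1.0, 2.0]

    def test_singleton_clusters_reproduce_matrix(self, small_dataset):
        expr = small_dataset.expression
        prof = cluster_profile(expr, _clustering(np.arange(expr.n_cells)))
        assert np.allclose(prof.values, expr.toarray().T)

    def test_all_zero_gene_stays_zero(self):
        expr = ExpressionMatrix(np.zeros((2, 6)), ["g1", "g2"], list("abcdef"))
        prof = cluster_profile(expr, _clustering([0, 0, 1, 1, 2, 2]))
        assert (prof.values == 0).all()

    def test_size_weighted_means_reproduce_global_mean(self, small_dataset):
        expr = small_dataset.expression
        c = partition(small_dataset.embedding, 12, seed=0)
        prof = cluster_profile(expr, c)
        weighted = (prof.values * prof.sizes[:, None]).sum(axis=0) / prof.sizes.sum()
        assert np.allclose(weighted, expr.toarray().mean(axis=1), rtol=1e-10)

    def test_cluster_means_bounded_by_cell_range(self, small_dataset):
        expr = small_dataset.expression
        c = partition(small_dataset.embedding, 10, seed=0)
        prof = cluster_profile(expr, c)
        dense = expr.toarray()
        assert (prof.values >= dense.min(axis=1)[None, :] - 1e-12).all()
        assert (prof.values <= dense.max(axis=1)[None, :] + 1e-12).all()

    def test_cell_count_mismatch_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            cluster_profile(small_dataset.expression, _clustering([0, 1]))


class TestCorrelatePair:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = correlate_pair(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_constant_vector_is_degenerate(self):
        res = correlate_pair(np.ones(5), np.arange(5.0))
        assert res.status == "degenerate"
        assert np.isnan(res.r) and np.isnan(res.p)

    def test_matches_closed_form_t_test(self, rng):
        for _ in range(200):
            x, y = rng.normal(size=(2, 20))
            res = correlate_pair(x, y)
            r_ref, p_ref = pearson_t_pvalue(x, y)
            assert res.r == pytest.approx(r_ref, abs=1e-12)
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_matches_scipy_and_statsmodels(self, rng):
        """The t-test p equals scipy's pearsonr and the Gaussian linear-model
        slope test (two independent routes)."""
        import statsmodels.api as sm
        from scipy import stats as sps

        x, y = rng.normal(size=(2, 30))
        res = correlate_pair(x, y)
        sp = sps.pearsonr(x, y)
        assert res.r == pytest.approx(sp.statistic, abs=1e-12)
        assert res.p == pytest.approx(sp.pvalue, abs=1e-10)
        glm = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.p == pytest.approx(glm.pvalues[1], abs=1e-10)

    def test_spearman_is_rank_pearson(self, rng):
        x, y = rng.normal(size=(2, 25))
        res = correlate_pair(x, y, method="spearman")
        from scipy import stats as sps

        ref = sps.spearmanr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            correlate_pair(np.arange(3.0), np.arange(4.0))
        with pytest.raises(ValueError):
            correlate_pair(np.arange(2.0), np.arange(2.0))
        with pytest.raises(ValueError):
            correlate_pair(np.arange(5.0), np.arange(5.0), method="kendall")


class TestCorrelatePairs:
    def _matrix(self, rng, n_genes=10, n_cells=40):
        vals = rng.gamma(2.0, size=(n_genes, n_cells))
        genes = [f"g{i}" for i in range(n_genes)]
        cells = [f"c{i}" for i in range(n_cells)]
        return ExpressionMatrix(vals, genes, cells)

    def test_single_pair_q_equals_p(self, rng):
        expr = self._matrix(rng)
        df = correlate_pairs(expr, [("g0", "g1")])
        assert df.q.iloc[0] == pytest.approx(df.p.iloc[0])

    def test_bh_matches_stepup_oracle(self, rng):
        expr = self._matrix(rng, n_genes=40)
        pairs = [(f"g{2*i}", f"g{2*i+1}") for i in range(20)]
        df = correlate_pairs(expr, pairs)
        assert np.allclose(df.q.values, bh_stepup(df.p.values))

    def test_missing_gene_skipped_with_status(self, rng):
        expr = self._matrix(rng)
        df = correlate_pairs(expr, [("g0", "g1"), ("g0", "nope")])
        assert df.status.tolist().count("missing") == 1
        missing = df[df.status == "missing"].iloc[0]
        assert np.isnan(missing.q)
        assert not missing.significant

    def test_degenerate_excluded_from_bh_denominator(self, rng):
        vals = rng.gamma(2.0, size=(4, 30))
        vals[3] = 1.0  # constant gene
        expr = ExpressionMatrix(vals, ["g0", "g1", "g2", "g3"], [f"c{i}" for i in range(30)])
        df = correlate_pairs(expr, [("g0", "g1"), ("g2", "g3")])
        ok = df[df.status == "ok"]
        assert len(ok) == 1
        # m = 1 for BH, so q == p
        assert ok.q.iloc[0] == pytest.approx(ok.p.iloc[0])

    def test_empty_pair_list_rejected(self, rng):
        with pytest.raises(ValueError):
            correlate_pairs(self._matrix(rng), [])

    def test_output_sorted_by_p(self, rng):
        expr = self._matrix(rng, n_genes=20)
        pairs = [(f"g{2*i}", f"g{2*i+1}") for i in range(10)]
        df = correlate_pairs(expr, pairs)
        ok = df[df.status == "ok"]
        assert (np.diff(ok.p.values) >= 0).all()


class TestBHProperty:
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=200))
    def test_stepup_oracle_agreement_on_random_pvectors(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.array(pvals)
        got = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(got, bh_stepup(p), atol=1e-12)

    def test_worked_example(self):
        # p = [.01,.02,.03,.04]: q(i) = p(i)*4/i -> [.04,.04,.04,.04]
        assert np.allclose(bh_stepup(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)
        from statsmodels.stats.multitest import multipletests

        got = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(got, 0.04)


class TestCompareClusterVsCell:
    def test_identity_at_k_equal_cells(self, small_dataset):
        pairs = [("g00000", "g00001"), ("g00002", "g00003"), ("g00004", "g00005")]
        merged, summary = compare_cluster_vs_cell(
            small_dataset.expression, small_dataset.embedding, pairs,
            k=small_dataset.expression.n_cells, seed=0,
        )
        assert np.allclose(merged.r_cell, merged.r_cluster, atol=1e-12)
        assert np.allclose(merged.p_cell, merged.p_cluster, atol=1e-12)

    def test_cluster_beats_cell_on_correlated_pair(self, small_dataset):
        merged, summary = compare_cluster_vs_cell(
            small_dataset.expression, small_dataset.embedding,
            [("g00000", "g00001")], k=15, seed=0,
        )
        row = merged.iloc[0]
        assert abs(row.r_cluster) > abs(row.r_cell)

    def test_summary_counts_consistent(self, small_dataset):
        pairs = [(f"g{2*i:05d}", f"g{2*i+1:05d}") for i in range(10)]
        merged, summary = compare_cluster_vs_cell(
            small_dataset.expression, small_dataset.embedding, pairs, k=20, seed=0,
        )
        assert summary["n_pairs"] == 10
        assert summary["significant_any"] == (
            summary["significant_cell"] + summary["significant_cluster"]
            - summary["significant_both"]
        )


class TestStabilityScan:
    def test_reference_only_returns_top_pairs(self, small_dataset):
        pairs = [(f"g{2*i:05d}", f"g{2*i+1:05d}") for i in range(8)]
        out = stability_scan(
            small_dataset.expression, small_dataset.embedding, pairs,
            ks=[20], reference_k=20, top_n=3, seed=0,
        )
        assert sorted(out.k.unique()) == [20]
        assert len(out) == 3

    def test_cell_count_level_equals_single_cell_baseline(self, small_dataset):
        expr = small_dataset.expression
        pairs = [(f"g{2*i:05d}", f"g{2*i+1:05d}") for i in range(6)]
        out = stability_scan(
            expr, small_dataset.embedding, pairs,
            ks=[20, expr.n_cells], reference_k=20, top_n=4, seed=0,
        )
        base = correlate_pairs(expr, pairs)
        level = out[out.k == expr.n_cells].set_index(["gene_a", "gene_b"])
        base = base.set_index(["gene_a", "gene_b"])
        for key in level.index:
            assert level.loc[key, "r"] == pytest.approx(base.loc[key, "r"], abs=1e-12)

    def test_truncates_with_warning_when_few_pairs(self, small_dataset):
        with pytest.warns(UserWarning, match="truncating"):
            out = stability_scan(
                small_dataset.expression, small_dataset.embedding,
                [("g00000", "g00001")], ks=[15], reference_k=15, top_n=5, seed=0,
            )
        assert len(out) == 1

    def test_reference_k_must_be_in_ks(self, small_dataset):
        with pytest.raises(ValueError):
            stability_scan(
                small_dataset.expression, small_dataset.embedding,
                [("g00000", "g00001")], ks=[10], reference_k=20, seed=0,
            )
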