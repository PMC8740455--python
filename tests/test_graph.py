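"""Graph construction, Louvain over-segmentation and greedy k-merging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from metacorr import (
    Embedding2D,
    GraphKPartitioner,
    GraphParams,
    SimulationConfig,
    build_cell_graph,
    cells_per_cluster_summary,
    filter_small_clusters,
    louvain_oversegment,
    merge_to_k,
    partition,
    partition_series,
    scale_embedding,
    simulate_dataset,
)
from metacorr.graph import Clustering

from .oracles import brute_force_edges, greedy_merge_oracle


def _emb(coords):
    coords = np.asarray(coords, dtype=float)
    return Embedding2D(np.arange(len(coords)).astype(object), coords)


def _prepared_graph(emb, params=GraphParams()):
    scaled = scale_embedding(emb, params.half_range)
    g = build_cell_graph(scaled, params)
    g._coords = scaled.coords
    return scaled, g


class TestScaleEmbedding:
    def test_maps_pm50_to_pm200_by_factor_four(self):
        emb = _emb([[-50, 10], [50, -20], [0, 0]])
        out = scale_embedding(emb, 200)
        assert np.allclose(out.coords, emb.coords * 4)

    def test_identity_when_already_at_half_range(self):
        emb = _emb([[-200, 0], [100, 150], [0, 0]])
        out = scale_embedding(emb, 200)
        assert np.allclose(out.coords, emb.coords)

    def test_auto_targets_depend_on_cell_count(self):
        small = _emb(np.random.default_rng(0).uniform(-1, 1, (100, 2)))
        assert np.abs(scale_embedding(small, "auto").coords).max() == pytest.approx(200)

    def test_distance_ratios_preserved(self, rng):
        coords = rng.normal(size=(20, 2))
        out = scale_embedding(_emb(coords), 300)
        d_in = np.linalg.norm(coords[0] - coords[1]) / np.linalg.norm(coords[2] - coords[3])
        d_out = np.linalg.norm(out.coords[0] - out.coords[1]) / np.linalg.norm(
            out.coords[2] - out.coords[3]
        )
        assert d_out == pytest.approx(d_in, rel=1e-12)

    def test_coincident_cells_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            scale_embedding(_emb([[1, 1], [1, 1], [1, 1]]), 200)


class TestBuildCellGraph:
    def test_collinear_forced_edge(self):
        g = build_cell_graph(_emb([[0, 0], [2, 0], [7, 0]]), GraphParams(cutoff=3))
        assert set(map(tuple, map(sorted, g.graph.edges()))) == {(0, 1)}

    def test_zero_cutoff_gives_no_edges(self):
        with pytest.warns(UserWarning, match="no edges"):
            g = build_cell_graph(_emb([[0, 0], [1, 0]]), GraphParams(cutoff=0))
        assert g.n_edges == 0

    @pytest.mark.parametrize("n", [100, 500])
    def test_matches_brute_force_threshold(self, n, rng):
        coords = rng.uniform(-20, 20, size=(n, 2))
        g = build_cell_graph(_emb(coords), GraphParams(cutoff=3))
        got = {tuple(sorted(e)) for e in g.graph.edges()}
        assert got == brute_force_edges(coords, 3.0)

    def test_weights_positive_and_distance_stored(self, rng):
        coords = rng.uniform(-5, 5, size=(50, 2))
        g = build_cell_graph(_emb(coords), GraphParams(cutoff=3))
        for i, j, data in g.graph.edges(data=True):
            assert data["weight"] > 0
            assert data["distance"] <= 3.0
            assert data["distance"] == pytest.approx(
                np.linalg.norm(coords[i] - coords[j])
            )


class TestLouvainOversegment:
    def test_two_cliques_recovered(self):
        # two 5-cliques joined by one edge: the modularity optimum is the
        # two cliques (verified by exhaustive search over all partitions)
        import itertools

        import networkx as nx

        g = nx.Graph()
        for base in (0, 5):
            g.add_edges_from(
                (base + i, base + j) for i in range(5) for j in range(i + 1, 5)
            )
        g.add_edge(0, 5)
        nx.set_edge_attributes(g, 1.0, "weight")

        def all_partitions(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            for part in all_partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [[first] + part[i]] + part[i + 1 :]
                yield [[first]] + part

        best = max(
            all_partitions(list(range(10))),
            key=lambda p: nx.community.modularity(g, [set(b) for b in p]),
        )
        assert sorted(map(sorted, best)) == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]

        from metacorr.graph import CellGraph

        cg = CellGraph(g, cutoff=3.0, component_labels=np.zeros(10, dtype=int))
        cg._coords = np.zeros((10, 2))
        clustering = louvain_oversegment(cg, k=1, seed=0)
        got = [sorted(np.flatnonzero(clustering.labels == l))
               for l in range(clustering.k)]
        assert sorted(got) == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]

    def test_edgeless_graph_gives_singletons(self):
        emb = _emb(np.arange(12).reshape(6, 2) * 100.0)
        _, g = _prepared_graph(emb)
        clustering = louvain_oversegment(g, k=2, seed=0)
        assert clustering.k == 6

    def test_k_at_cell_count_boundary(self, rng):
        coords = rng.uniform(-2, 2, size=(8, 2))
        _, g = _prepared_graph(_emb(coords))
        try:
            clustering = louvain_oversegment(g, k=7, seed=0)
            assert clustering.k == 8  # all singletons
        except (ValueError, RuntimeError):
            pass  # escalation limit reached: contract allows the error

    def test_k_not_below_cells_rejected(self, rng):
        coords = rng.uniform(-2, 2, size=(5, 2))
        _, g = _prepared_graph(_emb(coords))
        with pytest.raises(ValueError, match="over-segment"):
            louvain_oversegment(g, k=5)


class TestMergeToK:
    def test_zero_merges_preserves_partition(self, rng):
        coords = rng.uniform(-30, 30, size=(60, 2))
        emb = _emb(coords)
        scaled, g = _prepared_graph(emb)
        over = louvain_oversegment(g, k=3, seed=0)
        merged = merge_to_k(over, g, scaled, over.k)
        assert adjusted_rand_score(over.labels, merged.labels) == 1.0

    def test_forced_three_singletons(self):
        # singleton clusters at x = 0, 1, 10: closest pair {0, 1} merges
        coords = np.array([[0.0, 0], [1.0, 0], [10.0, 0]])
        emb = _emb(coords)
        g = build_cell_graph(emb, GraphParams(cutoff=30))
        g._coords = coords
        start = Clustering.from_labels(np.array([0, 1, 2]), coords, sort_by_size=False)
        merged = merge_to_k(start, g, emb, 2)
        assert merged.labels[0] == merged.labels[1] != merged.labels[2]

    def test_matches_rescan_oracle_on_random_instances(self, rng):
        for trial in range(3):
            coords = rng.uniform(-50, 50, size=(200, 2))
            emb = _emb(coords)
            scaled, g = _prepared_graph(emb)
            over = louvain_oversegment(g, k=10, seed=trial)
            expected = greedy_merge_oracle(over.labels.copy(), g.graph, scaled.coords, 10)
            got = merge_to_k(over, g, scaled, 10)
            assert adjusted_rand_score(expected, got.labels) == 1.0

    def test_k_out_of_range_rejected(self, rng):
        coords = rng.uniform(-3, 3, size=(30, 2))
        emb = _emb(coords)
        scaled, g = _prepared_graph(emb)
        over = louvain_oversegment(g, k=2, seed=0)
        with pytest.raises(ValueError):
            merge_to_k(over, g, scaled, over.k + 1)
        with pytest.raises(ValueError):
            merge_to_k(over, g, scaled, 0)


class TestPartition:
    def test_single_cluster(self, small_dataset):
        c = partition(small_dataset.embedding, 1, seed=0)
        assert c.k == 1 and c.sizes[0] == small_dataset.embedding.n_cells

    @pytest.mark.parametrize("k", [5, 25])
    def test_exactly_k_nonempty_clusters(self, small_dataset, k):
        c = partition(small_dataset.embedding, k, seed=0)
        assert c.k == k
        assert (c.sizes > 0).all()
        assert (c.labels >= 0).all()
        assert c.sizes.sum() == small_dataset.embedding.n_cells

    def test_identity_limit_is_singletons(self, small_dataset):
        n = small_dataset.embedding.n_cells
        c = partition(small_dataset.embedding, n, seed=0)
        assert c.k == n and (c.sizes == 1).all()
        assert np.array_equal(c.labels, np.arange(n))

    def test_separated_blobs_recovered(self):
        ds = simulate_dataset(
            SimulationConfig(n_genes=5, n_cells=600, zero_prob=0.5,
                             n_types=4, type_separation=400, seed=3)
        )
        c = partition(ds.embedding, 4, seed=0)
        assert adjusted_rand_score(ds.cell_labels, c.labels) == 1.0

    def test_blobs_never_mix_within_clusters(self):
        ds = simulate_dataset(
            SimulationConfig(n_genes=5, n_cells=500, zero_prob=0.5,
                             n_types=3, type_separation=300, seed=5)
        )
        c = partition(ds.embedding, 30, seed=1)
        for lab in range(c.k):
            types = np.unique(ds.cell_labels[c.labels == lab])
            assert len(types) == 1

    def test_seeded_determinism(self, small_dataset):
        a = partition(small_dataset.embedding, 20, seed=7)
        b = partition(small_dataset.embedding, 20, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_median_size_near_expected(self):
        ds = simulate_dataset(SimulationConfig(n_genes=5, n_cells=1000, zero_prob=0.5, seed=8))
        c = partition(ds.embedding, 10, seed=0)
        expected = 100
        assert expected / 3 <= np.median(c.sizes) <= expected * 3


class TestPartitionSeries:
    def test_nesting_between_levels(self, small_dataset):
        series = partition_series(small_dataset.embedding, [10, 20], seed=0)
        fine, coarse = series[20].labels, series[10].labels
        for lab in np.unique(fine):
            parents = np.unique(coarse[fine == lab])
            assert len(parents) == 1

    def test_single_k_matches_partition(self, small_dataset):
        series = partition_series(small_dataset.embedding, [15], seed=4)
        direct = partition(small_dataset.embedding, 15, seed=4)
        assert np.array_equal(series[15].labels, direct.labels)

    def test_rejects_bad_ks(self, small_dataset):
        with pytest.raises(ValueError):
            partition_series(small_dataset.embedding, [], seed=0)
        with pytest.raises(ValueError):
            partition_series(small_dataset.embedding, [10, 10], seed=0)
        with pytest.raises(ValueError):
            partition_series(small_dataset.embedding, [0, 5], seed=0)

    @given(st.integers(0, 1000))
    def test_nesting_is_seed_independent(self, seed):
        # nesting holds by construction for every seed
        coords = np.random.default_rng(3).uniform(-40, 40, (150, 2))
        series = partition_series(_emb(coords), [5, 12], seed=seed % 7)
        fine, coarse = series[12].labels, series[5].labels
        for lab in np.unique(fine):
            assert len(np.unique(coarse[fine == lab])) == 1


class TestSummaryAndFiltering:
    def test_expected_size_and_threshold_counts(self):
        labels = np.array([0] * 90 + [1] * 9 + [2])
        coords = np.zeros((100, 2))
        coords[90:99, 0] = 5
        coords[99, 0] = 50
        c = Clustering.from_labels(labels, coords)
        table, summary = cells_per_cluster_summary(c, size_threshold=10)
        assert summary["expected_size"] == pytest.approx(100 / 3)
        assert summary["n_below_threshold"] == 2
        assert sorted(table["size"]) == [1, 9, 90]

    def test_merge_mode_absorbs_small_cluster(self):
        labels = np.array([0] * 5 + [1] * 50)
        coords = np.vstack([np.zeros((5, 2)), np.ones((50, 2))])
        c = Clustering.from_labels(labels, coords)
        out, report = filter_small_clusters(c, min_cells=10, mode="merge")
        assert out.k == 1 and out.sizes[0] == 55
        assert report["n_affected"] == 1

    def test_drop_mode_unassigns_small_cluster(self):
        labels = np.array([0] * 5 + [1] * 50)
        coords = np.vstack([np.zeros((5, 2)), np.ones((50, 2))])
        c = Clustering.from_labels(labels, coords)
        out, report = filter_small_clusters(c, min_cells=10, mode="drop")
        assert out.k == 1 and out.sizes[0] == 50
        assert report["n_unassigned"] == 5
        assert (out.labels == -1).sum() == 5

    def test_noop_when_all_clusters_large(self, small_dataset):
        c = partition(small_dataset.embedding, 5, seed=0)
        out, report = filter_small_clusters(c, min_cells=2, mode="merge")
        assert np.array_equal(out.labels, c.labels)
        assert report["n_affected"] == 0

    def test_invalid_arguments(self, small_dataset):
        c = partition(small_dataset.embedding, 5, seed=0)
        with pytest.raises(ValueError):
            filter_small_clusters(c, min_cells=0)
        with pytest.raises(ValueError):
            filter_small_clusters(c, min_cells=5, mode="explode")


class TestGraphKPartitioner:
    def test_sklearn_contract(self, small_dataset):
        est = GraphKPartitioner(k=12, random_state=0)
        labels = est.fit_predict(small_dataset.embedding.coords)
        assert len(np.unique(labels)) == 12
        assert est.labels_ is labels or np.array_equal(est.labels_, labels)
        assert est.centroids_.shape == (12, 2)
        assert est.n_communities_ > 12
        params = est.get_params()
        clone = GraphKPartitioner(**params)
        assert np.array_equal(
            clone.fit_predict(small_dataset.embedding.coords), labels
        )

    def test_filtering_through_estimator(self, small_dataset):
        est = GraphKPartitioner(k=40, min_cells=5, small_mode="merge", random_state=0)
        est.fit(small_dataset.embedding.coords)
        assert est.cluster_sizes_.min() >= 5

    def test_rejects_non_2d_input(self):
        with pytest.raises(ValueError):
            GraphKPartitioner(k=2).fit(np.zeros((10, 3)))
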