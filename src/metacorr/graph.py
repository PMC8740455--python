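"""Graph-based k-partitioning of cells on a 2D embedding.

The method over-segments a distance-thresholded cell graph with Louvain
community detection into N > k communities, then greedily merges adjacent
communities by centroid distance until exactly k mini-clusters remain.
Averaging expression within these mini-clusters (see
:mod:`metacorr.correlate`) suppresses dropout zeros while preserving local
transcriptomic structure.

Pipeline: :func:`scale_embedding` -> :func:`build_cell_graph` ->
:func:`louvain_oversegment` -> :func:`merge_to_k`, composed by
:func:`partition` / :func:`partition_series` and wrapped in the
scikit-learn-style estimator :class:`GraphKPartitioner`.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_array, check_random_state

__all__ = [
    "Embedding2D",
    "GraphParams",
    "CellGraph",
    "Clustering",
    "ClusterSeries",
    "scale_embedding",
    "build_cell_graph",
    "louvain_oversegment",
    "merge_to_k",
    "partition",
    "partition_series",
    "cells_per_cluster_summary",
    "filter_small_clusters",
    "GraphKPartitioner",
]

#: additive epsilon keeping similarity weights strictly positive
WEIGHT_EPS = 1e-6


@dataclass
class Embedding2D:
    """Per-cell 2D coordinates (e.g. a tSNE projection computed upstream)."""

    cells: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n_cells, 2) array")
        if len(self.cells) != len(self.coords):
            raise ValueError("cell id count does not match coordinate rows")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell ids in embedding")
        if self.coords.size and not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class GraphParams:
    """Graph-construction parameters.

    cutoff : maximum edge length in scaled embedding units (default 3);
        any pair farther apart than this is not connected.
    half_range : target of the pre-scaling step — the largest absolute
        coordinate after scaling ("auto": 200 for up to 8000 cells, 400
        beyond, matching the recommended settings for small/large datasets).
    weight_mode : how edge distances become Louvain modularity weights.
        "inverted-distance" (default) uses cutoff - d + eps so that closer
        cells attract more strongly; "unweighted" uses 1; "raw-distance"
        uses d + eps (provided for fidelity experiments — note it inverts
        the affinity ordering).
    """

    cutoff: float = 3.0
    half_range: Union[float, str] = "auto"
    weight_mode: str = "inverted-distance"

    def __post_init__(self):
        if self.cutoff < 0:
            raise ValueError("cutoff must be nonnegative")
        if isinstance(self.half_range, str):
            if self.half_range != "auto":
                raise ValueError("half_range must be a positive number or 'auto'")
        elif self.half_range <= 0:
            raise ValueError("half_range must be positive")
        if self.weight_mode not in ("inverted-distance", "unweighted", "raw-distance"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class CellGraph:
    """Distance-thresholded weighted graph over cells."""

    graph: nx.Graph
    cutoff: float
    component_labels: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if len(self.component_labels) else 0

    def isolated_cells(self) -> list[int]:
        return [n for n, d in self.graph.degree() if d == 0]


@dataclass
class Clustering:
    """Cell -> cluster assignment for a single k.

    ``labels`` holds one integer per cell in 0..k-1, or -1 for cells marked
    unassigned by filtering.  ``centroids`` are arithmetic means of member
    coordinates; ``sizes`` the member counts.  ``n_initial`` and
    ``resolution`` record the Louvain over-segmentation that produced it,
    when applicable.
    """

    labels: np.ndarray
    centroids: np.ndarray
    sizes: np.ndarray
    n_initial: Optional[int] = None
    resolution: Optional[float] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=int)

    @property
    def k(self) -> int:
        return len(self.sizes)

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    @property
    def n_assigned(self) -> int:
        return int((self.labels >= 0).sum())

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    @classmethod
    def from_labels(
        cls,
        labels: np.ndarray,
        coords: np.ndarray,
        n_initial: Optional[int] = None,
        resolution: Optional[float] = None,
        sort_by_size: bool = True,
    ) -> "Clustering":
        """Build a Clustering from raw labels, re-indexing 0..k-1.

        With ``sort_by_size`` labels are ordered by descending cluster size
        (stable on ties, preserving the original label order).
        """
        labels = np.asarray(labels)
        assigned = labels >= 0 if np.issubdtype(labels.dtype, np.integer) else np.ones(len(labels), bool)
        uniq, inv = np.unique(labels[assigned], return_inverse=True)
        sizes = np.bincount(inv, minlength=len(uniq))
        order = np.argsort(-sizes, kind="stable") if sort_by_size else np.arange(len(uniq))
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        new_labels = np.full(len(labels), -1, dtype=int)
        new_labels[assigned] = rank[inv]
        k = len(uniq)
        centroids = np.zeros((k, 2))
        out_sizes = np.zeros(k, dtype=int)
        for lab in range(k):
            m = new_labels == lab
            centroids[lab] = coords[m].mean(axis=0)
            out_sizes[lab] = m.sum()
        return cls(new_labels, centroids, out_sizes, n_initial, resolution)


@dataclass
class ClusterSeries:
    """Nested clusterings for an ascending list of k values.

    All levels are snapshots of one merge path, so every cluster at a
    smaller k is an exact union of clusters at any larger k.
    """

    ks: list[int]
    clusterings: dict[int, Clustering] = field(default_factory=dict)

    def __getitem__(self, k: int) -> Clustering:
        return self.clusterings[k]

    def label_matrix(self) -> np.ndarray:
        """n_cells x n_levels label matrix, levels in ascending-k order."""
        return np.column_stack([self.clusterings[k].labels for k in self.ks])


def scale_embedding(emb: Embedding2D, half_range: Union[float, str] = "auto") -> Embedding2D:
    """Rescale coordinates so the largest |x| or |y| equals ``half_range``.

    One global multiplicative factor is applied to both axes (aspect ratio
    and all pairwise-distance ratios preserved; no centering, matching the
    convention that tSNE output is already centered near the origin).
    ``half_range="auto"`` picks 200 for n_cells <= 8000 and 400 beyond.
    """
    if emb.n_cells < 2:
        raise ValueError("need at least 2 cells to scale an embedding")
    if isinstance(half_range, str):
        if half_range != "auto":
            raise ValueError("half_range must be a positive number or 'auto'")
        half_range = 200.0 if emb.n_cells <= 8000 else 400.0
    if half_range <= 0:
        raise ValueError("half_range must be positive")
    span = np.ptp(emb.coords, axis=0)
    if np.all(span == 0):
        raise ValueError("degenerate embedding: all cells coincident")
    max_abs = np.abs(emb.coords).max()
    if max_abs == 0:  # pragma: no cover - excluded by the coincidence check
        raise ValueError("degenerate embedding: all coordinates zero")
    return Embedding2D(emb.cells, emb.coords * (half_range / max_abs))


def _edge_weights(dists: np.ndarray, cutoff: float, mode: str) -> np.ndarray:
    if mode == "inverted-distance":
        return cutoff - dists + WEIGHT_EPS
    if mode == "unweighted":
        return np.ones_like(dists)
    if mode == "raw-distance":
        return dists + WEIGHT_EPS
    raise ValueError(f"unknown weight_mode {mode!r}")


def build_cell_graph(emb: Embedding2D, params: GraphParams = GraphParams()) -> CellGraph:
    """Connect every cell pair within ``params.cutoff`` (scaled units).

    Edges store the Euclidean distance and a modularity weight per
    ``params.weight_mode``.  Connected components are labeled; isolated
    cells are allowed (a zero-edge graph triggers a warning only).
    """
    coords = emb.coords
    n = emb.n_cells
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if n >= 2 and params.cutoff > 0:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(params.cutoff, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
            # query_pairs uses strict/inclusive <= r; enforce d <= cutoff exactly
            keep = d <= params.cutoff
            pairs, d = pairs[keep], d[keep]
            w = _edge_weights(d, params.cutoff, params.weight_mode)
            g.add_edges_from(
                (int(i), int(j), {"distance": float(dd), "weight": float(ww)})
                for (i, j), dd, ww in zip(pairs, d, w)
            )
    if g.number_of_edges() == 0:
        warnings.warn(
            "cell graph has no edges (cutoff too small for this embedding scale); "
            "every cell is its own component"
        )
    comp = np.empty(n, dtype=int)
    for ci, nodes in enumerate(nx.connected_components(g)):
        comp[list(nodes)] = ci
    return CellGraph(g, params.cutoff, comp)


def louvain_oversegment(
    cell_graph: CellGraph,
    k: int,
    seed: Optional[int] = None,
    initial_resolution: float = 1.0,
    max_rounds: int = 20,
) -> Clustering:
    """Louvain communities on the weighted cell graph, guaranteed N > k.

    If the first pass yields N <= k communities, the resolution parameter is
    escalated geometrically (x1.5 per round, at most ``max_rounds`` rounds)
    until N > k.  Each connected component is handled naturally by Louvain
    (communities never span components).
    """
    n = cell_graph.n_cells
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(
            f"cannot over-segment {n} cells into more than k={k} communities "
            f"(need N > k, maximum N is {n})"
        )
    seed = 0 if seed is None else int(seed)
    resolution = float(initial_resolution)
    for _ in range(max_rounds):
        comms = nx.community.louvain_communities(
            cell_graph.graph, weight="weight", resolution=resolution, seed=seed
        )
        if len(comms) > k:
            labels = np.empty(n, dtype=int)
            # deterministic label order: by smallest member index
            comms = sorted(comms, key=min)
            for lab, nodes in enumerate(comms):
                labels[list(nodes)] = lab
            return Clustering.from_labels(
                labels,
                _coords_of(cell_graph),
                n_initial=len(comms),
                resolution=resolution,
                sort_by_size=False,
            )
        resolution *= 1.5
    raise RuntimeError(
        f"over-segmentation failure: could not reach N > k={k} communities "
        f"for {n} cells within {max_rounds} resolution escalations "
        f"(last N = {len(comms)})"
    )


def _coords_of(cell_graph: CellGraph) -> np.ndarray:
    # coordinates are attached by partition(); stand-alone graphs fall back
    # to zeros (centroids then meaningless but shapes stay valid)
    coords = getattr(cell_graph, "_coords", None)
    if coords is None:
        coords = np.zeros((cell_graph.n_cells, 2))
    return coords


class _MergeEngine:
    """Greedy centroid merging with adjacency priority.

    Repeatedly merges the adjacent (>= 1 inter-cluster edge) cluster pair
    with the smallest centroid distance; when no adjacent pair remains and
    more merges are needed, falls back to the globally closest centroid
    pair.  Ties break on the lexicographically smallest (label_a, label_b).

    Adjacency shrinks monotonically and, once exhausted, never returns (a
    merge of two edge-less clusters is edge-less), so the schedule is two
    clean phases: a lazy min-heap over adjacent pairs, then vectorized
    global nearest-centroid agglomeration over whatever clusters remain.
    """

    def __init__(self, labels: np.ndarray, graph: nx.Graph, coords: np.ndarray):
        self.coords = coords
        self.members: dict[int, list[int]] = {}
        for idx, lab in enumerate(labels):
            self.members.setdefault(int(lab), []).append(idx)
        self.centroid = {
            lab: coords[m].mean(axis=0) for lab, m in self.members.items()
        }
        self.adj: dict[int, set[int]] = {lab: set() for lab in self.members}
        for i, j in graph.edges():
            a, b = int(labels[i]), int(labels[j])
            if a != b:
                self.adj[a].add(b)
                self.adj[b].add(a)
        self.version = {lab: 0 for lab in self.members}
        self.h_adj: list[tuple] = []
        for a in self.adj:
            for b in self.adj[a]:
                if a < b:
                    self._push_adj(a, b)
        # phase-B state, built lazily when adjacency runs out
        self._dmat: Optional[np.ndarray] = None
        self._order: list[int] = []

    def _dist(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.centroid[a] - self.centroid[b]))

    def _push_adj(self, a: int, b: int) -> None:
        if a > b:
            a, b = b, a
        heapq.heappush(
            self.h_adj, (self._dist(a, b), a, b, self.version[a], self.version[b])
        )

    def _pop_adjacent(self) -> Optional[tuple[int, int]]:
        while self.h_adj:
            _, a, b, va, vb = heapq.heappop(self.h_adj)
            if (
                a in self.members
                and b in self.members
                and self.version[a] == va
                and self.version[b] == vb
                and b in self.adj[a]
            ):
                return a, b
        return None

    def _enter_global_phase(self) -> None:
        from scipy.spatial.distance import cdist

        self._order = sorted(self.members)
        cents = np.array([self.centroid[l] for l in self._order])
        self._dmat = cdist(cents, cents)
        np.fill_diagonal(self._dmat, np.inf)
        self._pos = {l: i for i, l in enumerate(self._order)}
        self._cent_arr = cents
        # cached per-row minima: global argmin in O(c) per step, O(c^2) total
        self._row_min = self._dmat.min(axis=1)
        self._row_arg = self._dmat.argmin(axis=1)

    def _pop_global(self) -> tuple[int, int]:
        i = int(np.argmin(self._row_min))
        j = int(self._row_arg[i])
        if i > j:
            i, j = j, i
        return self._order[i], self._order[j]

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def merge_once(self) -> None:
        if self.n_clusters < 2:  # pragma: no cover - k>N misuse
            raise RuntimeError("no cluster pair left to merge")
        pair = None
        if self._dmat is None:
            pair = self._pop_adjacent()
            if pair is None:
                self._enter_global_phase()
        if pair is None:
            pair = self._pop_global()
        a, b = pair  # a < b; merged cluster keeps label a
        self.members[a].extend(self.members[b])
        self.centroid[a] = self.coords[self.members[a]].mean(axis=0)
        if self._dmat is None:
            self.adj[a] = (self.adj[a] | self.adj[b]) - {a, b}
            for nb in self.adj.pop(b):
                self.adj[nb].discard(b)
                if nb != a:
                    self.adj[nb].add(a)
            del self.members[b], self.centroid[b], self.version[b]
            self.version[a] += 1
            for nb in self.adj[a]:
                self._push_adj(a, nb)
        else:
            ia, ib = self._pos[a], self._pos[b]
            del self.members[b], self.centroid[b], self.version[b]
            self._cent_arr[ia] = self.centroid[a]
            alive = np.array([self._pos[l] for l in self.members])
            d = np.full(self._dmat.shape[1], np.inf)
            diff = self._cent_arr[alive] - self.centroid[a]
            d[alive] = np.sqrt((diff * diff).sum(axis=1))
            d[ia] = np.inf
            self._dmat[ia, :] = d
            self._dmat[:, ia] = d
            self._dmat[ib, :] = np.inf
            self._dmat[:, ib] = np.inf
            # refresh row-min caches
            self._row_min[ib] = np.inf
            self._row_min[ia] = d.min()
            self._row_arg[ia] = int(d.argmin())
            improved = d < self._row_min
            improved[[ia, ib]] = False
            self._row_min[improved] = d[improved]
            self._row_arg[improved] = ia
            stale = np.flatnonzero(
                (~improved)
                & ((self._row_arg == ia) | (self._row_arg == ib))
                & np.isfinite(self._row_min)
            )
            for r in stale:
                if r == ia:
                    continue
                self._row_min[r] = self._dmat[r].min()
                self._row_arg[r] = int(self._dmat[r].argmin())

    def labels(self) -> np.ndarray:
        out = np.empty(len(self.coords), dtype=int)
        for lab, m in self.members.items():
            out[m] = lab
        return out


def merge_to_k(
    clustering: Clustering,
    cell_graph: CellGraph,
    emb: Embedding2D,
    k: int,
) -> Clustering:
    """Merge the N-cluster over-segmentation down to exactly k clusters.

    Each step merges the adjacent pair with minimum centroid distance (the
    merged centroid is recomputed from member cells); disconnected leftovers
    are merged by global centroid distance.  Output labels are re-indexed
    0..k-1 by descending cluster size.
    """
    if k < 1 or k > clustering.k:
        raise ValueError(f"k must lie in 1..{clustering.k}, got {k}")
    engine = _MergeEngine(clustering.labels, cell_graph.graph, emb.coords)
    while engine.n_clusters > k:
        engine.merge_once()
    return Clustering.from_labels(
        engine.labels(),
        emb.coords,
        n_initial=clustering.n_initial or clustering.k,
        resolution=clustering.resolution,
    )


def _singleton_clustering(emb: Embedding2D) -> Clustering:
    n = emb.n_cells
    return Clustering(
        labels=np.arange(n),
        centroids=emb.coords.copy(),
        sizes=np.ones(n, dtype=int),
        n_initial=n,
        resolution=None,
    )


def partition(
    emb: Embedding2D,
    k: int,
    params: GraphParams = GraphParams(),
    seed: Optional[int] = None,
) -> Clustering:
    """Full k-partitioning: scale, build graph, over-segment, merge to k.

    ``k = n_cells`` short-circuits to the singleton clustering (each cell
    its own cluster), the exact identity limit of the method.
    """
    n = emb.n_cells
    if k < 1 or k > n:
        raise ValueError(f"k must lie in 1..{n}, got {k}")
    if k == n:
        return _singleton_clustering(emb)
    scaled = scale_embedding(emb, params.half_range)
    graph = build_cell_graph(scaled, params)
    graph._coords = scaled.coords
    over = louvain_oversegment(graph, k, seed=seed)
    return merge_to_k(over, graph, scaled, k)


def partition_series(
    emb: Embedding2D,
    ks: Sequence[int],
    params: GraphParams = GraphParams(),
    seed: Optional[int] = None,
) -> ClusterSeries:
    """One over-segmentation, one merge path, snapshots at every k in ``ks``.

    The shared merge path guarantees nesting: the clustering at a smaller k
    is a coarsening of the clustering at every larger k in the series.
    """
    ks = sorted(int(k) for k in ks)
    n = emb.n_cells
    if not ks:
        raise ValueError("ks must be non-empty")
    if ks[0] < 1 or ks[-1] > n:
        raise ValueError(f"every k must lie in 1..{n}")
    if len(set(ks)) != len(ks):
        raise ValueError("duplicate k values")
    series = ClusterSeries(ks=ks)
    merge_ks = [k for k in ks if k < n]
    if ks[-1] == n:
        series.clusterings[n] = _singleton_clustering(emb)
    if merge_ks:
        scaled = scale_embedding(emb, params.half_range)
        graph = build_cell_graph(scaled, params)
        graph._coords = scaled.coords
        over = louvain_oversegment(graph, merge_ks[-1], seed=seed)
        engine = _MergeEngine(over.labels, graph.graph, scaled.coords)
        for k in reversed(merge_ks):
            while engine.n_clusters > k:
                engine.merge_once()
            series.clusterings[k] = Clustering.from_labels(
                engine.labels(),
                scaled.coords,
                n_initial=over.n_initial,
                resolution=over.resolution,
            )
    return series


def cells_per_cluster_summary(
    clustering: Clustering, size_threshold: int = 10
) -> tuple[pd.DataFrame, dict]:
    """Per-cluster sizes plus the expected size n_assigned / k.

    The expected cells-per-cluster under unbiased partitioning is simply the
    assigned cell count divided by the number of clusters; the summary also
    reports min/median/max and how many clusters fall below
    ``size_threshold`` (candidates for removal or merging).
    """
    table = pd.DataFrame(
        {"cluster": np.arange(clustering.k), "size": clustering.sizes}
    )
    expected = clustering.n_assigned / clustering.k
    summary = {
        "k": clustering.k,
        "n_assigned": clustering.n_assigned,
        "expected_size": expected,
        "min_size": int(clustering.sizes.min()),
        "median_size": float(np.median(clustering.sizes)),
        "max_size": int(clustering.sizes.max()),
        "n_below_threshold": int((clustering.sizes < size_threshold).sum()),
        "size_threshold": size_threshold,
    }
    return table, summary


def filter_small_clusters(
    clustering: Clustering,
    min_cells: int = 10,
    mode: str = "merge",
) -> tuple[Clustering, dict]:
    """Remove or absorb clusters with fewer than ``min_cells`` cells.

    mode="merge": each undersized cluster is absorbed into its
    nearest-centroid neighbor, iterating (smallest first) until every
    remaining cluster has >= min_cells cells or one cluster remains.
    mode="drop": undersized clusters' cells are marked unassigned (-1).
    Returns the filtered clustering and a report of affected clusters.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if mode not in ("merge", "drop"):
        raise ValueError(f"mode must be 'merge' or 'drop', got {mode!r}")
    labels = clustering.labels.copy()
    affected: list[int] = []
    if mode == "drop":
        for lab in range(clustering.k):
            if clustering.sizes[lab] < min_cells:
                labels[labels == lab] = -1
                affected.append(lab)
        coords_proxy = _centroid_proxy_coords(clustering)
        out = Clustering.from_labels(labels, coords_proxy) if (labels >= 0).any() else Clustering(
            labels, np.zeros((0, 2)), np.zeros(0, dtype=int)
        )
    else:
        cents = {lab: clustering.centroids[lab].copy() for lab in range(clustering.k)}
        sizes = {lab: int(clustering.sizes[lab]) for lab in range(clustering.k)}
        while len(sizes) > 1:
            small = [lab for lab, s in sizes.items() if s < min_cells]
            if not small:
                break
            lab = min(small, key=lambda l: (sizes[l], l))
            others = [o for o in sizes if o != lab]
            target = min(
                others, key=lambda o: (np.linalg.norm(cents[o] - cents[lab]), o)
            )
            labels[labels == lab] = target
            tot = sizes[lab] + sizes[target]
            cents[target] = (
                cents[target] * sizes[target] + cents[lab] * sizes[lab]
            ) / tot
            sizes[target] = tot
            del sizes[lab], cents[lab]
            affected.append(lab)
        coords_proxy = _centroid_proxy_coords(clustering)
        out = Clustering.from_labels(labels, coords_proxy)
    report = {
        "mode": mode,
        "min_cells": min_cells,
        "n_affected": len(affected),
        "affected_clusters": affected,
        "n_unassigned": int((out.labels < 0).sum()),
    }
    return out, report


def _centroid_proxy_coords(clustering: Clustering) -> np.ndarray:
    """Per-cell coordinates reconstructed as each cell's cluster centroid.

    Used when only the clustering (not the embedding) is available; exact
    member coordinates are unnecessary for relabeling, and centroids of
    merged clusters computed from these proxies equal the size-weighted
    centroid means, which equal the true member means.
    """
    coords = np.zeros((clustering.n_cells, 2))
    for lab in range(clustering.k):
        coords[clustering.labels == lab] = clustering.centroids[lab]
    return coords


class GraphKPartitioner(ClusterMixin, BaseEstimator):
    """Scikit-learn-style estimator for graph-based k-partitioning.

    Fits on an (n_cells, 2) embedding array and exposes the mini-cluster
    assignment as ``labels_``.  Composes with sklearn model-selection
    utilities via ``get_params`` / ``set_params``.

    Parameters
    ----------
    k : int
        Number of mini-clusters to produce.
    cutoff : float, default 3.0
        Edge-length threshold in scaled embedding units.
    half_range : float or "auto", default "auto"
        Coordinate scaling target (max absolute coordinate after scaling).
    weight_mode : str, default "inverted-distance"
        Edge-weight transform for Louvain modularity.
    min_cells : int or None, default None
        If set, clusters smaller than this are filtered after partitioning.
    small_mode : {"merge", "drop"}, default "merge"
        How undersized clusters are filtered when ``min_cells`` is set.
    random_state : int, RandomState or None
        Seeds the Louvain over-segmentation.

    Attributes
    ----------
    labels_ : ndarray of shape (n_cells,)
        Cluster label per cell (-1 when dropped by filtering).
    centroids_ : ndarray of shape (k, 2)
    cluster_sizes_ : ndarray of shape (k,)
    n_communities_ : int
        Louvain community count N before merging (N > k).
    resolution_ : float or None
        Final Louvain resolution used.
    """

    def __init__(
        self,
        k: int = 100,
        cutoff: float = 3.0,
        half_range: Union[float, str] = "auto",
        weight_mode: str = "inverted-distance",
        min_cells: Optional[int] = None,
        small_mode: str = "merge",
        random_state=None,
    ):
        self.k = k
        self.cutoff = cutoff
        self.half_range = half_range
        self.weight_mode = weight_mode
        self.min_cells = min_cells
        self.small_mode = small_mode
        self.random_state = random_state

    def _seed(self) -> int:
        rs = check_random_state(self.random_state)
        return int(rs.randint(0, 2**31 - 1)) if self.random_state is not None else 0

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        if X.shape[1] != 2:
            raise ValueError(f"expected a 2D embedding, got {X.shape[1]} columns")
        emb = Embedding2D(np.arange(len(X)).astype(object), X)
        params = GraphParams(
            cutoff=self.cutoff,
            half_range=self.half_range,
            weight_mode=self.weight_mode,
        )
        clustering = partition(emb, self.k, params=params, seed=self._seed())
        if self.min_cells is not None:
            clustering, report = filter_small_clusters(
                clustering, min_cells=self.min_cells, mode=self.small_mode
            )
            self.filter_report_ = report
        self.clustering_ = clustering
        self.labels_ = clustering.labels
        self.centroids_ = clustering.centroids
        self.cluster_sizes_ = clustering.sizes
        self.n_communities_ = clustering.n_initial
        self.resolution_ = clustering.resolution
        self.n_features_in_ = 2
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
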