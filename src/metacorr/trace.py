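"""Cluster evolution tracing across a series of k values.

As k grows along one merge path, clusters split; the resulting parent/child
relations form a forest whose levels are the k values.  The tree (plus
deterministic ladder and circular layouts) lets users pick a cluster number
by inspecting how stable the partition is across k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .graph import ClusterSeries

__all__ = ["EvolutionTree", "build_tree", "layout_ladder", "layout_circle", "render_tree"]

NodeId = tuple[int, int]  # (k level, cluster label)


@dataclass
class EvolutionTree:
    """Forest of cluster splits across ascending k levels.

    nodes map (k, label) -> size; edges connect a cluster at one level to
    its best-overlapping cluster at the previous (smaller-k) level, carrying
    the overlap cell count.  For a nested series the overlap equals the
    child size (the child is a subset of its parent).
    """

    levels: list[int]
    nodes: dict[NodeId, int] = field(default_factory=dict)
    edges: list[tuple[NodeId, NodeId, int]] = field(default_factory=list)

    def children(self, node: NodeId) -> list[NodeId]:
        return [c for p, c, _ in self.edges if p == node]

    def parent(self, node: NodeId) -> Union[NodeId, None]:
        for p, c, _ in self.edges:
            if c == node:
                return p
        return None

    def level_nodes(self, k: int) -> list[NodeId]:
        return sorted(n for n in self.nodes if n[0] == k)

    def is_nested(self) -> bool:
        """True when every edge's overlap equals the child's full size."""
        return all(ov == self.nodes[c] for _, c, ov in self.edges)


def _level_labels(series_or_labels) -> tuple[list[int], list[np.ndarray]]:
    if isinstance(series_or_labels, ClusterSeries):
        ks = list(series_or_labels.ks)
        labels = [series_or_labels[k].labels for k in ks]
    else:
        labels = [np.asarray(l) for l in series_or_labels]
        ks = [int(l.max()) + 1 for l in labels]
    return ks, labels


def build_tree(series) -> EvolutionTree:
    """Link clusters across levels by maximal cell overlap.

    Accepts a :class:`~metacorr.graph.ClusterSeries` or a plain list of
    per-cell label vectors (ascending cluster counts).  The parent of a
    cluster at level i is the level i-1 cluster sharing the most cells;
    ties break toward the smaller parent label.  Cells labeled -1
    (unassigned) are ignored.
    """
    ks, labels = _level_labels(series)
    if len(ks) < 1:
        raise ValueError("need at least one level")
    n = len(labels[0])
    if any(len(l) != n for l in labels):
        raise ValueError("levels cover inconsistent cell sets (different lengths)")

    tree = EvolutionTree(levels=ks)
    for k, lab in zip(ks, labels):
        assigned = lab[lab >= 0]
        sizes = np.bincount(assigned)
        for c, s in enumerate(sizes):
            tree.nodes[(k, c)] = int(s)

    for i in range(1, len(ks)):
        parent_lab, child_lab = labels[i - 1], labels[i]
        mask = (parent_lab >= 0) & (child_lab >= 0)
        # contingency: rows = child clusters, cols = parent clusters
        ct = pd.crosstab(child_lab[mask], parent_lab[mask])
        for child in ct.index:
            row = ct.loc[child]
            best = row.max()
            parent = int(min(row.index[row == best]))  # tie -> smaller label
            tree.edges.append(
                ((ks[i - 1], parent), (ks[i], int(child)), int(best))
            )
    return tree


def _subtree_leaf_size(tree: EvolutionTree, node: NodeId, child_map) -> int:
    kids = child_map.get(node, [])
    if not kids:
        return tree.nodes[node]
    return sum(_subtree_leaf_size(tree, c, child_map) for c in kids)


def _child_map(tree: EvolutionTree) -> dict[NodeId, list[NodeId]]:
    cm: dict[NodeId, list[NodeId]] = {}
    for p, c, _ in tree.edges:
        cm.setdefault(p, []).append(c)
    for kids in cm.values():
        kids.sort()
    return cm


def layout_ladder(tree: EvolutionTree, radius_scale: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ladder (top-down) layout: one row per level, children under parents.

    Returns (nodes, edges) tables.  Node rows carry level row index (y),
    horizontal slot (x) and a dot radius proportional to sqrt(size) (so dot
    *area* is proportional to cell number), scaled by ``radius_scale``.
    Deterministic for a given tree.
    """
    cm = _child_map(tree)
    roots = tree.level_nodes(tree.levels[0])
    # horizontal slots assigned by DFS leaf order; parents centered over children
    x: dict[NodeId, float] = {}
    next_slot = [0.0]

    def place(node: NodeId) -> float:
        kids = cm.get(node, [])
        if not kids:
            x[node] = next_slot[0]
            next_slot[0] += 1.0
        else:
            x[node] = float(np.mean([place(c) for c in kids]))
        return x[node]

    for r in roots:
        place(r)
    # any node not reachable from a root (non-nested inputs) gets appended
    for node in sorted(tree.nodes):
        if node not in x:
            x[node] = next_slot[0]
            next_slot[0] += 1.0

    level_row = {k: i for i, k in enumerate(tree.levels)}
    rows = [
        {
            "k": node[0],
            "cluster": node[1],
            "row": level_row[node[0]],
            "x": x[node],
            "y": -float(level_row[node[0]]),
            "size": tree.nodes[node],
            "radius": radius_scale * np.sqrt(tree.nodes[node]),
        }
        for node in sorted(tree.nodes)
    ]
    nodes_df = pd.DataFrame(rows)
    edges_df = pd.DataFrame(
        [
            {
                "parent_k": p[0],
                "parent_cluster": p[1],
                "child_k": c[0],
                "child_cluster": c[1],
                "overlap": ov,
                "x0": x[p],
                "y0": -float(level_row[p[0]]),
                "x1": x[c],
                "y1": -float(level_row[c[0]]),
            }
            for p, c, ov in tree.edges
        ]
    )
    return nodes_df, edges_df


def layout_circle(tree: EvolutionTree, radius_scale: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Circular layout: smallest k on the innermost ring.

    Each node receives an angular span proportional to its subtree leaf
    size; children's spans partition their parent's span, so every ring's
    spans sum to 360 degrees.  Node angle = span midpoint.
    """
    cm = _child_map(tree)
    roots = tree.level_nodes(tree.levels[0])
    total = sum(_subtree_leaf_size(tree, r, cm) for r in roots)
    if total == 0:
        raise ValueError("empty tree")
    span: dict[NodeId, tuple[float, float]] = {}

    def allocate(node: NodeId, a0: float, a1: float) -> None:
        span[node] = (a0, a1)
        kids = cm.get(node, [])
        if not kids:
            return
        weights = np.array([_subtree_leaf_size(tree, c, cm) for c in kids], float)
        bounds = a0 + np.concatenate([[0.0], np.cumsum(weights)]) / weights.sum() * (a1 - a0)
        for c, b0, b1 in zip(kids, bounds[:-1], bounds[1:]):
            allocate(c, b0, b1)

    start = 0.0
    for r in roots:
        frac = _subtree_leaf_size(tree, r, cm) / total
        allocate(r, start, start + 360.0 * frac)
        start += 360.0 * frac

    level_ring = {k: i + 1 for i, k in enumerate(tree.levels)}
    rows = []
    for node in sorted(tree.nodes):
        if node not in span:  # orphan in non-nested input: zero-width span
            span[node] = (0.0, 0.0)
        a0, a1 = span[node]
        rows.append(
            {
                "k": node[0],
                "cluster": node[1],
                "ring": level_ring[node[0]],
                "angle": (a0 + a1) / 2.0,
                "span_start": a0,
                "span_end": a1,
                "size": tree.nodes[node],
                "radius": radius_scale * np.sqrt(tree.nodes[node]),
            }
        )
    nodes_df = pd.DataFrame(rows)
    edges_df = pd.DataFrame(
        [
            {
                "parent_k": p[0],
                "parent_cluster": p[1],
                "child_k": c[0],
                "child_cluster": c[1],
                "overlap": ov,
            }
            for p, c, ov in tree.edges
        ]
    )
    return nodes_df, edges_df


def render_tree(tree: EvolutionTree, style: str = "ladder", path=None):
    """Optional matplotlib rendering of a layout (thin layer; the layout
    tables above are the tested surface)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if style == "ladder":
        nodes, edges = layout_ladder(tree)
        fig, ax = plt.subplots(figsize=(8, 5))
        for _, e in edges.iterrows():
            ax.plot([e.x0, e.x1], [e.y0, e.y1], "-", color="0.6", lw=0.8, zorder=1)
        ax.scatter(nodes.x, nodes.y, s=10 * nodes["size"] / max(nodes["size"].max(), 1),
                   zorder=2)
        ax.set_yticks(-np.arange(len(tree.levels)))
        ax.set_yticklabels([f"k={k}" for k in tree.levels])
        ax.set_xticks([])
    elif style == "circle":
        nodes, edges = layout_circle(tree)
        fig, ax = plt.subplots(figsize=(6, 6))
        theta = np.deg2rad(nodes.angle)
        r = nodes.ring
        xs, ys = r * np.cos(theta), r * np.sin(theta)
        pos = {(k, c): (x_, y_) for k, c, x_, y_ in zip(nodes.k, nodes.cluster, xs, ys)}
        for _, e in edges.iterrows():
            p = pos[(e.parent_k, e.parent_cluster)]
            c = pos[(e.child_k, e.child_cluster)]
            ax.plot([p[0], c[0]], [p[1], c[1]], "-", color="0.6", lw=0.8, zorder=1)
        ax.scatter(xs, ys, s=10 * nodes["size"] / max(nodes["size"].max(), 1), zorder=2)
        ax.set_aspect("equal")
        ax.axis("off")
    else:
        raise ValueError(f"unknown style {style!r}")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
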