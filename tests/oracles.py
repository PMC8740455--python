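"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (brute force, closed forms, full
rescans) and shares no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_force_edges(coords: np.ndarray, cutoff: float) -> set[tuple[int, int]]:
    """All-pairs distance thresholding, O(n^2)."""
    n = len(coords)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                edges.add((i, j))
    return edges


def greedy_merge_oracle(labels0, graph, coords, k) -> np.ndarray:
    """Spec-literal greedy merging: rescan every cluster pair each step.

    Adjacent pairs (>= 1 inter-cluster edge) take priority; ties break on
    the smallest (label_a, label_b); without adjacent pairs the globally
    closest centroid pair merges.  Centroids recomputed from member cells.
    """
    members: dict[int, list[int]] = {}
    for i, lab in enumerate(labels0):
        members.setdefault(int(lab), []).append(i)
    adj: dict[int, set[int]] = {lab: set() for lab in members}
    for i, j in graph.edges():
        a, b = int(labels0[i]), int(labels0[j])
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    while len(members) > k:
        cents = {lab: coords[m].mean(axis=0) for lab, m in members.items()}
        cand = [(a, b) for a in members for b in members if a < b and b in adj[a]]
        if not cand:
            cand = [(a, b) for a in members for b in members if a < b]
        best = None
        for a, b in cand:
            d = float(np.linalg.norm(cents[a] - cents[b]))
            if best is None or (d, a, b) < best:
                best = (d, a, b)
        _, a, b = best
        members[a].extend(members.pop(b))
        adj[a] = (adj[a] | adj[b]) - {a, b}
        for nb in adj.pop(b):
            nb_set = adj[nb]
            nb_set.discard(b)
            if nb != a:
                nb_set.add(a)
    out = np.empty(len(coords), dtype=int)
    for lab, m in members.items():
        out[m] = lab
    return out


def pearson_t_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form correlation t-test: t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * stats.t.sf(abs(t), n - 2))


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the textbook recipe.

    q(i) = min over j >= i of p(j) * m / j on the sorted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def max_overlap_parents(parent_labels: np.ndarray, child_labels: np.ndarray) -> dict[int, int]:
    """Contingency-table argmax-overlap parent per child cluster (ties ->
    smaller parent label)."""
    parents = {}
    for c in np.unique(child_labels[child_labels >= 0]):
        mask = child_labels == c
        vals, counts = np.unique(parent_labels[mask & (parent_labels >= 0)],
                                 return_counts=True)
        best = counts.max()
        parents[int(c)] = int(min(vals[counts == best]))
    return parents


def auc_by_ranks(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(equal)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((pos[:, None] > neg[None, :]).sum() for _ in [0])
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
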