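"""Cluster-level and single-cell gene-gene correlation with FDR control.

Within-cluster arithmetic averaging (zeros included) turns k mini-clusters
into k pseudo-observations per gene; Pearson (or Spearman) correlation over
those pseudo-observations recovers gene-gene relationships that dropout
zeros obscure at single-cell resolution.  P-values come from the Gaussian
linear-model slope test, which for a simple regression is exactly the
classical correlation t-test, t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees
of freedom; multiplicity is handled with Benjamini-Hochberg across all
non-degenerate tested pairs.

Each cluster contributes one unweighted observation, matching per-cluster
averaging; a size-weighted variant is available behind ``weighted=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph import Clustering, Embedding2D, GraphParams, partition, partition_series
from .matrix import ExpressionMatrix

__all__ = [
    "ClusterProfile",
    "GenePairResult",
    "cluster_profile",
    "correlate_pair",
    "correlate_pairs",
    "compare_cluster_vs_cell",
    "stability_scan",
]

RESULT_COLUMNS = [
    "gene_a", "gene_b", "method", "n_units",
    "r", "r_spearman", "p", "q", "significant", "status",
]


@dataclass
class ClusterProfile:
    """k x genes matrix of within-cluster mean expression (zeros included)."""

    labels: np.ndarray          # cluster labels 0..k-1, row order
    genes: np.ndarray
    values: np.ndarray          # (k, n_genes) dense means
    sizes: np.ndarray

    @property
    def k(self) -> int:
        return len(self.labels)

    def gene_values(self, gene: str) -> np.ndarray:
        idx = np.flatnonzero(self.genes == gene)
        if not len(idx):
            raise KeyError(f"gene {gene!r} not in profile")
        return self.values[:, idx[0]]


@dataclass
class GenePairResult:
    """Correlation estimate for one gene pair over one set of units."""

    gene_a: str
    gene_b: str
    r: float
    p: float
    n_units: int
    method: str = "cluster"
    r_spearman: Optional[float] = None
    q: Optional[float] = None
    status: str = "ok"


def cluster_profile(expr: ExpressionMatrix, clustering: Clustering) -> ClusterProfile:
    """Average each gene over the member cells of every cluster.

    Zeros count toward the mean (they are the signal the averaging is meant
    to dilute).  Cells marked unassigned (label -1) are excluded.  The
    size-weighted mean of the cluster means reproduces the global per-gene
    mean over assigned cells exactly.
    """
    if expr.n_cells != clustering.n_cells:
        raise ValueError(
            f"expression has {expr.n_cells} cells but clustering covers "
            f"{clustering.n_cells}"
        )
    k = clustering.k
    if k == 0 or (clustering.sizes == 0).any():
        raise RuntimeError("clustering contains an empty cluster")
    labels = clustering.labels
    assigned = labels >= 0
    # indicator (cells x k), sparse: profile = (X @ I) / sizes
    ind = sp.csr_matrix(
        (
            np.ones(assigned.sum()),
            (np.flatnonzero(assigned), labels[assigned]),
        ),
        shape=(expr.n_cells, k),
    )
    sums = expr.values @ ind  # genes x k
    sums = np.asarray(sums.todense()) if sp.issparse(sums) else np.asarray(sums)
    means = (sums / clustering.sizes[None, :]).T  # k x genes
    return ClusterProfile(
        labels=np.arange(k),
        genes=expr.genes,
        values=means,
        sizes=clustering.sizes.copy(),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided linear-model (t-test) p-value."""
    n = len(x)
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    r = float(np.clip((xd @ yd) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_pair(
    x: np.ndarray, y: np.ndarray, method: str = "pearson",
    gene_a: str = "x", gene_b: str = "y", unit_method: str = "cluster",
) -> GenePairResult:
    """Correlate two value vectors over matched units.

    ``method="pearson"`` gives the product-moment coefficient; "spearman"
    rank-transforms both vectors first and applies the same machinery.  A
    constant input vector yields a degenerate result (no r/p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 units, got {n}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return GenePairResult(
            gene_a, gene_b, r=np.nan, p=np.nan, n_units=n,
            method=unit_method, status="degenerate",
        )
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    r, p = _pearson(x, y)
    rs = None
    if method == "pearson":
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        if np.ptp(rx) > 0 and np.ptp(ry) > 0:
            rs = _pearson(rx, ry)[0]
    return GenePairResult(
        gene_a, gene_b, r=r, p=p, n_units=n,
        method=unit_method, r_spearman=rs, status="ok",
    )


def _unit_matrix(data) -> tuple[np.ndarray, np.ndarray, str]:
    """(units x genes dense array, gene ids, method tag) from profile/matrix."""
    if isinstance(data, ClusterProfile):
        return data.values, data.genes, "cluster"
    if isinstance(data, ExpressionMatrix):
        vals = data.toarray().T  # cells x genes
        return vals, data.genes, "cell"
    raise TypeError("expected a ClusterProfile or ExpressionMatrix")


def correlate_pairs(
    data,
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    method: str = "pearson",
    weighted: bool = False,
    sizes: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Correlate a list of gene pairs over clusters or cells, with BH FDR.

    Parameters
    ----------
    data : ClusterProfile or ExpressionMatrix
        Units are clusters (profile rows) or cells respectively.
    pairs : list of (gene_a, gene_b)
        Pairs whose genes are missing from ``data`` are reported with
        status "missing" and excluded from testing.
    alpha : float
        BH significance level on q-values (the FDR < alpha rule).
    weighted : bool
        If True (cluster profiles only), the correlation is size-weighted:
        each cluster's observation is centered at the weighted mean and
        scaled by sqrt(cluster size).  Default False matches the
        one-cluster-one-observation convention of per-cluster averaging.

    Returns a DataFrame sorted by p (missing/degenerate rows last) with
    columns gene_a, gene_b, method, n_units, r, r_spearman, p, q,
    significant, status.  BH adjusts over the non-degenerate tested pairs
    only.
    """
    if not len(pairs):
        raise ValueError("empty pair list")
    units, genes, tag = _unit_matrix(data)
    if weighted:
        if not isinstance(data, ClusterProfile) and sizes is None:
            raise ValueError("weighted correlation needs cluster sizes")
        w = np.sqrt(sizes if sizes is not None else data.sizes).astype(float)
    gene_idx = {g: i for i, g in enumerate(genes)}
    rows: list[GenePairResult] = []
    for a, b in pairs:
        if a not in gene_idx or b not in gene_idx:
            rows.append(GenePairResult(a, b, np.nan, np.nan, 0, tag, status="missing"))
            continue
        x = units[:, gene_idx[a]]
        y = units[:, gene_idx[b]]
        if weighted:
            x, y = _weighted_center_scale(x, w), _weighted_center_scale(y, w)
        rows.append(correlate_pair(x, y, method=method, gene_a=a, gene_b=b, unit_method=tag))

    df = pd.DataFrame(
        {
            "gene_a": [r.gene_a for r in rows],
            "gene_b": [r.gene_b for r in rows],
            "method": [r.method for r in rows],
            "n_units": [r.n_units for r in rows],
            "r": [r.r for r in rows],
            "r_spearman": [r.r_spearman for r in rows],
            "p": [r.p for r in rows],
            "status": [r.status for r in rows],
        }
    )
    ok = df.status == "ok"
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.values] = multipletests(df.loc[ok, "p"].values, method="fdr_bh")[1]
    df["q"] = q
    df["significant"] = (df.q < alpha).fillna(False)
    df = df[RESULT_COLUMNS].sort_values(
        ["status", "p"], key=lambda s: s.map({"ok": 0, "degenerate": 1, "missing": 2}) if s.name == "status" else s,
        kind="stable",
    ).reset_index(drop=True)
    return df


def _weighted_center_scale(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Transform so unweighted Pearson on the result equals size-weighted
    Pearson on the input: center at the weighted mean, scale by sqrt(w)."""
    mu = np.average(v, weights=w * w)
    return (v - mu) * w


def compare_cluster_vs_cell(
    expr: ExpressionMatrix,
    emb: Embedding2D,
    pairs: Sequence[tuple[str, str]],
    k: int,
    params: GraphParams = GraphParams(),
    seed: Optional[int] = None,
    alpha: float = 0.05,
    clustering: Optional[Clustering] = None,
) -> tuple[pd.DataFrame, dict]:
    """Side-by-side correlation at single-cell vs mini-cluster resolution.

    Runs :func:`correlate_pairs` on the raw cells and on the k-cluster
    profile of the same data, joins per pair, and reports direction
    agreement plus detection counts.  At k = n_cells the two columns are
    identical (clusters of size one).
    """
    cell_res = correlate_pairs(expr, pairs, alpha=alpha)
    if clustering is None:
        clustering = partition(emb, k, params=params, seed=seed)
    prof = cluster_profile(expr, clustering)
    clus_res = correlate_pairs(prof, pairs, alpha=alpha)

    merged = cell_res.merge(
        clus_res,
        on=["gene_a", "gene_b"],
        suffixes=("_cell", "_cluster"),
    )
    merged["agreement"] = np.sign(merged.r_cell) == np.sign(merged.r_cluster)
    n_cell = int(merged.significant_cell.sum())
    n_clus = int(merged.significant_cluster.sum())
    n_both = int((merged.significant_cell & merged.significant_cluster).sum())
    summary = {
        "k": clustering.k,
        "n_pairs": len(merged),
        "significant_cell": n_cell,
        "significant_cluster": n_clus,
        "significant_both": n_both,
        "significant_any": n_cell + n_clus - n_both,
        "agreement_fraction": float(merged.agreement.mean()) if len(merged) else np.nan,
    }
    return merged, summary


def stability_scan(
    expr: ExpressionMatrix,
    emb: Embedding2D,
    pairs: Sequence[tuple[str, str]],
    ks: Sequence[int],
    reference_k: int = 100,
    top_n: int = 10,
    params: GraphParams = GraphParams(),
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Track the reference-k top pairs across a series of cluster numbers.

    The ``top_n`` pairs are ranked by p-value at ``reference_k``; r and p
    are then recomputed at every k in ``ks`` along the same merge path
    (k = n_cells, if present, is the single-cell baseline).  The long-format
    output (k, gene_a, gene_b, r, p) feeds a stability line plot used to
    choose a working cluster number.
    """
    ks = sorted(set(int(k) for k in ks))
    if reference_k not in ks:
        raise ValueError(f"reference_k={reference_k} must be among ks")
    series = partition_series(emb, ks, params=params, seed=seed)
    profiles = {}
    for k in ks:
        if k == expr.n_cells:
            profiles[k] = expr
        else:
            profiles[k] = cluster_profile(expr, series[k])

    ref = correlate_pairs(profiles[reference_k], pairs)
    ok = ref[ref.status == "ok"]
    if len(ok) < top_n:
        import warnings

        warnings.warn(
            f"only {len(ok)} non-degenerate pairs available; truncating top_n"
        )
    top = list(ok.head(top_n)[["gene_a", "gene_b"]].itertuples(index=False, name=None))

    out = []
    for k in ks:
        res = correlate_pairs(profiles[k], top)
        res.insert(0, "k", k)
        out.append(res[["k", "gene_a", "gene_b", "n_units", "r", "r_spearman", "p", "q", "status"]])
    return pd.concat(out, ignore_index=True)
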