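"""Synthetic zero-inflated scRNA-seq data with known ground truth.

The generator emulates the situation the clustering method exploits: gene
expression varies smoothly across a low-dimensional cell-state manifold (here,
the 2D embedding itself), while observed values are censored by an
entry-wise Bernoulli dropout mask.  Averaging transcriptomically similar
cells then cancels dropout noise but preserves the shared latent signal.

Model
-----
* Cells belong to ``n_types`` populations laid out as uniform-density discs
  in the embedding plane (centroids ``type_separation`` apart, radius
  ``type_radius``).  Uniform discs mimic the near-constant point density of
  tSNE output, which the distance-thresholded graph construction assumes.
* Genes named in ``latent_pairs`` carry correlated log-scale signal split
  into two parts.  The shared part (variance ``sum of |rho|`` over the
  gene's partners) lives on smooth latent fields over the embedding — random
  Fourier features of the coordinates, orthonormalized across cells and
  mixed through a Cholesky factor so the requested cross-gene covariances
  are hit exactly.  The remainder is per-cell white noise.  Total log-scale
  variance is 1 and the expected log-scale correlation of each pair is its
  rho.  Cell-state signal is smooth (cells near each other co-vary), while
  gene-specific noise is not — exactly the structure cluster averaging
  exploits.
* All other genes are i.i.d. standard normal on the log scale (pure noise,
  valid null pairs).
* Optional marker genes receive a per-type log-mean shift so that cell
  populations are separable from expression (off by default).
* Latent expression is exp(log-scale value): log-normal, positive.
* Observed expression = latent, with each entry independently set to zero
  with probability ``zero_prob`` (optionally expression-dependent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph import Embedding2D
from .matrix import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "expected_merged_zero_fraction",
    "run_merge_simulation",
    "simulate_dataset",
    "zero_diagnostics",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dataset generator.

    Attributes
    ----------
    n_genes, n_cells : int
        Matrix dimensions.
    zero_prob : float in [0, 1]
        Per-entry probability that an observed value is censored to zero.
        Default 0.95, the typical zero abundance of droplet scRNA-seq.
    latent_pairs : sequence of (int, int, float)
        Ground-truth correlated gene pairs: indices of the two genes and the
        log-scale correlation rho in [-1, 1].
    n_types : int
        Number of cell populations (embedding blobs).
    type_separation : float
        Distance between adjacent disc centroids, in embedding units.
        The default leaves a clear gap between discs (distinct cell types
        occupy distinct embedding islands, as on a typical tSNE plot).
    type_radius : float
        Disc radius in embedding units; 50 mimics the typical +-50 span of
        raw tSNE coordinates.
    n_marker_genes : int
        Number of genes (taken from the end of the gene list) given a
        per-type mean shift, making types separable from expression.
    marker_shift : float
        Log-scale magnitude of that shift.
    field_lengthscale : float
        Smoothness of the latent signal fields, in units of the overall
        coordinate spread; 1.0 means signal varies on the scale of a whole
        blob, so mini-clusters are locally homogeneous.
    expression_dependent_dropout : bool
        If True, the dropout probability decreases logistically with latent
        magnitude (mean probability still ``zero_prob``); off by default,
        matching the plain Bernoulli design.
    seed : int
        Seed for all randomness in the generator.
    """

    n_genes: int
    n_cells: int
    zero_prob: float = 0.95
    latent_pairs: Sequence[tuple[int, int, float]] = field(default_factory=tuple)
    n_types: int = 1
    type_separation: float = 150.0
    type_radius: float = 50.0
    n_marker_genes: int = 0
    marker_shift: float = 0.0
    field_lengthscale: float = 1.0
    expression_dependent_dropout: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be positive")
        if not 0.0 <= self.zero_prob <= 1.0:
            raise ValueError(f"zero_prob must lie in [0, 1], got {self.zero_prob}")
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if self.type_separation < 0:
            raise ValueError("type_separation must be nonnegative")
        if self.type_radius <= 0:
            raise ValueError("type_radius must be positive")
        if self.n_marker_genes < 0 or self.n_marker_genes > self.n_genes:
            raise ValueError("n_marker_genes out of range")
        for a, b, rho in self.latent_pairs:
            if not (0 <= a < self.n_genes and 0 <= b < self.n_genes):
                raise ValueError(f"pair ({a}, {b}) indexes outside 0..{self.n_genes - 1}")
            if a == b:
                raise ValueError(f"pair ({a}, {b}): a gene cannot pair with itself")
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"pair ({a}, {b}): |rho| must be <= 1, got {rho}")


@dataclass
class SyntheticDataset:
    """Observed + latent expression, embedding, labels and the truth config."""

    expression: ExpressionMatrix
    latent: ExpressionMatrix
    embedding: Embedding2D
    cell_labels: np.ndarray
    truth: SimulationConfig


def expected_merged_zero_fraction(p: float, m: int) -> float:
    """Closed-form zero fraction after merging ``m`` cells.

    With independent per-entry zeros at rate ``p``, a gene's merged value
    over ``m`` cells is zero iff all ``m`` entries are zero: probability
    ``p**m``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"m must be a positive integer, got {m}")
    return float(p) ** int(m)


def run_merge_simulation(
    config: SimulationConfig,
    max_m: int,
    reps: int = 1000,
    ms: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Monte-Carlo zero fraction of merged random cell groups.

    For each group size ``m`` (1..``max_m``, or the explicit list ``ms``),
    draws ``reps`` random m-cell subsets, merges them by summing expression
    per gene, and records the fraction of genes whose merged value is exactly
    zero.  Under the independent Bernoulli dropout model the expectation is
    ``zero_prob ** m``; the empirical curve is non-increasing in ``m`` up to
    Monte-Carlo noise.

    Returns a DataFrame with columns ``m``, ``zero_fraction`` (mean over
    reps), ``se`` (standard error of that mean) and ``expected`` (closed
    form).
    """
    if max_m < 1:
        raise ValueError("max_m must be >= 1")
    if max_m > config.n_cells:
        raise ValueError(
            f"max_m={max_m} exceeds the number of cells ({config.n_cells})"
        )
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if ms is None:
        ms = range(1, max_m + 1)
    ms = [int(m) for m in ms]
    if any(m < 1 or m > max_m for m in ms):
        raise ValueError("every m must lie in 1..max_m")

    rng = np.random.default_rng(config.seed)
    # Only the zero pattern matters for this simulation: nonzero indicator
    # matrix genes x cells with per-entry nonzero probability 1 - p.
    nonzero = rng.random((config.n_genes, config.n_cells)) >= config.zero_prob

    rows = []
    for m in ms:
        fracs = np.empty(reps)
        for r in range(reps):
            cols = rng.choice(config.n_cells, size=m, replace=False)
            merged_nonzero = nonzero[:, cols].any(axis=1)
            fracs[r] = 1.0 - merged_nonzero.mean()
        se = fracs.std(ddof=1) / np.sqrt(reps) if reps > 1 else np.nan
        rows.append(
            {
                "m": m,
                "zero_fraction": fracs.mean(),
                "se": se,
                "expected": expected_merged_zero_fraction(config.zero_prob, m),
            }
        )
    return pd.DataFrame(rows)


def _pair_correlation_matrix(
    pairs: Sequence[tuple[int, int, float]],
) -> tuple[np.ndarray, list[int]]:
    """Correlation matrix over the genes involved in ``pairs``.

    Raises ValueError naming the offending pairs when the requested matrix is
    not positive semi-definite (e.g. an impossible triangle of rhos).
    """
    involved = sorted({g for a, b, _ in pairs for g in (a, b)})
    pos = {g: i for i, g in enumerate(involved)}
    R = np.eye(len(involved))
    for a, b, rho in pairs:
        if R[pos[a], pos[b]] not in (0.0, rho):
            raise ValueError(f"conflicting rho values for pair ({a}, {b})")
        R[pos[a], pos[b]] = rho
        R[pos[b], pos[a]] = rho
    # jitter-free PSD check; tiny negative eigenvalues from roundoff tolerated
    eigmin = np.linalg.eigvalsh(R).min() if involved else 1.0
    if eigmin < -1e-10:
        raise ValueError(
            "latent_pairs correlation matrix is not positive semi-definite; "
            f"offending pairs: {[(a, b, rho) for a, b, rho in pairs]}"
        )
    return R, involved


def _smooth_orthonormal_fields(
    coords: np.ndarray,
    n_fields: int,
    lengthscale: float,
    rng: np.random.Generator,
    n_features: int = 32,
) -> np.ndarray:
    """n_cells x n_fields matrix of smooth cell-state fields with exact
    identity sample covariance.

    Each raw field is a sum of ``n_features`` random Fourier features of the
    (standardized) coordinates — the standard finite approximation of a
    squared-exponential Gaussian-process sample, so marginals are close to
    Gaussian and the field varies over ``lengthscale`` (in units of the
    coordinate spread).  The raw fields are then centered and QR-
    orthonormalized across cells, which preserves smoothness (linear
    combinations of smooth fields) while making the sample covariance
    exactly the identity, so downstream Cholesky mixing hits requested
    covariances exactly.
    """
    n = coords.shape[0]
    if n_fields >= n:
        raise ValueError(
            f"need more cells than correlated genes ({n_fields}) to embed the "
            "requested correlation structure exactly"
        )
    std = coords.std()
    if std == 0:
        std = 1.0
    x = (coords - coords.mean(axis=0)) / std
    omega = rng.normal(scale=1.0 / lengthscale, size=(2, n_fields * n_features))
    phase = rng.uniform(0, 2 * np.pi, size=n_fields * n_features)
    feats = np.cos(x @ omega + phase).reshape(n, n_fields, n_features).sum(axis=2)
    feats -= feats.mean(axis=0)
    q, r = np.linalg.qr(feats)
    diag = np.diag(r)
    if np.any(np.abs(diag) < 1e-10 * np.abs(diag).max()):  # pragma: no cover
        raise ValueError("degenerate embedding: cannot build independent fields")
    # fix sign for determinism across platforms
    signs = np.sign(diag)
    signs[signs == 0] = 1.0
    q = q * signs
    # unit sample variance (ddof=0): columns of q have squared norm 1
    return q * np.sqrt(n)


def _type_centroids(n_types: int, separation: float) -> np.ndarray:
    """Blob centroids on a line, adjacent centroids ``separation`` apart."""
    xs = (np.arange(n_types) - (n_types - 1) / 2.0) * separation
    return np.column_stack([xs, np.zeros(n_types)])


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic dataset under ``config``; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n_g, n_c = config.n_genes, config.n_cells

    # cell types and embedding islands (uniform discs, tSNE-like density)
    labels = rng.integers(0, config.n_types, size=n_c)
    centroids = _type_centroids(config.n_types, config.type_separation)
    radius = config.type_radius * np.sqrt(rng.random(n_c))
    theta = rng.uniform(0, 2 * np.pi, size=n_c)
    coords = centroids[labels] + np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta)]
    )

    # log-scale expression: white noise everywhere, smooth shared signal on
    # pair-involved genes
    log_expr = rng.normal(size=(n_g, n_c))
    if config.latent_pairs:
        R, involved = _pair_correlation_matrix(config.latent_pairs)
        pos = {g: i for i, g in enumerate(involved)}
        # handle each connected component of the pair graph separately:
        # fields stay well-conditioned (tiny QR blocks) and within-component
        # sample covariances are hit exactly
        import networkx as nxg

        pair_graph = nxg.Graph()
        pair_graph.add_nodes_from(involved)
        pair_graph.add_edges_from((a, b) for a, b, _ in config.latent_pairs)
        for comp in sorted(nxg.connected_components(pair_graph), key=min):
            genes_c = sorted(comp)
            idx = [pos[g] for g in genes_c]
            Rc = R[np.ix_(idx, idx)]
            nv = len(genes_c)
            # smooth-part variance per gene: sum of |rho| over its partners
            # (diagonal dominance keeps the smooth covariance PSD)
            smooth_var = np.abs(Rc - np.eye(nv)).sum(axis=1)
            if np.any(smooth_var > 1 + 1e-12):
                bad = [genes_c[i] for i in np.flatnonzero(smooth_var > 1 + 1e-12)]
                raise ValueError(
                    f"genes {bad} carry total |rho| > 1 across their pairs; "
                    "the latent model cannot allocate that much shared variance"
                )
            smooth_cov = (Rc - np.eye(nv)) + np.diag(smooth_var)
            fields = _smooth_orthonormal_fields(
                coords, nv, config.field_lengthscale, rng
            )
            L = np.linalg.cholesky(smooth_cov + 1e-10 * np.eye(nv))
            white_sd = np.sqrt(np.clip(1.0 - smooth_var, 0.0, None))
            log_expr[genes_c, :] = (
                (fields @ L.T).T + white_sd[:, None] * log_expr[genes_c, :]
            )

    if config.n_marker_genes and config.marker_shift:
        markers = np.arange(n_g - config.n_marker_genes, n_g)
        owner = markers % config.n_types  # round-robin marker-to-type map
        shift = np.where(owner[:, None] == labels[None, :], config.marker_shift, 0.0)
        log_expr[markers, :] = log_expr[markers, :] + shift

    latent = np.exp(log_expr)

    # dropout mask
    if config.expression_dependent_dropout and 0 < config.zero_prob < 1:
        # logistic in the log-scale value, centered so the mean rate stays
        # approximately zero_prob; slope 1 per log-unit
        offset = np.log(config.zero_prob / (1 - config.zero_prob))
        p_drop = 1.0 / (1.0 + np.exp(-(offset - (log_expr - log_expr.mean()))))
    else:
        p_drop = config.zero_prob
    dropped = rng.random((n_g, n_c)) < p_drop
    observed = np.where(dropped, 0.0, latent)

    genes = np.array([f"g{i:05d}" for i in range(n_g)], dtype=object)
    cells = np.array([f"c{i:05d}" for i in range(n_c)], dtype=object)
    type_names = np.array([f"type{t}" for t in labels], dtype=object)

    sparse_obs = sp.csr_matrix(observed) if config.zero_prob >= 0.5 else observed
    return SyntheticDataset(
        expression=ExpressionMatrix(sparse_obs, genes, cells),
        latent=ExpressionMatrix(latent, genes, cells),
        embedding=Embedding2D(cells, coords),
        cell_labels=type_names,
        truth=replace(config),
    )


def zero_diagnostics(expr: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene and per-cell fractions of exactly-zero entries."""
    if expr.n_genes == 0 or expr.n_cells == 0:
        raise ValueError("empty expression matrix")
    if expr.is_sparse():
        nz_gene = expr.values.getnnz(axis=1)
        nz_cell = expr.values.getnnz(axis=0)
        # explicit stored zeros would inflate nnz; eliminate first
        if expr.values.nnz and (expr.values.data == 0).any():  # pragma: no cover
            warnings.warn("matrix stores explicit zeros; eliminating")
            v = expr.values.copy()
            v.eliminate_zeros()
            nz_gene = v.getnnz(axis=1)
            nz_cell = v.getnnz(axis=0)
    else:
        nz_gene = np.count_nonzero(expr.values, axis=1)
        nz_cell = np.count_nonzero(expr.values, axis=0)
    per_gene = 1.0 - nz_gene / expr.n_cells
    per_cell = 1.0 - nz_cell / expr.n_genes
    return per_gene, per_cell
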