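"""Canonical genes x cells expression container.

Single-cell expression matrices arrive in several dialects (Matrix-Market
triplets with separate gene/cell label files, dense CSV/TSV in either
orientation).  Everything downstream of the readers operates on one canonical
object: genes along rows, cells along columns, nonnegative finite values,
sparse-capable.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
import scipy.sparse as sp

ArrayLike = Union[np.ndarray, sp.spmatrix]


class ExpressionMatrix:
    """Genes x cells nonnegative expression matrix with ordered id vectors.

    Parameters
    ----------
    values : ndarray or scipy sparse matrix, shape (n_genes, n_cells)
        Normalized expression values. Negative or non-finite entries are
        rejected; zeros are meaningful (dropout candidates) and preserved.
    genes, cells : sequences of str
        Unique, ordered identifiers matching the matrix dimensions.
    """

    def __init__(self, values: ArrayLike, genes: Sequence[str], cells: Sequence[str]):
        genes = np.asarray(genes, dtype=object)
        cells = np.asarray(cells, dtype=object)
        if sp.issparse(values):
            values = sp.csr_matrix(values)
        else:
            values = np.asarray(values, dtype=float)
            if values.ndim != 2:
                raise ValueError("expression values must be 2-dimensional")
        if values.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene ids")
        if len(set(cells)) != len(cells):
            raise ValueError("duplicate cell ids")
        data = values.data if sp.issparse(values) else values
        if data.size and not np.all(np.isfinite(data)):
            raise ValueError("expression contains non-finite values")
        if data.size and np.any(data < 0):
            raise ValueError("expression contains negative values")
        self.values = values
        self.genes = genes
        self.cells = cells
        self._gene_index = {g: i for i, g in enumerate(genes)}

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_sparse(self) -> bool:
        return sp.issparse(self.values)

    def toarray(self) -> np.ndarray:
        """Dense genes x cells ndarray (copy for sparse input)."""
        if sp.issparse(self.values):
            return self.values.toarray()
        return self.values

    # -- lookups --------------------------------------------------------
    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        """Expression of one gene across all cells as a dense 1-D vector."""
        i = self.gene_index(gene)
        row = self.values[i]
        if sp.issparse(row):
            return np.asarray(row.todense()).ravel()
        return np.asarray(row).ravel()

    # -- summaries ------------------------------------------------------
    def zero_fraction(self) -> float:
        """Overall fraction of exactly-zero entries."""
        total = self.n_genes * self.n_cells
        if total == 0:
            return 0.0
        if sp.issparse(self.values):
            nnz = self.values.count_nonzero()
        else:
            nnz = int(np.count_nonzero(self.values))
        return 1.0 - nnz / total

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(self.values[idx], np.asarray(genes, dtype=object), self.cells)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "sparse" if self.is_sparse() else "dense"
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_cells} cells, {kind})"
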