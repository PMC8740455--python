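"""Readers and writers for the supported on-disk formats.

Expression matrices: Matrix-Market triplets (10x-style, with sibling
gene/cell label TSVs) or dense CSV/TSV with row/column headers.  Embeddings,
gene-pair lists and cell labels: TSV/CSV.  Everything is normalized to the
canonical genes x cells orientation on read; Matrix-Market indices are
1-based on disk (the format standard) and 0-based in memory.  TSV output is
tab-separated UTF-8 with a header row and '.' decimals.
"""

from __future__ import annotations

import logging
import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .graph import Embedding2D
from .matrix import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_embedding",
    "write_embedding",
    "align_embedding",
    "read_pairs",
    "read_labels",
    "write_table",
]

log = logging.getLogger("metacorr")


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_id_file(path: str) -> np.ndarray:
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).values
    return np.asarray(ids, dtype=object)


def read_expression(
    path: str,
    orientation: str = "genes_by_cells",
    genes_path: Optional[str] = None,
    cells_path: Optional[str] = None,
) -> ExpressionMatrix:
    """Load an expression matrix from .mtx (+ label files) or dense CSV/TSV.

    For Matrix-Market input the gene and cell id files default to
    ``genes.tsv`` / ``cells.tsv`` (or ``barcodes.tsv``) next to the matrix.
    ``orientation`` states what the file's rows are; output is always
    genes x cells.
    """
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError("orientation must be 'genes_by_cells' or 'cells_by_genes'")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if str(path).lower().endswith(".mtx"):
        values = sio.mmread(path)
        base = os.path.dirname(os.path.abspath(path))
        if genes_path is None:
            genes_path = os.path.join(base, "genes.tsv")
        if cells_path is None:
            for cand in ("cells.tsv", "barcodes.tsv"):
                cells_path = os.path.join(base, cand)
                if os.path.exists(cells_path):
                    break
        rows = _read_id_file(genes_path if orientation == "genes_by_cells" else cells_path)
        cols = _read_id_file(cells_path if orientation == "genes_by_cells" else genes_path)
        if values.shape != (len(rows), len(cols)):
            raise ValueError(
                f"matrix is {values.shape[0]} x {values.shape[1]} but label files "
                f"list {len(rows)} rows and {len(cols)} columns"
            )
        values = sp.csr_matrix(values)
        if orientation == "cells_by_genes":
            values, rows, cols = values.T.tocsr(), cols, rows
        genes, cells = rows, cols
    else:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        if df.empty:
            raise ValueError(f"empty expression file: {path}")
        if orientation == "cells_by_genes":
            df = df.T
        genes = np.asarray(df.index.astype(str), dtype=object)
        cells = np.asarray(df.columns.astype(str), dtype=object)
        values = df.to_numpy(dtype=float)
    expr = ExpressionMatrix(values, genes, cells)
    log.info("read expression: %d genes x %d cells, zero fraction %.3f",
             expr.n_genes, expr.n_cells, expr.zero_fraction())
    return expr


def write_expression(
    expr: ExpressionMatrix,
    path: str,
    genes_path: Optional[str] = None,
    cells_path: Optional[str] = None,
) -> None:
    """Write .mtx (+ gene/cell TSVs) or a dense TSV/CSV, by extension."""
    if str(path).lower().endswith(".mtx"):
        base = os.path.dirname(os.path.abspath(path))
        os.makedirs(base, exist_ok=True)
        sio.mmwrite(path, sp.coo_matrix(expr.values))
        pd.Series(expr.genes).to_csv(
            genes_path or os.path.join(base, "genes.tsv"),
            sep="\t", header=False, index=False,
        )
        pd.Series(expr.cells).to_csv(
            cells_path or os.path.join(base, "cells.tsv"),
            sep="\t", header=False, index=False,
        )
    else:
        pd.DataFrame(expr.toarray(), index=expr.genes, columns=expr.cells).to_csv(
            path, sep=_sep_for(path)
        )


def read_embedding(path: str) -> Embedding2D:
    """Read a per-cell 2D embedding: columns cell id, x, y (header optional)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None)
    if df.empty:
        raise ValueError(f"empty embedding file: {path}")
    if df.shape[1] < 3:
        raise ValueError("embedding file needs 3 columns: cell, x, y")
    # header detection: numeric coordinates in the first data row
    first = df.iloc[0]
    try:
        float(first.iloc[1]), float(first.iloc[2])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    cells = np.asarray(df.iloc[:, 0].astype(str), dtype=object)
    coords = df.iloc[:, 1:3].astype(float).to_numpy()
    return Embedding2D(cells, coords)


def write_embedding(emb: Embedding2D, path: str) -> None:
    pd.DataFrame(
        {"cell": emb.cells, "x": emb.coords[:, 0], "y": emb.coords[:, 1]}
    ).to_csv(path, sep=_sep_for(path), index=False)


def align_embedding(emb: Embedding2D, expr: ExpressionMatrix) -> Embedding2D:
    """Reorder the embedding to the expression matrix's cell order.

    Cells present in only one of the two inputs are reported; zero overlap
    is an error.
    """
    pos = {c: i for i, c in enumerate(emb.cells)}
    matched = [c for c in expr.cells if c in pos]
    if not matched:
        raise ValueError("no embedding cell ids match the expression matrix")
    n_expr_only = expr.n_cells - len(matched)
    n_emb_only = emb.n_cells - len(matched)
    if n_expr_only or n_emb_only:
        log.warning(
            "embedding/expression id mismatch: %d cells lack coordinates, "
            "%d coordinates lack expression", n_expr_only, n_emb_only,
        )
    if n_expr_only:
        raise ValueError(
            f"{n_expr_only} expression cells have no embedding coordinates"
        )
    idx = [pos[c] for c in expr.cells]
    return Embedding2D(expr.cells.copy(), emb.coords[idx])


def read_pairs(path: str) -> list[tuple[str, str]]:
    """Read a two-column gene-pair list (TSV/CSV, optional header)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str)
    if df.empty:
        raise ValueError(f"empty pair file: {path}")
    if df.shape[1] < 2:
        raise ValueError("pair file needs two gene-id columns")
    head = [str(v).lower() for v in df.iloc[0, :2]]
    if head in (["gene_a", "gene_b"], ["a", "b"], ["gene1", "gene2"]):
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"pair file {path} contains a header but no pairs")
    return [tuple(row) for row in df.iloc[:, :2].to_numpy()]


def read_labels(path: str) -> pd.Series:
    """Read per-cell labels: columns cell id, label (optional header)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str)
    if df.empty:
        raise ValueError(f"empty label file: {path}")
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: cell, label")
    head = [str(v).lower() for v in df.iloc[0, :2]]
    if head[0] in ("cell", "cell_id", "barcode"):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="label")


def labels_for(expr: ExpressionMatrix, labels: pd.Series) -> np.ndarray:
    """Per-cell label vector in expression order; every cell must be labeled."""
    missing = [c for c in expr.cells if c not in labels.index]
    if missing:
        raise ValueError(f"{len(missing)} cells lack labels (e.g. {missing[:3]})")
    return labels.loc[list(expr.cells)].to_numpy(dtype=object)


def write_table(df: pd.DataFrame, path: str) -> None:
    """Canonical TSV output: tab-separated, header, no index."""
    df.to_csv(path, sep="\t", index=False)
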