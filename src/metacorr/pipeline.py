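"""End-to-end pipeline: partition -> filter -> profile -> correlate (+
optional classification and evolution tracing), with a provenance report.

All randomness flows from the single configured seed; identical configs
produce byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .celltype import auc_vs_k_scan
from .correlate import cluster_profile, compare_cluster_vs_cell, correlate_pairs
from .graph import (
    GraphParams,
    cells_per_cluster_summary,
    filter_small_clusters,
    partition,
    partition_series,
)
from .io import (
    align_embedding,
    labels_for,
    read_embedding,
    read_expression,
    read_labels,
    read_pairs,
    write_table,
)
from .trace import build_tree, layout_circle, layout_ladder

log = logging.getLogger("metacorr")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Paths: expression (required), embedding (required), pairs/labels
    optional.  ``ks`` is the series of cluster numbers; ``k`` the working
    cluster number used for correlation.  ``seed`` drives every stochastic
    step and is always recorded in the provenance block.
    """

    expression: str = ""
    embedding: str = ""
    pairs: Optional[str] = None
    labels: Optional[str] = None
    orientation: str = "genes_by_cells"
    k: int = 100
    ks: Sequence[int] = field(default_factory=list)
    cutoff: float = 3.0
    half_range: object = "auto"
    weight_mode: str = "inverted-distance"
    min_cells: Optional[int] = 10
    small_mode: str = "merge"
    alpha: float = 0.05
    folds: int = 10
    target: Optional[str] = None
    classify: bool = False
    trace: bool = False
    seed: int = 0
    outdir: str = "metacorr_out"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, n_cells: Optional[int] = None) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if n_cells is not None and self.k > n_cells:
            raise ValueError(f"k={self.k} exceeds n_cells={n_cells}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_cells is not None and self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        GraphParams(self.cutoff, self.half_range, self.weight_mode)  # domain check


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write outputs under config.outdir.

    Returns the machine-readable run report (also written as report.json).
    Any stage failure aborts with the stage name attached.
    """
    t0 = time.time()
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {
        "tool": "metacorr",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "parameters": {
            k: (list(v) if isinstance(v, (tuple, set)) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {},
        "stages": [],
    }

    stage = "read-inputs"
    try:
        expr = read_expression(config.expression, orientation=config.orientation)
        emb = align_embedding(read_embedding(config.embedding), expr)
        pairs = read_pairs(config.pairs) if config.pairs else None
        labels = (
            labels_for(expr, read_labels(config.labels)) if config.labels else None
        )
        for key in ("expression", "embedding", "pairs", "labels"):
            p = getattr(config, key)
            if p:
                report["inputs"][key] = {"path": p, "sha256_16": _checksum(p)}
        config.validate(n_cells=expr.n_cells)
        report["n_genes"] = expr.n_genes
        report["n_cells"] = expr.n_cells
        report["zero_fraction"] = expr.zero_fraction()
        report["stages"].append(stage)

        stage = "partition"
        params = GraphParams(config.cutoff, config.half_range, config.weight_mode)
        ks = sorted(set(list(config.ks) + [config.k]))
        if len(ks) > 1:
            series = partition_series(emb, ks, params=params, seed=config.seed)
            clustering = series[config.k]
        else:
            series = None
            clustering = partition(emb, config.k, params=params, seed=config.seed)
        report["n_initial_communities"] = clustering.n_initial
        report["louvain_resolution"] = clustering.resolution
        if config.min_cells:
            clustering, filt = filter_small_clusters(
                clustering, min_cells=config.min_cells, mode=config.small_mode
            )
            report["small_cluster_filter"] = filt
        sizes_df, size_summary = cells_per_cluster_summary(
            clustering, size_threshold=config.min_cells or 10
        )
        report["cluster_summary"] = size_summary
        assign = np.rec.fromarrays(
            [expr.cells, clustering.labels], names=("cell", "cluster")
        )
        import pandas as pd

        write_table(pd.DataFrame.from_records(assign), os.path.join(config.outdir, "assignment.tsv"))
        summary_df = sizes_df.assign(
            centroid_x=clustering.centroids[:, 0], centroid_y=clustering.centroids[:, 1]
        )
        write_table(summary_df, os.path.join(config.outdir, "clusters.tsv"))
        report["stages"].append(stage)

        if config.trace and series is not None and len(ks) > 1:
            stage = "trace"
            tree = build_tree(series)
            nodes_l, edges_l = layout_ladder(tree)
            nodes_c, _ = layout_circle(tree)
            write_table(nodes_l, os.path.join(config.outdir, "tree_ladder_nodes.tsv"))
            write_table(edges_l, os.path.join(config.outdir, "tree_edges.tsv"))
            write_table(nodes_c, os.path.join(config.outdir, "tree_circle_nodes.tsv"))
            report["stages"].append(stage)

        if pairs:
            stage = "correlate"
            prof = cluster_profile(expr, clustering)
            res = correlate_pairs(prof, pairs, alpha=config.alpha)
            write_table(res, os.path.join(config.outdir, "correlations_cluster.tsv"))
            comparison, cmp_summary = compare_cluster_vs_cell(
                expr, emb, pairs, config.k, params=params, seed=config.seed,
                alpha=config.alpha, clustering=clustering,
            )
            write_table(comparison, os.path.join(config.outdir, "correlations_compared.tsv"))
            report["correlation"] = cmp_summary
            report["pairs_tested"] = int((res.status == "ok").sum())
            report["pairs_degenerate"] = int((res.status == "degenerate").sum())
            report["pairs_missing"] = int((res.status == "missing").sum())
            report["pairs_significant"] = int(res.significant.sum())
            report["stages"].append(stage)

        if config.classify and labels is not None:
            stage = "classify"
            table, baseline = auc_vs_k_scan(
                expr, emb, labels, ks=[config.k], folds=config.folds,
                seed=config.seed, target=config.target, params=params,
            )
            table = pd.concat(
                [table, pd.DataFrame([{"k": expr.n_cells, "auc": baseline.auc,
                                       "folds": baseline.folds,
                                       "n_units": baseline.n_units}])],
                ignore_index=True,
            )
            write_table(table, os.path.join(config.outdir, "classification.tsv"))
            report["classification"] = {
                "cluster_auc": float(table.auc.iloc[0]),
                "baseline_auc": baseline.auc,
            }
            report["stages"].append(stage)
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        with open(os.path.join(config.outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    report["runtime_s"] = round(time.time() - t0, 3)
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
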