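# metacorr

Graph-based k-partitioning of single cells into mini-clusters to recover
gene–gene correlations hidden by scRNA-seq dropout.

## The problem

Droplet scRNA-seq captures only a small fraction of each cell's
transcripts, so 90–95% of the entries in a normalized expression matrix
are zeros that do not mean "not expressed".  Pearson correlation between
two genes across single cells is crushed toward zero by this capture
noise: well-established co-expressed pairs show r ≈ 0 at single-cell
resolution.  Yet merging even a few transcriptomically similar cells
removes zeros rapidly — under independent per-cell zeros at rate *p*, a
gene's merged value over *m* cells is zero with probability *p*ᵐ.

`metacorr` exploits this: it builds a distance-thresholded weighted graph
over cells from a 2D embedding (e.g. tSNE, computed upstream),
over-segments it with Louvain community detection into N > k communities,
greedily merges adjacent communities by centroid distance down to exactly
k mini-clusters, averages each gene within clusters (zeros included), and
computes gene-pair correlations across the k cluster means — with
linear-model (correlation t-test) p-values and Benjamini–Hochberg FDR.
Supporting tools cover cluster-evolution tracing across a series of k
values (ladder/circle tree layouts), cluster-size diagnostics with the
recommended <10-cell filter, cross-validated cell-type classification
from cluster profiles, and a synthetic-data generator with known ground
truth.  The audience is anyone analyzing zero-inflated scRNA-seq
co-expression: the library is the primary interface, with a thin
`metacorr` CLI for shell pipelines and a scikit-learn-style estimator
(`GraphKPartitioner`) for composition with sklearn tooling.

## Worked example

```python
import numpy as np
from metacorr import (SimulationConfig, simulate_dataset, partition,
                      compare_cluster_vs_cell)

# 2000 cells, 100 genes, 90% dropout; genes 0 and 1 share latent rho = 0.8
cfg = SimulationConfig(n_genes=100, n_cells=2000, zero_prob=0.9,
                       latent_pairs=[(0, 1, 0.8)], seed=5)
ds = simulate_dataset(cfg)
print(f"zero fraction: {ds.expression.zero_fraction():.3f}")

clustering = partition(ds.embedding, k=50, seed=0)
print(f"k={clustering.k} clusters from N={clustering.n_initial} Louvain communities; "
      f"median size {int(np.median(clustering.sizes))} (expected {2000 // 50})")

pairs = [("g00000", "g00001"), ("g00010", "g00011")]   # true pair + null pair
table, summary = compare_cluster_vs_cell(ds.expression, ds.embedding, pairs,
                                         k=50, seed=0, clustering=clustering)
cols = ["gene_a", "gene_b", "r_cell", "p_cell", "r_cluster", "p_cluster"]
print(table[cols].round(4).to_string(index=False))
```

prints

```
zero fraction: 0.899
k=50 clusters from N=1587 Louvain communities; median size 40 (expected 40)
gene_a gene_b  r_cell  p_cell  r_cluster  p_cluster
g00010 g00011  0.0104  0.6423     0.0563     0.6976
g00000 g00001 -0.0049  0.8263     0.5392     0.0001
```

Reading it: at single-cell resolution the truly correlated pair
(`g00000`–`g00001`, latent rho 0.8) is invisible (r = −0.005, p = 0.83).
Averaged over 50 mini-clusters of ~40 similar cells, the correlation
re-emerges (r = 0.54, p = 1e-4), while the null pair stays null at both
resolutions.  The same flow runs from the shell:

```bash
metacorr simulate --n-genes 100 --n-cells 2000 --zero-prob 0.9 \
    --pairs 0:1:0.8 --seed 5 --outdir sim/
metacorr partition --embedding sim/embedding.tsv --k 50 --seed 0 --out assign.tsv
metacorr correlate --expr sim/matrix.mtx --pairs pairs.tsv \
    --clusters assign.tsv --out correlations.tsv
```

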