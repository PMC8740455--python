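# Methods

## The problem

Droplet scRNA-seq expression matrices are dominated by zeros: a transcript
present in a cell is frequently not captured, so 90–95% of entries are zero
even after normalization.  Pearson correlation between two genes computed
across single cells is then attenuated toward zero — the product of two
independent capture indicators scales the covariance by the square of the
capture rate, while most of each gene's variance is capture noise.  Known
co-expressed pairs consequently show near-zero single-cell correlations.

`metacorr` implements the graph-based k-partitioning remedy: group
transcriptomically similar cells into k mini-clusters on a 2D embedding,
average each gene within a cluster (zeros included), and correlate genes
across the k cluster means.  Averaging m similar cells shrinks the
capture-noise variance by 1/m while the shared cell-state signal survives,
so the cluster-level correlation approaches the latent one.

## The partitioning algorithm

1. **Scaling.**  Embedding coordinates (typically tSNE output spanning
   roughly ±50) are multiplied by one global factor so the largest
   absolute coordinate equals `half_range` (auto: 200 up to 8000 cells,
   400 beyond).  No centering is applied; distance ratios are preserved.
2. **Graph.**  Cells become nodes; every pair at Euclidean distance
   d ≤ `cutoff` (default 3, in scaled units) is an edge.  The distance
   threshold applies in the scaled system, so `cutoff` and `half_range`
   jointly set the neighborhood radius.  Modularity weights default to
   `cutoff − d + 1e-6` (closer cells attract more strongly); `unweighted`
   and `raw-distance` modes exist for fidelity experiments, the latter
   noting that raw distances invert the affinity ordering Louvain expects.
3. **Over-segmentation.**  Louvain community detection (seeded, via
   networkx) produces N communities; if N ≤ k the resolution escalates
   ×1.5 per round (≤20 rounds) until N > k.
4. **Greedy merging.**  While more than k clusters remain, the *adjacent*
   pair (≥1 inter-cluster edge) with the smallest centroid distance is
   merged, the merged centroid recomputed from member cells; when no
   adjacent pair remains (disconnected leftovers) the globally closest
   centroid pair merges.  Ties break on the smallest (label_a, label_b).
   Adjacency can only shrink and never returns once exhausted, so the
   implementation runs a lazy min-heap over adjacent pairs followed by a
   cached-row-minimum nearest-centroid agglomeration — equivalent to the
   naive rescan-every-step greedy (asserted against it in tests) but
   O(N² + E log E) instead of O(N³).
5. **Labels** are re-indexed 0..k−1 by descending cluster size.

`k = n_cells` short-circuits to singleton clusters: the exact identity
limit in which every cluster-level statistic equals its single-cell
counterpart (this limit is asserted to 0 floating error in the tests).

A series of k values shares one over-segmentation and one merge path with
snapshots, which guarantees nesting: the partition at smaller k is a
coarsening of every larger-k partition.  The evolution-trace module links
clusters across levels by maximal cell overlap and emits deterministic
ladder and circular layouts (dot radius ∝ √size, so dot area ∝ cell
count; circular spans allocated by subtree size, children nested within
parents).

Clusters with fewer than `min_cells` (default 10) cells should be removed
or merged into their nearest-centroid neighbor; both modes are provided.
The expected cluster size is simply n_cells / k, and the partitioner's
median size stays within a small factor of it on uniform-density
embeddings.

## Correlation statistics

Cluster profiles are arithmetic means including zeros; the size-weighted
mean of cluster means reproduces the global gene mean exactly (a conserved
invariant).  Correlation across the k cluster means uses Pearson r (or
Spearman via rank transform) with the two-sided p-value of the Gaussian
linear-model slope test, which for simple regression is identically the
classical correlation t-test, t = r√((n−2)/(1−r²)) on n−2 df.  It is
implemented in that closed form and cross-checked against
`scipy.stats.pearsonr` and a `statsmodels` OLS fit; users expecting a
count-model likelihood behind the "glm" label should note it is ordinary
least squares with identity link.  Each cluster contributes one unweighted
observation (matching the per-cluster averaging definition); a
size-weighted variant (observations centered at the weighted mean and
scaled by √size) is available behind `weighted=True`.  Pairs with a
constant vector are flagged degenerate and excluded from the
Benjamini–Hochberg denominator; BH q-values (statsmodels) are compared
against a hand-rolled step-up in the tests, and significance means
q < alpha (default 0.05).

### Calibration caveat

Pearson p-values are exact under bivariate normality.  Cluster means of
zero-inflated, heavy-tailed expression are skewed, and with few cells per
cluster the far null tail of the t-test becomes anticonservative: at ~20–40
cells per cluster we measure ~5× inflation at p < 0.001, which raises the
empirical FDR of BH-thresholded detections above its nominal level.  At the
reference sizing of ~100–125 cells per cluster the means are close enough
to Gaussian that FDR control holds empirically (≤0.1 in the detection
study below).  The rank-based Spearman p-values are calibrated at every
cluster size we examined and are reported alongside Pearson throughout.
This is why choosing k from the desired cells-per-cluster — not just the
desired resolution — matters.

## Cell-type classification

Cluster profiles carry a majority-vote label (ties → lexicographically
smallest, flagged by a majority fraction of 0.5).  A regularized logistic
regression (the method's classifier is deliberately simple and pluggable)
is evaluated by stratified k-fold cross-validation; within each training
fold the most variable genes (default 500) are selected and standardized —
fold-internal, to avoid leakage — and the ROC AUC is computed on pooled
out-of-fold decision scores (per-fold AUCs are also reported).  The
identity limit k = n_cells reproduces the raw single-cell baseline exactly
under the same fold seed.

## The synthetic-data generator

The generator emulates the data regime the method targets, with known
ground truth:

* **Embedding:** each of `n_types` cell populations is a uniform-density
  disc (radius 50, mimicking both the ±50 span and the near-constant point
  density of tSNE output), centroids `type_separation` (150) apart so
  distinct types occupy distinct islands.
* **Latent expression:** log-normal with unit log-scale variance.  For
  each requested correlated pair (a, b, rho), the shared component of the
  two genes' log expression is carried by smooth *cell-state fields* over
  the embedding — sums of 32 random Fourier features approximating a
  squared-exponential Gaussian-process sample with lengthscale equal to
  the coordinate spread, centered and QR-orthonormalized per connected
  component of the pair graph so the requested covariances are hit exactly
  in sample.  The shared variance of a gene is the sum of |rho| over its
  partners (diagonal dominance keeps the block PSD; an infeasible
  allocation raises an error naming the genes); the remainder is per-cell
  white noise.  Genes in no pair are i.i.d. noise and serve as exact
  nulls.  The smooth/white split is the substantive modeling choice: cell
  state (which co-regulates genes) varies along the embedding and survives
  cluster averaging, while gene-specific noise averages away — precisely
  the mechanism the method exploits.  With i.i.d. cells instead, averaging
  would leave Pearson r unchanged in expectation and no clustering method
  could help.
* **Markers:** optionally the last `n_marker_genes` genes get a per-type
  log-mean shift (`marker_shift`) so types are separable from expression;
  off by default.
* **Dropout:** each entry is independently zeroed with probability
  `zero_prob` (default 0.95, the typical droplet-scRNA-seq zero rate).  An
  expression-dependent mode (logistic in latent magnitude) exists but is
  off by default, matching the plain Bernoulli design of the zero-merge
  analysis.
* The merged-cell zero-fraction simulation draws random m-cell subsets
  and reports the fraction of genes whose merged value is exactly zero;
  under entry-wise independent zeros the closed form is p^m, and the
  Monte-Carlo curve is required to track it within binomial error.

What the generator does *not* model: UMI count noise, library-size
variation, batch effects, expression-dependent capture (by default), or
any mismatch between the embedding and expression (here the embedding
*is* the cell-state coordinate, whereas real tSNE is itself derived from
noisy expression).  Passing tests therefore demonstrate the estimator's
behavior under the stated generative regime, not performance on any real
dataset.

## Problem sizes and numerical choices

Study-scale defaults used by the test suite and `scripts/acceptance.py`
(chosen as desk-scale versions of the method's operating regime): 2300
genes for the zero-merge curve (p = 0.95, 100 reps, m up to 100); 2000
cells for partitioning contracts (including the 16-set series 40–100 by
10 and 200–1000 by 100); recovery with rho = 0.8 under 90% dropout at
k = 50 over 50 replicates; detection with 50 true (rho = 0.7) + 450 null
pairs at ~125 cells per cluster over 20 replicates; classification with
2 types, 20 markers among 300 genes, k = 40, 10-fold CV over 10
replicates.  Full-scale inputs (tens of thousands of genes and cells) are
supported; the partitioner is near-linear in practice for fixed N.

Numerical details worth knowing: edge weights carry a 1e-6 epsilon so
zero-distance pairs keep positive weight; Louvain label order is fixed by
smallest member index and all randomness flows from explicit seeds, so
identical inputs and seeds give identical outputs end to end; merged
centroids are recomputed from member cells (not averaged from parent
centroids) to keep the greedy sequence exactly reproducible; |r| is
clipped to 1 before the t transform and |r| = 1 maps to p = 0; BH is
applied only over non-degenerate tested pairs; Matrix-Market files are
1-based on disk and 0-based in memory.

## Known limitations

* Pearson p-value anticonservativeness at small cells-per-cluster (see
  the calibration caveat); prefer Spearman or ≥100 cells per cluster when
  FDR control matters.
* The embedding is trusted as given; a distorted embedding produces
  clusters that mix cell states, and nothing in the package detects that.
* Greedy centroid merging is order-dependent by design (it mirrors the
  original algorithm); it does not optimize any global objective, and the
  k-cluster solution is not a global partition optimum.
* Only 2D embeddings and pair-list correlation (no all-vs-all matrices)
  are supported in this version.
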