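# corrsearch

Large-scale correlation network construction for high-dimensional data.

The package computes correlation networks two ways and lets you pick based on
how many features you have:

- **matrix backend** — the exact full correlation matrix as a single matrix
  product of *correlation-projected* feature vectors (each column centered
  and scaled to unit norm, so scalar products are Pearson correlations), with
  exact top-k / threshold extraction;
- **index backend** — a ball tree built jointly over the projected vectors
  *and their negations* (2n points), so nearest-neighbor and radius queries
  retrieve the strongest correlations of either sign without ever
  materializing the n x n matrix. Top-k search is approximate (each query
  feature inspects `k' = ceil(a * k / n)` candidates, `a` being the
  *approximation factor*); threshold search via radius queries is exact.

On top of these it provides:

- **differential correlation search**: a paired representation of two
  conditions in which a single scalar product equals a correlation
  difference, enabling the same index machinery for top-k *changes* in
  correlation;
- **Spearman** (rank-transform first) and **phi** (Pearson on 0/1 columns)
  coefficient classes in every operation;
- **statistics**: correlation p-values from the t-statistic, Bonferroni
  correction, a truncated Benjamini–Hochberg procedure for top-k results
  (unseen p-values are conservatively treated as 1), and Cliff's delta;
- **embedding coordinates**: projected columns as feature coordinates so any
  Euclidean embedder (t-SNE, UMAP, MDS) reflects correlation structure;
  negatively correlated features map to *large* distances by design;
- **single-cell coordination recipe**: dual bootstrap resampling of cell
  types, counting top cell–cell correlations per cell-type pair, and
  screening pairs for very large effect sizes (|Cliff's delta| > 0.622)
  between two conditions;
- **synthetic fixtures** with known ground truth (planted correlation
  blocks, planted differential edges, grouped cell-like data).

## CLI

Input matrices are CSV/TSV with a header of feature names and one row per
sample (use `--transpose` for features-as-rows files with feature names in
the first column), or MatrixMarket `.mtx` with a `<file>.mtx.names` sidecar.

```bash
# exact full matrix
corrsearch matrix data.csv corr.tsv --method spearman

# approximate global top-k (k as a count, a multiple of n, or a % of pairs)
corrsearch topk data.csv edges.tsv --k 0.1% --approximation-factor 10
corrsearch topk data.csv edges.tsv --k 100n --pvalues --adjust bh

# exact thresholded network
corrsearch threshold data.csv edges.tsv -t 0.8

# top-k correlation differences between two conditions
corrsearch diff-topk cond1.csv cond2.csv diff.tsv --k 50

# feature coordinates for an external embedder
corrsearch embed-coords data.csv coords.tsv

# dataset cleaning: clamp negatives, drop constant and duplicate features
corrsearch preprocess raw.csv clean.csv --report removed.json

# synthetic fixtures
corrsearch simulate blocks sim.csv --n-features 100 --m-samples 500 \
    --block-sizes 5,5 --rho 0.9 --seed 1

# single-cell coordination screen between two conditions
corrsearch cell-coord cells_t1.csv labels_t1.txt cells_t2.csv labels_t2.txt \
    out.tsv --target-per-group 10000 --replicates 1000
```

Shared search flags: `--method {pearson,spearman,phi}`, `--ranking
{abs,signed}`, `--approximation-factor`, `--batch-size`, `--n-workers`,
`--symmetrize`, `--dualtree`, `--low-memory`, `--seed`, and a global
`--log-level`. Results are deterministic: independent of batch size and
worker count, and byte-identical between the two backends when the
approximation factor is exhaustive.

### Choosing the backend

The full matrix needs `64 n^2 / 8e9` GB (about 8 GB at n = 32,000; 32 GB at
n = 64,000; see `estimate_full_matrix_memory_gb`). Prefer the matrix backend
while that fits in memory, the index backend beyond.

### Choosing the approximation factor

There is no closed-form mapping from a desired sensitivity to `a` in this
implementation: the default is a conservative `a = 10`, and
`empirical_sensitivity(X, k, a_grid)` measures recall against the exact
oracle on data small enough to check. Sensitivity is non-decreasing in `a`
and reaches 1.0 once `k' >= 2n` (exhaustive). In practice sensitivity is
usually far better than worst case because correlations are not adversarially
distributed.

The truncated BH procedure has an optional `u_replacement` flag tightening
the adjusted values tied with the largest retained p-value; its published
description is ambiguous, so the default is the plain pad-with-ones upper
bound.

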