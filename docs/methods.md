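# Methods

## The analysis

The unit of analysis is the *type*: a (genotype, morph) pair, of which
the full pea-aphid design has 15 (genotypes F1, I18, BK11 × morphs WF,
UWF, SF, WM, UWM). Replicate libraries are collapsed to one column per
type by the arithmetic mean (the median is available; the mean is the
simplest unbiased choice and the aggregation method real studies rarely
report). Genes are called expressed when their maximum FPKM across
columns strictly exceeds 0.5. Filtering is applied to the aggregated
type matrix by default; applying it before aggregation is a
configuration flag (`filter_before_aggregate`), since the ordering is a
genuine degree of freedom with negligible effect at these cutoffs.

All threshold comparisons mirror their conventional phrasing: "over x"
is strict (`>`), "x or more" is non-strict (`>=`). So tau > 0.8,
SD > 6, MI > 0.4/0.5 are strict, and the core-gene degree rule
(>= 20 partners) is not.

### tau specificity

For expression v_1..v_N over the N type columns,
tau = sum_i (1 - x_i) / (N - 1) with x_i = v_i / max_j v_j. tau is 0 for
uniform expression, 1 for single-type expression, and depends only on
values relative to the row maximum (scale invariant per gene). It is
computed on linear FPKM — the formula's native scale — with a log2
option exposed because specificity indices are transform sensitive.
N = 15 types is the default; specific calls are then tallied per morph.
Genes whose maximum is zero are rejected (run the expressed filter
first). Argmax ties take the first column in order and set a tie flag.

### Highly variable genes

Per-gene sample standard deviation (N−1 denominator) across the type
columns on linear FPKM; `sd > 6` is only meaningful on that scale. A
flag allows replicate-level columns instead.

### Mutual-information network

The estimator is deterministic and rank-based: each vector is converted
to ordinal ranks (stable sort, so ties are resolved identically across
strictly monotone transforms) and cut into B equal-frequency bins,
B = floor(sqrt(n/2)) with a floor of 2 (B = 5 at the default n = 60
replicate columns). The plug-in MI over the joint histogram, in nats, is
debiased by the Miller–Madow term (m_xy − m_x − m_y + 1)/(2n) — m being
occupied-cell counts — and floored at 0. Rank binning makes the network
identical on linear and log expression; the estimator tracks the
closed-form Gaussian value −½·ln(1 − ρ²) within ±0.1 nat at n = 2000
(verified in the test suite). MI is computed on replicate-level columns:
15 type columns alone would leave the estimate bias-dominated. Pairwise
computation is vectorized as a single joint-histogram matrix product
over one-hot binned data.

DPI pruning follows the classic convention: for every triangle of the
input graph, the strictly weakest edge is marked pruned when
mi_min < (1 − tolerance)·min(other two), default tolerance 0. Decisions
are evaluated on the input graph, so the result is independent of
triangle processing order, idempotent, and exactly reproducible by an
exhaustive triangle scan (the test oracle). Ties (no strict minimum)
prune nothing.

Core genes: a gene's co-expressed partners are its unpruned neighbours
with edge MI > 0.4 (the edge-level cutoff reuses the mean-MI threshold,
the only value conventionally stated near this rule; both knobs are
independent settings); a gene is core with >= 20 partners and mean
partner-edge MI > 0.4. The display network exports unpruned edges with
MI > 0.5 as TSV or GML with per-node degree attributes.

### Expression patterns

Rows of the log2(FPKM+1) type matrix are z-scored (zero-variance rows
dropped with a warning) and clustered with Euclidean k-means, k = 6,
best of 50 random initializations by within-cluster sum of squares,
deterministic under the seed. Raw k-means labels are arbitrary, so
clusters are re-indexed by descending size for stable reporting.
Heatmap ordering uses average-linkage agglomerative clustering on
correlation distance (complete linkage and Euclidean distance are
options).

### Morph markers

Observations are replicate-level samples labelled by morph (the 5-class
problem; the full 15-type labelling is a flag, but with 4 replicates per
type out-of-bag estimates need the larger per-class counts). The forest
is an explicit bootstrap loop over CART trees — 1000 trees,
floor(sqrt(p)) candidate features per split, Gini criterion, unlimited
depth — because out-of-bag (OOB) permutation importance requires
per-tree OOB indices. Mean decrease Gini is the unnormalized per-tree
impurity decrease averaged over trees (proportional to the R
`randomForest` convention; rankings identical). Mean decrease accuracy
permutes, per tree, each feature actually used by that tree within the
OOB samples and averages the accuracy drop over all trees. Ranking is
by Gini with ties broken by gene order; the top 30 are reported.

### Pipeline

One seed governs everything stochastic; k-means and forest sub-seeds
are derived from it via `numpy.random.SeedSequence`, so stages rerun
independently and identically. The manifest records config, sub-seeds,
version and per-stage counts. Any stage failure aborts with the stage
name.

## The synthetic generator

The generator emulates the 15-type design: all expression is simulated
on the log2 scale and exponentiated, which keeps FPKM non-negative
without truncation. Background genes are i.i.d. log2-normal
(mean 3, sd 1.5 — median FPKM ≈ 8 with a realistic spread); planted
genes draw their baseline from N(5, 1) because signal genes in real
data are moderately-to-highly expressed and fold changes on barely
expressed genes would vanish under the linear-scale SD filter.
Per-sample multiplicative noise is log2-normal with sd 0.5.

Planted structure, with the default study configuration:

| signal | default | mechanism |
|---|---|---|
| type-specific genes | 40, fold 16 | + log2(16) in one type's columns, round-robin over the 15 types |
| co-expression modules | 5 × 25 genes, rho 0.85 | per-sample latent N(0,1) factor; member loading gives pairwise log-scale correlation ≈ rho; the first member (hub) is loaded at variance share 0.95 |
| morph markers | 6 per morph, fold 8 | + log2(8) in all three genotypes of one morph |
| sex-biased block | 0 (off) | + log2(sex_fold) in all morphs of one sex |

The module factor varies across all 60 replicate columns, not only
across types, so MI is estimable at replicate resolution. The sex block
exists because sex-dimorphic expression is the dominant axis in real
morph transcriptomes and is what makes same-sex samples cluster
together in the sample dendrogram; it is off by default because a
planted sex block is itself a strong co-expression cluster that
competes with the module hubs in network recovery — the default
configuration is the module/hub recovery condition, and the dendrogram
demonstration enables the block explicitly (60 genes, fold 3).

What the generator does not emulate: count-level sampling noise and
mean–dispersion coupling, gene-length effects in FPKM, correlated
background (housekeeping co-expression), batch effects, and expression
that is specific to a genotype rather than a type or morph. Passing
recovery tests therefore shows the pipeline identifies the structures
it targets under clean planted signal; it does not bound performance on
real libraries.

## Numerical and degenerate-input choices

* Constant vectors: MI returns 0 with a warning (no information, not an
  error); z-scoring drops constant rows with a warning; hierarchical
  ordering on a constant matrix raises (correlation undefined).
* Strict/non-strict boundaries as above; a gene at FPKM exactly 0.5 or
  tau exactly 0.8 is excluded.
* Mapping rate is rounded to the nearest 0.1 percentage point, the
  precision of published summary tables.
* MI is floored at 0 after bias correction; the diagonal is excluded.
* All tie-breaks (argmax type, Gini ranks, k-means label order) are
  deterministic and documented in the relevant docstrings.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so
the full suite completes in about a minute: the default synthetic study
(1000 genes, 15 × 4 samples) for recovery, n = 2000 for the Gaussian MI
oracle, 10 000 random profiles for the tau oracle, 100 random 10-node
graphs for the DPI brute force, and 10 generator seeds for the
marker-recovery median. Transcriptome-scale inputs (tens of thousands
of genes) run through the same code paths; the all-pairs MI step is
O(k²B²) memory in the number of HVGs k and is the only stage that needs
thought beyond ~5000 HVGs.

## Known limitations

* With 25-gene modules and 60 samples, strict DPI retains star-like
  module backbones with hub degrees near 10, so the degree >= 20 core
  rule calls no genes on the default synthetic data; hubs are instead
  validated as the top-degree genes. Which module gene ends up most
  central is itself noisy: the hub's latent-factor loading (variance
  share 0.95 vs 0.85 for members) exceeds the members' by less than the
  MI estimation noise at 60 samples, so an ordinary member occasionally
  out-ranks its hub by degree. The rule is written for
  transcriptome-scale networks with thousands of HVGs and larger
  modules.
* The MI estimator is the binned/Miller–Madow plug-in, not the
  Gaussian-kernel or adaptive-partitioning variants of other ARACNE
  implementations; absolute MI values (and hence the 0.4/0.5 cutoffs)
  are comparable in magnitude but not interchangeable across
  estimators.
* No permutation-based significance threshold for MI edges; the fixed
  cutoffs stand in for it.
* OOB permutation importance permutes one feature at a time and, like
  all such scores, splits importance between correlated features.
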