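# Methods

This note records the statistical model behind each stage, the parameters
that matter, the numerical conventions, and the genuinely open design
choices the package had to make.

## Expression input and filtering

Expression matrices are genes × samples tables of log2-scale values;
replicate samples belonging to one condition group are collapsed by the
arithmetic mean (missing values excluded per cell). Averaging is idempotent
for singleton groups and must happen *after* any differential-expression
testing — DE needs replicates, so the pipeline never feeds averaged
matrices to `de_test`.

The low-variance filter removes genes whose interquartile range across
samples is small. The published phrasing "IQR less than the median" admits
two readings; the default compares each gene's IQR to the **median of all
genes' IQRs** (the standard variance-filter convention, removing roughly
half the genes), with strict inequality so exact ties are retained. The
alternative reading — IQR below the gene's own median expression level — is
available as `rule="gene_median"`. Quartiles use linear interpolation
between order statistics; this convention is fixed for reproducibility.
Genes missing in more than 50% of samples are removed with a warning.
Whether the filter should precede network construction (as opposed to only
the DE analysis) is not dictated by the method; it is therefore an optional
stage everywhere (`--apply-iqr-filter` on `build-network`, on by default
for `de`).

## Coexpression scores and the network

Pearson correlations are computed across conditions for all unordered,
non-self gene pairs (upper triangle only; each pair stored once). Genes
with zero variance are an error — they must be filtered first. Fisher's
z-transform `arctanh(r)` stabilizes the variance; |r| is clamped to
1 − 10⁻¹⁵ beforehand so duplicated genes yield large finite scores and the
ranking is preserved. Standardization is **global over all pairs**
(sample mean and SD, ddof = 1); per-gene standardization is deliberately
not offered. Because standardization is affine and arctanh strictly
increasing, ranking by z_cs equals ranking by r.

Edges are the pairs with z_cs strictly above the cutoff (default 1.96,
the upper 2.5% point of a standard normal). The network records the
realized kept fraction and the minimum r among kept edges — the
dataset-specific Pearson equivalent of the cutoff, which is reported, not
asserted, since it depends on the correlation distribution at hand. The
edge weight carried into all downstream computation is r; z_cs is
metadata. With the default positive cutoff no negative weight can enter
the network; if a user forces a low cutoff, the clustering stage rejects
negative weights with an explicit error rather than producing undefined
densities.

Missing expression values are handled by pairwise-complete correlation
with a minimum-overlap parameter (default: every sample present).

Memory: complete-data correlations are computed in row chunks
(`chunk_size`, default 512 genes) against the standardized matrix, so the
full n² correlation matrix is never materialized for large gene counts.

## Density clustering

The greedy procedure follows the SPICi scheme: seed at the unclustered
node with maximal weighted degree; pair it with its best available
neighbor (maximum edge weight, ties by weighted degree, then lexicographic
gene order — the original's weight-binning speedup is replaced by exact
tie-breaking, so runs are fully deterministic); then repeatedly take the
adjacent unclustered node with maximal support (summed weight into the
set). Growth stops when the best support falls below T_s·|S|·density(S)
(T_s default 0.5); a candidate whose addition would drop the density below
T_d is rejected individually and the search continues. Emitted clusters
must have ≥ `min_cluster_size` genes (default 3, matching the
clusters-of-three-or-more reporting convention) and density ≥ T_d — the
latter is asserted at emission on every run. Everything else, including
a seed pair whose grown set never reaches the bounds, lands in the
unclustered list. Weighted mode is used throughout since the evaluation
statistics are weight-based.

Clusters are ordered by decreasing size then smallest member, and named
`ClusterNNNN` (zero-padded to at least 4 digits) in that order.

## Sweep evaluation

`sweep_cluster` runs the clustering independently on a grid of T_d values
(canonically 0.1–0.9); `evaluate_sweep` scores each result by:

1. number of clusters (size ≥ 3);
2. fraction of network genes clustered (clustered genes / all nodes);
3. average segregation per cluster: mean internal edge weight divided by
   the mean weight of all **distinct** edges incident on cluster members,
   internal edges counted once. Summing incident weights per member
   instead (which double-counts internal edges) is a defensible literal
   alternative; the distinct-edge convention is used because it makes an
   isolated clique score exactly 1. Clusters with no internal edge are
   flagged missing;
4. enrichment extent against a gene-set collection restricted to sets
   annotating < 500 genes (specificity preset): the number of clusters
   and of distinct sets with at least one pair at q < 0.1, plus the
   distribution over clusters of each cluster's best ES.

Box-plot notch bounds (median ± 1.58·IQR/√n, a rough 95% CI for the
median) are emitted alongside quartiles so a "first significant drop" in
segregation can be judged; the choice of T_d is intentionally left to the
analyst — no automatic elbow detection is applied.

## Enrichment statistics

The overlap p-value is the upper cumulative hypergeometric tail
P(X ≥ m) via `scipy.stats.hypergeom.sf`, which works in log-space
combinatorics and is verified in the test suite against exhaustive subset
enumeration for every parameter combination with universe size ≤ 12.
All pairs tested in one call form a single BH family (matching a
cluster-by-set q-value table); BH is order-preserving and monotone.
ES = −log10(q) with q floored at 10⁻³⁰⁰; the annotation rule ES > 1.3 is
exactly q < 10⁻¹·³ ≈ 0.05. The universe defaults to all genes the
clustering partitioned (network genes); it is overridable since the
choice between array genes and network genes is a judgment call. Set sizes
for the 10–1500 filter are computed within the declared universe.

Responsive-cluster identification tests each cluster against named DE
gene lists (each labelled `up` or `down`); scores are signed −log10(q),
zeroed when q fails the cutoff, and a cluster is responsive when at least
one list is significant. Motif annotation applies a single rule to
precomputed hit tables: a motif annotates a cluster iff it is present in
strictly more than 50% of the cluster's genes; de-novo motif discovery is
out of scope.

## Differential expression

Per gene the log2 fold change is the difference of group means and the
test statistic is the two-group linear-model t with **empirical-Bayes
variance moderation**: per-gene pooled variances s²_g (df d) are shrunk to
s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d), where the prior (d₀, s₀²) is fitted by
moments of log s²_g under a scaled-F model (trigamma inversion by Newton's
method), and the t-test gains d₀ degrees of freedom. Moderation was chosen
over the plain pooled t because typical replicate designs here have 2–4
residual df, where the unmoderated test has essentially no power at
stringent FDR thresholds: in the packaged simulation (1000 genes, 100
shifted by 2 log2 units at σ = 0.5, 3 vs 3) the moderated test recovers
91–98 of 100 planted genes at q < 0.01 with an observed false-discovery
proportion ≤ 0.02, while the unmoderated test recovers ≈ 0. The
unmoderated pooled t remains available (`moderated=False`); genes with
zero residual variance are flagged missing there, and when the prior
cannot be fitted (fewer than two genes with positive variance) the
moderated path falls back to it. BH q-values are used rather than Storey's
estimator so one multiple-testing procedure, conservative and
parameter-free, serves the whole package. Selection at q < 0.01 (strict)
splits by fold-change sign into disjoint up/down lists.

## Perturbation scoring

The PAGE statistic Z = (S_m − μ)·√m/δ uses the mean and sample SD
(ddof = 1) of **all profiled fold changes** — not all array genes — since
the uploaded profile is the population the user actually measured. Cluster
genes absent from the profile are ignored (m counts profiled members);
clusters with m below `min_set_size` (default 10, to keep the CLT
approximation honest) are skipped with a warning. Z is invariant to
shifting or positively scaling the whole profile. Under a null i.i.d.
profile the Z of random sets is standard normal up to a finite-population
factor √((N−m)/(N−1)) ≈ 0.999 at m = 25, N = 10⁴ — indistinguishable at
the packaged test sizes (KS test at 5,000 sets). Two-sided normal
p-values are BH-adjusted across scored clusters; selection (default
q < 0.01) returns clusters ranked by |Z|.

A planted per-gene shift Δ gives a cluster E[Z] ≈ Δ·√m/δ. Note the
regime Δ = 2δ/√m therefore centers Z at 2 regardless of cluster size —
a signal at the edge of single-test detectability that no FDR-controlled
selection can recover with high sensitivity; the calibration tests use
this fact to bound false positives, and detectable planted effects in the
fixtures use Δ of 2–3 fold-change SDs per gene (E[Z] ≈ 11–16 at m = 30).

## Synthetic fixtures

`simulate_expression` uses latent-factor mixing: a block gene is
√ρ_out·g + √(ρ_in−ρ_out)·f_b + √(1−ρ_in)·ε with independent
standard-normal condition profiles g (global), f_b (block) and ε (gene),
so the expected correlation is exactly ρ_in within blocks and ρ_out
elsewhere; a per-gene baseline (mean 7, SD 2) moves values onto a
realistic log2 scale without touching correlations. Defaults — 45
conditions, five planted 30-gene modules at ρ_in = 0.9 over independent
background genes, 400 genes total — mirror the compendium scale the
package emulates, at desk size. What the generator does **not** emulate:
probe-level artifacts, batch structure, heteroskedastic noise across
conditions, and correlated background — so passing recovery tests shows
the algorithmic chain is correct under its stated model, not that any
particular biological dataset will yield modules this clean.
`simulate_profile` plants i.i.d. standard-normal fold changes plus a
constant shift on chosen clusters and records the signed truth.

## Problem sizes and determinism

All simulation-based tests and the acceptance script run at desk scale
chosen once: ≤ 2,000 genes for scoring (≈ 2·10⁶ pairs, seconds on one
core), networks of a few thousand edges for clustering, 5,000 random sets
for the calibration KS. Every stochastic component takes an explicit seed
through `numpy.random.default_rng`; identical inputs and parameters give
byte-identical outputs, including cluster ordering (all clustering ties
are lexicographic).

## Known limitations

- The greedy clustering is order-dependent by design (as is the
  original); it guarantees the density invariant, not global optimality,
  and small planted modules adjacent to strong hubs can be split.
- The moderated-t prior assumes variances are exchangeable across genes;
  strongly intensity-dependent variance would call for a trend fit that
  is not implemented.
- Hypergeometric annotation treats gene sets as flat (no ontology
  propagation), and the enrichment family is defined per call — merging
  results across calls invalidates the q-values.
- PAGE's normal approximation degrades below ~10 profiled genes per
  cluster; such clusters are skipped rather than scored badly.
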