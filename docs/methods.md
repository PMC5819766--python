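# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `sentinelpanel`. It states nothing the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

The pipeline's universal currency is a genes × comparisons matrix of
log2 fold changes. Each comparison is one treatment-vs-control contrast
within a study; study labels matter because both the co-expression score
and cross-validation partition at the *study* level, so correlated
comparisons from one study never straddle a train/test boundary. When a
signal matrix plus design table is supplied instead, fold changes are
the difference of arithmetic means of log2 signals (the standard
limma-style contrast; averaging on the log scale matches how RMA-style
summaries are combined). Missing values are rejected rather than
imputed, and gene identifiers are opaque case-sensitive strings; a
convenience utility collapses probe-level rows to gene level by the mean,
but identifier mapping is otherwise upstream of this package.

## PCA convention

Fold changes are differential contrasts, already expressed relative to a
control, so principal components are computed **without centering**:
"variance" means squared singular value, and the eigengene count G is
the smallest number of components whose cumulative variance fraction
reaches `var_fraction` (default 0.9). A `center="gene-mean"` switch is
available for data whose rows carry offsets; centered extrapolation
models add the training means back on application. Uncentered PCA also
keeps the extrapolation operator linear-homogeneous: a zero sentinel
profile predicts zero everywhere.

## Diversity score (DIS)

Experiments are k-means clustered (k = 10 by default, k-means++ with 10
restarts and a fixed seed — the initialization is a free choice, made
deterministic) on the G-dimensional eigengene coordinates, Euclidean
distance. Within each cluster the components are recomputed and a
gene's score is its summed squared loadings over the first
min(G, cluster rank) components. Because loading columns are
orthonormal, these scores sum to exactly that count across genes — the
conservation law the test suite asserts at 1e-8. Clusters with fewer
than two comparisons admit no decomposition and are skipped with a
warning. The global G (not a per-cluster re-derivation) bounds the
within-cluster sum, truncated to the cluster's numerical rank.

## Co-expression score (CIS)

Studies are partitioned into `n_folds` folds (default 20) of near-equal
study counts by a shuffled round-robin. Within a fold, gene-gene
distance is 1 − |Pearson r|, so perfectly anti-correlated genes are as
close as perfectly correlated ones — a negated proxy is as informative as
a positive one. Average linkage was chosen for the hierarchical
clustering (the distance and the h = 0.9 cut are fixed; the linkage is a
free choice — average linkage respects the interpretation of the cut
height as a mean within-cluster dissimilarity). Zero-variance genes
within a fold have undefined correlation and are forced to singletons;
singletons score 0. Folds with fewer than three comparisons cannot give
non-degenerate correlations and are skipped with a warning.

## Robust aggregation

Both per-cluster DIS and per-fold CIS are summarized by a Tukey biweight
location: start at the median, fix the scale at
MAD + 1e-4·median(|x|), and iterate weights (1 − u²)² with
u = (x − t)/(c·scale), c = 5 (the tuning constant follows the Affymetrix
biweight convention), until the update falls below 1e-9 or 100
iterations. Constant input returns that constant; a zero scale (possible
when more than half the values tie at zero) degrades to the arithmetic
mean. The eps guard makes the estimator exactly scale-equivariant but
only approximately shift-equivariant — irrelevant here because both
scores are non-negative with meaningful zeros.

## Overall score and selection

OIS(g) = sqrt((rank_CIS(g)² + rank_DIS(g)²)/2)/N with ascending ranks
1..N. Average ranks on ties would break the ranks-are-a-permutation
invariant, so ties are resolved by ascending gene identifier — fully
deterministic and documented. OIS lies in (0, 1], equals 1 exactly when
a gene ranks last (largest) on both criteria, and is strictly increasing
in each rank. The panel is the top n by OIS (ties again by identifier).

## Coverage refinement

A pathway is covered when the panel holds at least q of its genes
(default q = 3), **capped at the number of its genes present in the
scoring universe** — without the cap, pathways smaller than q could never
be satisfied and the loop could not terminate. Each iteration swaps the
best exclusion candidate (fewest pathway memberships, then smallest OIS,
then identifier) for the best inclusion candidate (most uncovered-pathway
memberships, then largest OIS, then identifier). Membership is evaluated
against the scoring universe.

Two safeguards make the greedy provably terminating and deterministic:

* a selected gene whose removal would drop any pathway below its
  attainable coverage is ineligible for exclusion, so the total coverage
  deficit strictly decreases every iteration;
* when the top inclusion candidate would pin every selected gene, the
  next-ranked candidates are tried before declaring the step infeasible.

Single-swap greedy still has genuine local minima: escaping them can
require temporarily uncovering a pathway (e.g. when the only equal-size
cover uses different members of a currently-pinned pathway). When the
greedy stalls, a bounded exact search enumerates all equal-size subsets
and keeps the one maximizing (pathways covered, total OIS) — capped at
200 000 subsets, so it only ever runs on small universes; at realistic
corpus sizes a stall returns the partial greedy result with the residual
uncovered pathways listed. On 2 000 random small instances checked
against a brute-force subset-enumeration oracle, the combined procedure
covered every pathway whenever any equal-size cover existed.

Nominated genes are merged afterwards as a plain union: already-present
genes keep their provenance, new genes are flagged `nominated`, and the
data-driven panel size is never changed by refinement (size
conservation).

## Extrapolation

Principal component regression on the sentinel submatrix: retain
components 1..K where K is the largest index with
eigenvalue_K / eigenvalue_1 ≥ λ (default 0.01, eigenvalues = component
variances of the sentinel matrix). The component coordinates are
mutually orthogonal regressors, so each non-sentinel gene's
least-squares fit is closed-form and needs no regularization — rank
deficiency is exactly what the λ cutoff removes. The composed operator
`coefficients @ loadings.T` is stored explicitly (t × s), making
application a single matrix product and serialization (HDF5) exact.
When training data are exactly rank-K, the λ rule retains all K
components and the sentinels span the latent space, held-out
reconstruction is exact to machine precision — the test suite asserts
≤ 1e-6.

## Evaluation

Gene-level metrics pool all (gene, comparison) entries of the evaluated
block rather than averaging per-gene statistics (a per-comparison
variant is a config option): Pearson r, concordance of the
|log2FC| ≥ `fc_threshold` (default 1.0, i.e. two-fold) changed call, the
overlap of the top `top_fraction` (default 1 %) entries by absolute
value (ceiling size, position tie-break), and MSE. The two-fold
concordance default reproduces the characteristic behavior that even
poor predictions score high concordance, because most entries of a
fold-change matrix are null.

The enrichment score ranks genes by fold change (descending, identifier
tie-break) and walks a weighted Kolmogorov–Smirnov running sum: hits
advance by |fc|^p normalized over the in-set total (p = 1 by default;
p = 0 recovers the classic unweighted KS statistic, verified
exhaustively against an independent step-walk oracle and cross-checked
against gseapy's preranked ES), misses retreat by 1/(N − N_hits); the ES
is the running-sum value of maximum absolute deviation. All-zero
columns fall back to equal hit weights and remain deterministic.
Pathway significance uses the asymptotic two-sample KS test of in-set vs
out-of-set fold changes (a permutation null would be exchangeable but
needlessly slow at these scales); differential pathways require
|ES| > 0.5 and p < 0.001, with sign(ES) as direction. The
pathway-by-comparison score matrix is computed in one vectorized pass
per comparison and agrees cell-for-cell with the per-pathway functions.

Cross-validation partitions studies into folds; per fold, selection
(scoring + refinement, or a size-matched random panel as baseline) and
extrapolation fitting use only the retained folds, and the held-out fold
is scored at the gene level (extrapolated vs measured targets) and at
the pathway level (ES from fully measured profiles vs ES from
sentinel + extrapolated profiles, with measured differential calls as
truth for recall/precision). Reports carry per-fold records plus
mean/min/max summaries.

## Synthetic data

The generator emulates the statistical structure the method exploits:
gene modules driven by shared latent Gaussian factors (module loadings
uniform on [0.5, 1.5] with random signs, so the 1 − |r| distance must
group anti-correlated partners), background genes of pure Gaussian
noise, study-specific factor intensity multipliers (log-uniform in
[0.5, 2]) that give experiment clustering structure to find, and pathway
collections aligned with modules with controllable probability. Defaults
(400 genes, 5 modules of 30, 120 comparisons over 24 studies, noise sd
0.2 at unit factor scale) give a small corpus with the module-to-noise
contrast typical of curated expression compendia.

What it does **not** emulate: probe-level noise physics, saturation,
platform batch effects, count-based RNA-seq sampling, non-linear
regulation, or the heavy-tailed module-size distribution of real
transcriptomes. Passing tests therefore demonstrate correctness of the
algorithms and recoverability of planted linear-factor structure, not
performance on any particular real corpus.

## Problem sizes used in validation

The validation suite and acceptance script run on deliberately scaled
corpora — hundreds of genes, 40 gene sets, tens of studies — chosen so
the full pipeline (including 20 paired cross-validation runs) completes
in minutes on one CPU while keeping every statistical contrast
well-powered: planted-module recovery is asserted at hypergeometric
p < 1e-6 per seed, and panel-vs-random comparisons are paired across
seeds. Corpus-scale headline numbers from production datasets (tens of
thousands of genes and comparisons, 1 320 pathways) are outside what
synthetic desk-scale runs can reproduce; the suite instead checks the
corresponding directional claims (refined panels cover all pathways
while random panels never do; selected panels beat random panels on
pathway-level significance overlap in ≥ 80 % of paired runs).

## Known limitations

* Gene-level pooled Pearson treats all comparisons as exchangeable;
  strong per-study variance differences can dominate the pooled value.
* The hierarchical clustering is O(g²) per fold in memory; corpora
  beyond ~20 000 genes per fold need chunking that this package does not
  provide.
* The asymptotic KS p-value is anti-conservative for very small gene
  sets (< ~10 in-universe members).
* Coverage refinement optimizes a greedy local criterion; panel-level
  global optimality (ILP set cover) is explicitly out of scope.
* Extrapolation is linear; genes whose response is non-linearly related
  to the sentinels are systematically attenuated toward their
  subspace projection.
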