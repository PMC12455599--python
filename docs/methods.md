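# Methods

This note documents the statistical model, the algorithmic choices, the
synthetic-data generators and the numerical decisions behind `space-st`.

## The model

For a single gene, let `y = (y_1, ..., y_N)` be normalized expression over
`N` spots with 2-D coordinates `s_i`. The gene is modeled by Gaussian-process
regression

    y ~ MVN(X beta, sigma_s^2 K + delta I)

where `X` is a covariate design (an intercept by default; spot-level
covariates may be added), `K` is an `N x N` spot-similarity kernel built from
pairwise Euclidean distances, `sigma_s^2` scales the spatial covariance and
`delta` the independent noise. A gene is *spatially variable* (an SVG) iff
`sigma_s^2 > 0`, so SVG detection is the test of `H0: sigma_s^2 = 0`.

### Score test (step 1)

With OLS residuals `r = P y` under the null (`P` the residual projector of
`X`), the variance-component score statistic is `T = r' K r`. Under `H0`,

    T  ~  sum_i lambda_i chi2_1,    lambda_i = sigma_hat^2 * eig(P K P),

with `sigma_hat^2 = r'r / (N - k)` plugged in. The mixture tail probability
is computed by numerical inversion of the characteristic function (the
Davies/Imhof approach; see *Numerics* below), which handles the mixed-sign
eigenvalues produced by indefinite Cosine kernels. The overall per-gene
p-value combines the ten per-kernel p-values with the Cauchy (ACAT) rule

    t = mean_i tan((0.5 - p_i) pi),    p_comb = 0.5 - arctan(t) / pi,

which is calibrated in the tail under arbitrary dependence. Genes are called
at a Benjamini-Hochberg FDR of 0.05 by default (`test.fdr`). A Bonferroni
min-p combination is available behind `test.combine = "minp"`.

Per-kernel p-values are clipped into `[1e-15, 1 - 1e-3]` before the tangent
transform. The asymmetric upper clip is the standard ACAT guard: with
indefinite kernels a statistic deep in the *left* tail yields `p = 1`
exactly, whose tangent at machine-precision clipping would single-handedly
drive every combination to 1.

### Kernel bank

Ten kernels by default: Gaussian `exp(-d^2 / 2 l^2)` and Cosine
`cos(2 pi d / phi)`, five of each, with scales set to the
{0.1, 0.25, 0.5, 0.75, 0.9} quantiles of the nonzero pairwise-distance
distribution. The bank spans short- to long-range and periodic structure;
because only distances enter, every downstream p-value is invariant to rigid
motions of the tissue (verified to 1e-8 in the test suite). Above 5000 spots
the quantiles are estimated from a fixed-seed subsample.

### Covariate-adjusted re-testing and SVG clustering (step 2)

Two SVGs with the same spatial pattern are correlated, so regressing one on
the other (or on shared factors) removes the spatial signal. For each SVG
`j`:

1. **Related set** `S_j`: all other SVGs whose Pearson correlation test with
   `j` passes BH at `alpha = 0.05` (adjusted within the candidate tests for
   this target). Spearman and fixed `|r|` thresholds are config
   alternatives.
2. **Covariates**: the raw member vectors if `|S_j| <= 3`; otherwise the top
   `k_j` principal-component scores of the centered member matrix, `k_j`
   chosen so at least 80% of the member variance is explained
   (`step2.var_threshold`).
3. **Adjusted test**: the step-1 test re-run with `X = [1, covariates]`.
   SVGs whose adjusted combined p survives BH at the step-1 FDR level keep a
   *unique pattern*; the rest are *explained* by their related genes.
4. **Dependency graph**: every explained SVG contributes edges to all of its
   related genes, weighted `|Pearson r|`; parallel edges keep the maximum;
   unique-pattern SVGs contribute none (they may still receive edges).
5. **Leiden** modularity clustering (resolution `step2.resolution = 1`,
   seeded) yields the spatial-pattern gene clusters; isolated nodes are
   singletons, and clusters below `step2.min_size = 5` are flagged
   singleton-like.

### Domain detection

Each non-singleton gene cluster is embedded into five "spatial PCs": gene
vectors are smoothed by Gaussian-kernel-weighted neighborhood averaging and
the smoothed cluster matrix is decomposed by PCA over spots. This is a
deliberately simple, self-contained stand-in for spatially aware PCA;
genuine external embeddings (e.g. SpatialPCA scores) can be substituted per
cluster through `embed.method = "external"`.

**Smoothing bandwidth.** The default bandwidth is 1.5x the median
nearest-neighbor distance. This is deliberately *density-invariant*: a
quantile of the full pairwise-distance distribution scales with tissue
extent rather than spot spacing, so any fixed quantile under-smooths sparse
arrays (label speckle) and over-smooths dense ones — at half the tissue
diameter, smoothing provably collapses banded architectures into a single
monotone gradient and domain recovery caps near ARI 0.5 no matter the
clustering method. A quantile override (`embed.bandwidth_quantile`) remains
for users who want explicit control; `0` disables smoothing (plain PCA).

Per-cluster embeddings are concatenated with each block standardized to unit
total variance, so a large cluster cannot drown out a small one — the point
of clustering first is precisely that weak-but-real patterns survive.
Spots are then clustered on a shared-nearest-neighbor graph (20 neighbors,
Jaccard weights, overlaps below 1/15 pruned) by Leiden at resolution 1 when
the number of domains is unknown, or — when a target count `k_d` is given —
by a geometric bisection of the Leiden/Louvain resolution (at most 50
iterations) or a Walktrap dendrogram cut.

The comparator arm (`baseline_pipeline`) reproduces the conventional
workflow: one joint embedding of the top 3000 SVGs (all of them when fewer
exist) with 20 components, then the same spot clustering.

### Evaluation metrics

* **ARI** — permutation-adjusted Rand index between predicted and true
  labelings (computed via scikit-learn; validated in-tree against a
  pair-counting enumeration).
* **PAS** — percentage of abnormal spots: the fraction of spots whose label
  differs from at least 6 of their 10 nearest neighbors. The spot itself is
  excluded from its neighborhood; distance ties are quantized (relative
  1e-9) and broken by ascending spot index so the score is deterministic and
  invariant to rigid motions.

## Synthetic data generators

### Scenario I — SVG classification

53 genes x 2000 spots (jittered grid on the unit square), reproducing the
standard SVG-classification benchmark layout:

| genes   | role                                              |
|---------|---------------------------------------------------|
| g1-g10  | independent noise                                 |
| g11-g20 | correlated (CS or AR(1), rho = 0.6) but non-spatial |
| g21-g30 | pattern 1 (linear gradient), increasing effect    |
| g31-g40 | pattern 2 (central hotspot), increasing effect    |
| g41-g50 | pattern 3 (off-center diagonal stripe), increasing effect |
| g51-g53 | unique patterns 4-6 at fixed strong effect        |

Within-group noise follows compound symmetry (`rho_ij = rho`) or AR(1)
(`rho_ij = rho^|i-j|`). The spatial effect multiplies the pattern's mean
field and rises linearly from 0.2 to 2.0 (in noise-sd units) across each
patterned group; unique genes use 2.0. The six pattern fields are smooth
parametric forms on the unit square, min-max bounded in [0, 1] and
constructed to be close to mutually uncorrelated (max pairwise |r| < 0.5 on
a 2000-spot grid), so that pattern groups are distinguishable in principle.

### Domain-template design — domain detection

A built-in layered-tissue template replaces any external annotation: 3484
spots on a jittered grid, five curved bands of roughly equal area (quantile
bins of `y + 0.15 sin(2 pi x)`), standing in for four cortex-like layers
plus a white-matter-like band. 2000 of 4865 genes are SVGs, split
800 / 150 / 1050 across three clusters mapped to band 1, bands 2-4, and
band 5 respectively. Each SVG is overexpressed (by `effect_size = 1` times
its own noise sd) in **one** band drawn from its cluster's band set —
spreading the middle cluster's genes across the middle layers keeps every
band identifiable while the cluster remains the biological unit. Gene
baselines and noise scales are drawn from log-normal distributions
(`exp(N(0, 0.5))` and `exp(N(-0.5, 0.25))`) to emulate the marginal
mean/variance heterogeneity of normalized spot-level data.

What the generators do **not** emulate: count-level sampling (values are
Gaussian on the normalized scale), within-spot cell-type mixtures, spatial
platform artifacts, or multi-sample structure. Passing the simulation-based
tests therefore demonstrates correctness of the statistical machinery and
the qualitative superiority of per-cluster embeddings under these
conditions, not end-to-end performance on any particular real platform.

## Numerics

* **Mixture tails.** `P(sum lambda_i chi2 >= q)` is computed by Imhof's
  inversion integral with `scipy.integrate.quad` (absolute tolerance 1e-6,
  acceptance threshold ~1e-3/pi on the p scale). Spectra longer than ~128
  terms are compressed: the largest-magnitude weights are kept exactly and
  the remainder is replaced, per sign, by a moment-matched scaled
  chi-square. The integration window is cut where the integrand envelope
  falls below ~2e-9 unless the window would contain more oscillations than
  the quadrature budget can resolve, in which case the infinite-interval
  transform is used. Equal-weight spectra short-circuit to the exact scaled
  chi-square. Failures fall back to Satterthwaite moment matching. The
  engine is validated against 1e6-draw Monte Carlo in the tests.
* **Shared-spectrum batching.** In step 1 all genes share the projected
  spectrum of each kernel, so the per-kernel tail function is evaluated on
  an 80-point quantile grid and interpolated monotonically on the log scale
  for large gene batches (error far below the integration tolerance).
* **Projected spectra without O(N^3) per gene.** Each kernel is
  eigendecomposed once, truncated at a relative |eigenvalue| mass of 1e-9
  (1e-5 for the per-gene adjusted tests of step 2). For a design `X`, the
  nonzero eigenvalues of `P K P` are those of `C' Lambda C` where
  `U' P U = C C'`, costing `O(r^3)` per gene instead of `O(N^3)`.
* **Step-2 tail hybrid.** Adjusted tests evaluate the body of the null with
  the four-moment (Liu-Tang-Zhang) approximation and recompute any p below
  0.15 exactly; body error (~1e-2 worst case, typically 1e-3) is
  inferentially irrelevant there and the adjusted p-values remain
  KS-uniform under the null.
* **Degenerate inputs.** Zero-residual genes (constant expression, exact
  collinearity) report p = 1 and are never SVGs; collinear covariates are
  dropped by pivoted QR with a warning; identical embedding rows yield a
  single domain.
* **Determinism.** All simulators draw from `numpy` Generators seeded from
  their configs; Leiden/Louvain/Walktrap are seeded; SNN and PAS tie-breaks
  are index-deterministic. Double runs are byte-identical.

## Problem sizes used in the test suite

Simulation-based tests run at reduced sizes chosen so the phenomena of
interest are preserved: scenario-I checks use 500 spots (10-20 replicates);
the domain-detection comparison uses 500 spots x 1000 genes with an
800-SVG 320/60/420 split (10 replicates), the smallest configuration at
which the pooled-baseline's overshadowing of minor clusters — and hence the
ARI/PAS advantage of per-cluster embeddings — is reliably expressed. The
full-size defaults (53 x 2000; 4865 x 3484 with 800/150/1050) are exercised
directly by the generator-fidelity tests.

## Known limitations

* The built-in embedding is a smoothing approximation, not a probabilistic
  spatial factor model; for real analyses the `external` hook accepts
  genuine spatially aware embeddings.
* Kernel construction and eigendecomposition are dense `O(N^2)`-memory /
  `O(N^3)`-time per kernel; beyond ~10^4 spots low-rank or projection-based
  approximations (not implemented) become necessary.
* The test operates on normalized expression; no count-level (Poisson/NB)
  likelihood is provided.
* Step-2 related-set selection is marginal; penalized-regression selection
  is out of scope.
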