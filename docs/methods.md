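# Methods

## Spatial model and the surrogate null

A parcellated map is a vector x over n labelled cortical regions with 3-D
centroid coordinates. Spatial structure is encoded by the weight matrix
W, w_ij = 1/‖c_i − c_j‖ for i ≠ j, zero diagonal. Coincident centroids are
an error (the kernel diverges); a row-normalization flag exists but is off
by default — the raw inverse-distance kernel is the reference
configuration, and normalization is symmetrized afterwards so the
eigenbasis remains orthogonal.

Global autocorrelation is Moran's I = (n/Σw)·(zᵀWz)/(zᵀz) with z the
centered map. Under exchangeability (random permutation of values over
regions) E[I] = −1/(n−1); smooth maps sit well above this.

The doubly-centered weight matrix HWH (H = I − 11ᵀ/n) has the constant
vector as an exact null eigenvector; the remaining n−1 eigenvectors are
the Moran eigenvector maps (MEM), orthonormal, each summing to zero,
ordered by descending eigenvalue (broad spatial scales first). All n−1
components are kept — no truncation, which would silently discard
fine-scale variance. Eigenvectors get a deterministic sign (largest
magnitude entry positive) so results are bit-reproducible across runs.

Surrogates (Moran spectral randomization, singleton procedure): project
the centered map on the MEM basis to get component scores r_k, flip each
score's sign independently at random, reconstruct, and rescale affinely to
the source map's mean and sample SD. Because Moran's I of a MEM
combination depends only on the squared scores, every surrogate has
exactly the source map's I; the sign flips randomize the spatial phase.
A variant that redraws score magnitudes as |r_k|·√2·cos φ (conserving
E[r_k²] rather than r_k² itself) was evaluated during design and found
conservative on very smooth maps — few effective components with
arcsine-distributed weights fatten the null's tails — so the pure
sign-flip form is the default; the procedure tag is recorded in every
`SurrogateSet`.

A correspondence test computes Spearman's r (mid-ranks for ties) between
two maps on their pairwise-complete region subset, regenerates the spatial
basis on that subset (a sub-basis is a fresh eigendecomposition of the
weight submatrix, not a slice), replaces the first map by n_null
surrogates, and reports p = (1 + #{|r_null| ≥ |r_obs|})/(1 + n_null).
Two-sided by default, since negative gene–receptor correspondences are
meaningful; one-sided tails and randomizing the second map instead are
options. The p-value floor is 1/(1+n_null); p is never zero. Defaults:
n_null = 10,000, α = 0.05. Rank-based r makes the test invariant to any
monotone rescaling (z-scoring is display-only), which the suite asserts.

Batch benchmarks derive per-row seeds as `seed + row_index`, so a batch is
reproducible and insensitive to evaluation order. Layer-wise benchmarks
test one layer-free receptor map against each layer's expression matrix;
within-region laminar profiles (each layer one data point) use exact
permutation p-values (all orderings enumerated up to 7 layers, seeded
Monte-Carlo beyond); the layer×layer cross-matrix (each gene–receptor pair
one data point) applies FDR jointly over all its entries.

## Supporting statistics

Benjamini–Hochberg FDR (step-up, via statsmodels), Pearson χ² on 2×2
proportion tables (no Yates correction by default — a toggle exists — with
degenerate margins rejected), and pooled-variance independent-samples t
with df = n_a + n_b − 2 and Cohen's d = Δmean / pooled SD. Each is a thin,
validated wrapper over scipy/statsmodels; the test-suite checks every one
against an independently hand-coded formula or enumeration oracle, keeping
implementation and oracle on separate routes.

## Connectome projection

x′_i averages the map over region i's outgoing connections, weighted by
connection strength; the diagonal is structurally zero so a region never
contributes to its own projection. Neighbours with missing values are
excluded and the weights renormalized over the observed ones; regions with
no (retained) outgoing connections — or none observed — become missing
rather than zero, since 0/0 is undefined, and are reported. Incoming-
connection and weight-threshold toggles exist for sensitivity analyses; no
threshold is applied by default. The projected map is convex in neighbour
values and invariant to per-row weight rescaling, both asserted.

## Gradients and region-wise profiles

PCA uses column z-scoring by default (correlation-matrix PCA): gene
columns differ in dynamic range and the analysis should not be dominated
by high-variance genes; covariance-matrix PCA (`scale=False`) is the
documented alternative. Features with missing values or zero variance are
dropped and reported. The decomposition is a deterministic SVD; since a
principal axis has no intrinsic sign, every component is oriented to
correlate positively with the row-mean of the preprocessed matrix (falling
back to a positive peak entry when that correlation vanishes), and
gradient correspondence additionally reports r under sign flip with
significance taken two-sided on |r|.

The region-wise profile transposes the usual question: for each region,
Spearman correlation across shared features between two datasets (each
data point a gene). Regions with fewer than 3 shared non-missing features
(configurable floor) are missing. Class contrasts delegate to the pooled
t/Cohen's d machinery; class labels are an input column of the
parcellation, not a built-in taxonomy.

## Synthetic study conditions

Generated maps are Gaussian fields on the MEM basis: independent N(0,1)
component scores weighted by rank^(−β) over all n−1 eigenvalue-ranked
components, reconstructed and standardized. β = 0 weights all components
equally, which is distributionally identical to exchangeable iid noise
(mean simulated I ≈ −1/(n−1)); increasing β concentrates variance on broad
scales and raises I monotonically. `calibrate_smoothness` maps β → mean I
for a given basis by simulation. On the 10×10 unit grid the
inverse-distance kernel caps attainable mean I near 0.345 (the
(n/Σw)·λ_max bound), so calibration toward higher targets lands at the
plateau.

Correlated pairs: y = ρ·z(x) + √(1−ρ²)·e with e an independent field at
the same β, then standardized; ρ targets the generating Pearson
correlation, and rank-based recovery tests use replicate bands rather than
point equality. The benchmark dataset plants ρ per gene–receptor pair
(defaults: 12 pairs, six at ρ = 0.9, six at 0, classes assigned
round-robin over GABA/glutamate/neuromodulatory); the layered variant
shares one receptor map across layers and plants the coupling only in the
designated layers (default L5). Gradient matrices are
outer(gradient, N(0,1) loadings) plus noise whose per-gene SD is
`noise_sd` × that gene's signal SD (default 0.3). Connectomes sample
directed edges at a given density with log-normal weights, forcing one
outgoing edge for any region left isolated (reported).

Default scale is 80 regions placed uniformly in the unit cube with a 0.05
minimum separation, 200 genes, 6 layers. The default smoothness β = 0.75
(mean Moran's I ≈ 0.18 at this geometry) was fixed by a design-stage power
analysis: it is smooth enough that naive tests are visibly miscalibrated,
while retaining enough effective spatial degrees of freedom that a planted
ρ = 0.9 effect is detected essentially always at n = 80; much smoother
fields (β ≥ 2) collapse onto a handful of MEM components and power
deteriorates sharply, which is a property of the inference problem, not of
the implementation. Every generator is a pure function of (config, seed);
regeneration is bit-identical, and generated objects round-trip through
the CSV writers unchanged.

What the generators deliberately do not emulate: transcriptomic count
noise, dropout, spatial capture artefacts, within-region heterogeneity, or
realistic cortical geometry. Fixtures are Gaussian fields on synthetic
point clouds — sufficient for validating rank-based inference machinery,
but passing tests say nothing about upstream preprocessing of real data.

## Numerical and interface choices

- Region and feature labels match exactly after whitespace/case
  normalization; fuzzy matching is refused so cross-atlas correspondences
  stay explicit in mapping tables. Aggregation over mapped regions is mean
  by default (median available).
- Missing values propagate through every stage; nothing is imputed.
- All numeric CSV output uses 10 significant digits, enough for exact
  textual round-trips of float64 at the precision that matters here.
- Pipeline exit codes: 0 success, 2 input/validation error, 3 statistical
  precondition failure (constant map, too few regions), each with a
  one-line diagnostic; logs go to stderr plus `run.log`, never interleaved
  with result tables.
- Eigenvalue comparisons, orthonormality and score-orthogonality checks
  use absolute tolerances of 1e-8; oracle comparisons in the test-suite
  use 1e-10 to 1e-12 (double-precision round-off across differing
  summation orders).

## Known limitations

- The surrogate null conditions on the observed map's Moran spectrum; at
  extreme smoothness (a few effective components) empirical p-values
  become slightly granular and mildly conservative.
- Inference assumes one map of the pair is exchangeable under the null
  given its spatial spectrum; the choice of which map to randomize is a
  convention (first argument by default) and can matter when coverage or
  smoothness differ strongly between the maps.
- No surface-mesh spin tests or variogram-matching surrogates; the MSR
  family on centroid distances is the only null model.
- PCA gradients are linear; no diffusion-map or other nonlinear embedding.
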