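# Methods

This note documents the models and numerical choices behind
`resistscape`: what each stage assumes, which parameters matter and why
their defaults are what they are, what the synthetic generator does and
does not emulate, and the known limitations.

## Raster model and preparation

Rasters are regular planar grids in projected meters, origin-anchored at
the upper-left corner, row-major, with a nodata mask; point lookups use
the cell-center convention. Only planar inputs are supported: buffers,
IDW weights and graph edge lengths are Euclidean, so geographic lon/lat
layers must be projected upstream. The IO format is the ESRI ASCII grid,
which round-trips values, origin, cell size and mask exactly.

Preparation steps are deliberately plain: block-mean aggregation
(conserves spatial means over fully covered regions), bilinear
interpolation for coarse-to-fine resampling, inverse-distance-weighted
interpolation of station tables with power 2 by default (the common
default of interpolation tools; configurable) and exactness at station
locations, a minimum-convex-polygon study extent dilated by an external
buffer (default 75 km), and an iterative variance-inflation-factor
screen (default threshold 2.5) that drops the worst predictor until all
VIFs pass. Ties in the VIF screen — typically exactly collinear layers —
drop the later-listed covariate, so derived layers lose to their
sources. Host cover and defoliation, when both present, are merged as
host − defoliation floored at 0 before the screen, collapsing the most
collinear pair into one interpretable layer.

## Resistance transformations

Raw covariates are affinely rescaled to r ∈ [0, 1] and passed through
one of eight two-parameter families built from two base curves,

* Monomolecular: f(r) = 1 − exp(−r/s) (saturating),
* Ricker: f(r) = r·exp(−r/s) (unimodal, peak at r = s),

with "Reverse" evaluating the base at 1 − r (argument reflection) and
"Inverse" reflecting the transformed values (value reflection). The
result is rescaled so valid cells span exactly [1, m]. These precise
definitions are this package's own fixing of a family that the
literature names but does not define uniformly; they reproduce the
qualitative shapes that matter (a decreasing-cost inverse monomolecular;
a mid-range-peaked reverse Ricker) while keeping the two-parameter
(shape s > 0, maximum resistance m > 1) contract. Exact numeric parity
with any other implementation is not claimed.

Anchoring the minimum at 1 makes the uniform (isolation-by-distance)
surface the m → 1 limit of every family, so distance-only behavior is a
nested special case of every landscape model — a property the optimizer
tests rely on. Composites are cellwise sums (resistances add as costs of
traveling through a cell), and each part's percent contribution is the
mean over cells of its share of the summed resistance.

Because [0, 1] rescaling is data-dependent, every fitted model stores
its calibration bounds (the raw min/max used); re-applying a model to a
scenario raster rescales with the *stored* bounds, clipped to [0, 1].
Without this, a uniform shift in a covariate would be invisible to the
projection.

## The movement graph and effective distances

Valid cells are nodes of a queen-neighborhood (8-neighbor) graph. Edge
conductance is the arithmetic mean of the two cells' conductances (1/R)
divided by the center-to-center distance, so diagonal edges are
down-weighted by √2; the harmonic-mean alternative is available behind a
flag. Edge cost is the reciprocal convention: distance × mean
resistance.

Commute distance is C(i,j) = vol(G)·R_eff(i,j), with vol(G) the total
node degree and R_eff the two-point effective resistance from grounded
Laplacian solves. All Laplacian systems go through one sparse LU
factorization per surface (scipy's splu); a dense pseudo-inverse path
exists as the independent test oracle and agrees to well below 1e-8.
Note a property of this definition worth knowing: uniformly rescaling
all resistances leaves C unchanged (R_eff scales up, vol scales down) —
commute distance counts random-walk steps, and the walk does not change.
Only *relative* resistance is identified, which is also why the MLPE
stage standardizes predictors.

Randomized shortest paths reweight the conductance-driven random walk by
exp(−θ·cost) with the target absorbing; expected edge flows come from
fundamental-matrix solves, and a cell's net passage is half the sum of
absolute net flows over incident edges plus the unit injection at the
endpoints (so both endpoints score exactly 1). θ ∈ (0, 20): θ → 0
recovers circuit current flow, θ large the least-cost path. Below
`circuit_tolerance` (default 1e-4, covering the production setting
θ = 1e-6) the exact circuit formulation is used instead: the two limits
coincide analytically, while the exact RSP solve at tiny θ is
ill-conditioned. Cost is length-weighted edge resistance, consistent
with the commute-distance graph. At θ large the solve underflows once
θ·(path cost) approaches ~700; this regime exists for limit tests, not
production mapping.

## MLPE mixed models

For populations i < j, y_ij = β₀ + x_ij'β + u_i + u_j + ε_ij with
u ~ N(0, σ²ᵤ), ε ~ N(0, σ²ₑ). With Z the pair-to-population incidence,
Var(y) = σ²ₑ(I + λ ZZᵀ), λ = σ²ᵤ/σ²ₑ. Fitting profiles the likelihood
over λ on a log grid via bounded scalar minimization (the λ = 0 boundary
is always checked), with GLS for β and a closed-form σ̂²ₑ at each λ —
made cheap by eigendecomposing ZZᵀ once per population count (it depends
only on the complete pair set, so bootstrap replicates reuse it). Full
maximum likelihood, not REML, so AICc comparisons across different
fixed-effect structures are valid. A variance floor of 1e-10 guards
degenerate exact fits. Designs must cover the complete pair set; the fit
refuses anything else.

AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1) with k = 1 intercept + p slopes +
2 variance components + 2 per optimized surface (its shape and maximum
were tuned to this response), and n = the number of populations, not
pairs — pairs are not independent observations. Both conventions are
config-exposed. R²m = σ²_f/(σ²_f + 2σ²ᵤ + σ²ₑ) and R²c adds 2σ²ᵤ to the
numerator; the factor 2 appears because each pair carries two population
effects.

## Optimization

The chromosome holds, per covariate, a continuous family gene (rounded
to one of the 8 families at decode), log₁₀(shape) and log₁₀(max
resistance); log-scale genes make the search roughly scale-free across
the wide bounds s ∈ [0.01, 10], m ∈ (1, 2500]. The GA is elitist (best
chromosome always survives, so the objective trace is non-decreasing)
with tournament selection (k = 3), BLX blend crossover (α = 0.5,
probability 0.8) and per-gene Gaussian mutation (probability 0.1, sd =
15% of the gene range), clipped to bounds. Library defaults are
population 50, max 200 generations, stop after 25 stalled generations;
the pipeline's desk-scale defaults are smaller (population 20, ≤ 20
generations) and all settings are config-exposed. Graph topology is
built once per optimization; each evaluation only recomputes edge
conductances, refactorizes, and refits the MLPE (a cached-topology
evaluation is asserted equal to a cold one). A chromosome that
disconnects the site graph scores −∞ rather than aborting the run.
Replicate runs draw independent seeds from the master seed and report
cross-run dispersion of selected families and parameters.

The objective during search is the MLPE log-likelihood; AICc enters only
at the selection stage, where parameter counts differ across candidates.

## Model selection and bootstrap

Candidates are every non-empty covariate subset plus the intercept-only
null and the distance-only (all-ones resistance) model: 2^v − 1 + 2
models, 33 for five covariates. The pipeline's default caps subsets at
pairs to keep desk-scale runs in minutes. Ranking uses ΔAICc < 2 for the
top set, ties broken by fewer parameters then name. Rank stability:
populations are subsampled *without replacement* (the default fraction
0.75 of 24 populations gives 18 populations and 153 pairs per
replicate), all pairwise matrices are restricted, and every candidate is
fully refit — variance components included — with its previously
optimized surfaces (no re-optimization inside the bootstrap). Tied
models all receive the top rank, so top-rank percentages can exceed 100
in aggregate; this is documented behavior, not an error.

## Connectivity mapping and projection

Nodes are a square lattice over the buffered study extent (intersected
with the raster bounds), spacing tuned so the count lands within 5% of
the request where geometry allows, snapped to cell centers; nodes on
nodata are dropped and counted. The cumulative map sums per-pair net
passages over all unordered pairs. At the circuit setting this uses one
grounded factorization and one solve per node — potential columns
superpose into per-pair currents — and is asserted equal to the
pair-by-pair computation to 1e-8; the full-scale design this enables
(tens of thousands of nodes) remains cluster-scale, and the desk-scale
default is 400 nodes, which preserves the corridor pattern at test
sizes. Buffer cropping happens after summation and never changes
interior values. Corridors keep cells at or above the (1 − keep)
quantile (linear interpolation; threshold ties kept), default keep 0.5.

Projection gathers the top-ranked (ΔAICc < 2) models of each replicate
run, rebuilds each from its stored transformation parameters and
calibration bounds on the scenario stack (swapped covariates take
precedence; everything else is the present layer — e.g. host cover held
constant for a 2040 precipitation scenario), averages resistance per
pixel across models, and reruns the mapping with the same node design.
The difference map is future − present; an identity scenario reproduces
the present map exactly. "Passages" are net node throughflow
(circuit-consistent at θ → 0); gross-passage aggregation is a noted
alternative, not implemented.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study design the pipeline targets at reduced
size: a 50×50 grid of 5 km cells, 24 sampling sites with ≥ 2-cell
separation, ~20 diploid individuals per site and 2000 biallelic loci by
default (the motivating design used 24 sites, 447 individuals and 3562
SNPs on a provincial-scale 5 km grid).

* **Covariates** are stationary Gaussian random fields with exponential
  covariance, built by circulant embedding on a doubled torus (negative
  embedding eigenvalues clipped — standard, and rare at these sizes),
  correlated across covariates through a shared common factor
  (pairwise correlation = `covariate_corr`), and affinely mapped to
  plausible physical ranges by name (precipitation 20–120 mm, host
  cover 0–100%, ...). Affine maps preserve all correlation structure.
* **Genetic distances** come from the exact MLPE generative model on
  standardized commute distances of the true surface. Defaults
  (β₀ = 0.05, β₁ = 0.02, σᵤ = 0.0125, σₑ = 0.0155) were chosen so the
  generative variance shares give marginal/conditional R² near 0.42/0.75
  — the regime the method is meant to operate in — at Fst-like response
  magnitudes.
* **Genotypes** follow a correlated Balding–Nichols approximation: per
  locus an ancestral frequency p ~ U(0.1, 0.9); population frequencies
  have Beta(p(1−F)/F, q(1−F)/F) marginals with divergence F =
  `fst_scale` (default 0.1), coupled through a Gaussian copula with
  correlation exp(−d/φ) so pairwise divergence grows as
  ≈ F(1 − exp(−d/φ)) with resistance distance; genotypes are
  Binomial(2, freq). The copula construction (rather than clipped
  Gaussian frequency deviations) keeps the marginal variance exact, so
  the Weir–Cockerham estimator recovers the target divergence within
  Monte-Carlo error.

Not emulated: coalescent genealogies, linkage, selection, temporal
outbreak demography, anisotropic dispersal, and real spatial structure
of any particular region. Passing tests therefore demonstrate that the
estimators and the optimization recover the structure *they assume*; on
real data, model misspecification (non-equilibrium demography, IBD
nonlinearity, unmodeled layers) can dominate, and the bootstrap rank
stability is the in-package guard against overinterpreting a single
ranking.

A note on two estimator fine points the tests encode: (1) pairwise
Weir–Cockerham θ on two *identical* samples is not 0 but ≈ −1/(2n−1) —
the finite-sample correction expects sampling noise between independent
samples and finds none — vanishing with sample size; (2) the fraction of
negative pairwise estimates is reported, never truncated, because
truncation would distort the regression response.

## Numerical choices and degenerate inputs

* Sparse LU for all Laplacian and RSP solves; connectivity is checked
  before any solve and disconnected queries fail with the components
  named.
* Constant covariates are rejected at rescaling (no resistance
  information); exactly collinear covariates report infinite VIF and are
  dropped first with a warning.
* Monomorphic population pairs score Fst 0 with a warning; pairs with no
  locus having ≥ 2 genotyped individuals on both sides are an error
  naming the pair. Missing genotypes recompute per-locus, per-pair
  sample sizes; nothing is imputed.
* All randomness flows from integer seeds through numpy Generators with
  per-operation streams, so identical configs and seeds are bit-identical
  regardless of call order; GA replicate runs spawn child seeds from the
  master seed.
* Fst linearization (Fst/(1−Fst)) before regression is available via
  `build_design(..., linearize=True)`; the default regresses raw Fst.

## Problem sizes

Defaults throughout are desk-scale by design: the full synthetic
pipeline (50×50 grid, 24 sites, 2000 loci, 3 candidate surfaces × 5 GA
replicate runs, 200 bootstrap replicates, 400-node passage maps, one
scenario projection) completes in a few minutes on one CPU, and
`scripts/acceptance.py` regenerates all reported quantities in under a
minute plus the GA-recovery experiment. The study-scale configuration
(1000-replicate bootstrap, ten GA replicate runs, 50,000-node maps) uses
the same code paths and is a matter of budget, not implementation.
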