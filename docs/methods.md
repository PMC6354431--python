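# Methods

## Slice geometry

A cross-section is a 2-D greyscale raster with isotropic pixel spacing
(mm/pixel); rows run cranio-caudally, columns medio-laterally.  Images must
be pre-oriented to this convention; the stack reader's `rotate` flag
applies quarter turns for stacks stored otherwise.  Anisotropic spacing is
rejected rather than resampled: resampling would break the closed-form
oracles the geometry is validated against, and scanners produce isotropic
transverse pixels in practice.

Bone tissue is every pixel with intensity at or above a single per-slice
minimum threshold, mirroring the manual segmentation workflow this models;
`otsu_threshold` is offered as an explicit automatic alternative and is
never applied silently.  Pixels are **point areas at their centres**:
`SMA = Σ A·d²` carries no per-pixel self-moment term (h²/12).  The omission
biases SMA low by ~(h²/12)·CSA, which is O(h²) relative to the moment of a
bone-like section, while the staircase boundary error is O(h); at 0.05 mm
spacing on millimetre-scale sections both are comfortably inside the 1%
validation band.  A single-pixel section therefore has SMA = 0, and its
MOD is defined as 0 (the extreme-fibre distance is also 0).

Stacks are downsampled to 21 slices at 0, 5, …, 100% of the
proximal-to-distal slice span: index k maps to
`proximal + round(k·span/20)` with round-half-away-from-zero.  The rounding
rule is a deliberate choice (banker's rounding would be equally defensible;
no convention is canonical here); spans of 20–39 slices can produce
duplicate indices, which are retained.  Statistics downstream use the 19
interior increments (5–95%) — the extremes sit in articular bone where
cortical geometry is not meaningful.

Dimensionless traits divide the trait's n-th root (n = its length
dimension) by the bone's inter-articular length L: `CSA½/L`, `SMA¼/L`,
`MOD⅓/L`.  The resistance ratio is defined on the dimensionless scale,
`R = (SMA¼/L)/(CSA½/L)`, not as raw SMA/CSA.  Illustrative stresses are
`σ_compression = F/CSA` and `σ_bending = M·y/SMA` (MPa with N, N·mm, mm
inputs).

## Synthetic data

No empirical scans or trait tables are available to this pipeline, so all
inputs are generated:

* **Bone stacks** are elliptical annuli (outer semi-axes a, b; endosteal
  a′, b′; b cranio-caudal), linearly interpolated along the stack, with
  exact CSA = π(ab − a′b′), SMA_ML = (π/4)(ab³ − a′b′³), MOD_ML = SMA_ML/b.
  Defaults (4 × 3 mm outer, 2.5 × 1.8 mm inner, 30 mm length, 0.05 mm
  pixels) approximate a small-carnivore humerus diaphysis.
* **Trees** are pure-birth with the requested tip count, rescaled to unit
  height so α and r are expressed per total tree depth; 28 tips is the
  default study size.
* **Habit histories** are continuous-time equal-rates Mk over four states
  (generalist, fossorial, natatorial, scansorial) from a uniform root
  state.  The default per-transition rate q = 0.5 (lineages leave their
  state at rate 3q) yields histories with a handful of changes per
  root-to-tip path and all four habits usually realised at 28–64 tips —
  enough signal for mapping without saturating.
* **Traits** are simulated by exact per-branch (BM/EB) or per-segment (OU)
  Gaussian transition sampling — no Euler discretization, so there is no
  step-size tolerance to tune.  BM-family and EB draws consume one Gaussian
  per branch in fixed preorder, which makes the degenerate reductions
  (EB with r = 0; multi-rate BM with equal rates) reproduce single-rate BM
  bit-for-bit (EB) or to rounding (BM3/BM4) at matched seeds.
* The reference strong-selection condition used throughout validation is
  αT = 8 with optima spaced 4 stationary standard deviations apart
  (σ² = 1, so SD = √(1/16) = 0.25, spacing 1.0).  Wider spacing does not
  make map-averaged selection easier: when optima are extremely far apart,
  small errors in the sampled histories near the tips dominate the OU mean
  and multi-rate BM can absorb the variance instead.

What the generator does **not** emulate: measurement error and
intraspecific variation, non-ultrametric (fossil) trees, correlated
evolution among traits or increments, habit-dependent diversification, and
cortical geometry beyond concentric ellipses.  Passing tests therefore
demonstrate correctness of the machinery under the stated models, not
robustness of the biology to violations of them.

## Increment-wise statistics

The ahistorical test at each interior increment is a classical one-way
F test with Tukey HSD pairwise comparisons (Tukey–Kramer correction for
unequal group sizes, via statsmodels).  Degenerate all-equal data returns
F = 0, p = 1 rather than NaN.  Pairwise results are reported only at
increments whose omnibus p passes the Bonferroni family threshold
α/m (0.05/19 ≈ 0.0026 for the standard family); a different family size is
honoured with a warning.  Species with multiple specimens are averaged to
one value per species before any comparative test.

The phylogenetic ANOVA whitens the trait and the habit design matrix by
C^(−1/2) (symmetric eigendecomposition of the BM covariance; a singular C
from zero-length branches is an error) and assesses the GLS F by residual
randomization: reduced-model (intercept) residuals are permuted, added to
the reduced fit, and F recomputed; p = (#{F* ≥ F} + 1)/(n_perm + 1), so the
smallest attainable p is 1/(n_perm + 1).  The default n_perm = 999 is a
runtime compromise and is configurable — a study quoting p = 0.0001 needs
9,999.

The phylogeny–habit association uses two-block PLS: block A holds tip
scores from the eigendecomposition of the doubly centered C (a principal
coordinates embedding of the tree), block B the centered habit indicators;
r_PLS is the correlation of the first pair of singular-vector scores of
the cross-block covariance, tested by permuting tip-to-habit assignment.
The block-A construction is a documented method choice; any
rotation-equivalent embedding gives the same statistic.

## Trait-evolution models

All likelihoods are exact multivariate-normal densities on the tips.

* BM1: mean z0·1, covariance σ²C.
* Multi-rate BM: V_ij = Σ_k σ²_k · (shared root-to-MRCA time in regime k).
* OU (Hansen): V_ij = σ²/(2α)·e^(−α(T_i+T_j−2s_ij))·(1−e^(−2αs_ij));
  the tip mean is the path integral of the optima with exponentially
  decaying memory.  The root state is pinned to the root regime's optimum
  (no free z0) — the common OUM convention; multi-optimum models share one
  α and one σ² across regimes.  Parameter counts: BM1 2, BM3 4, BM4 5,
  OU1 3, OU3 5, OU4 6, EB 3.
* EB: BM on a branch-length transform, each branch contributing
  σ₀²(e^(rt₂) − e^(rt₁))/r, r ≤ 0.

Fitting profiles everything linear: optima/ancestral states by GLS and the
overall scale analytically, leaving a bounded 1-D search over α
(∈ [10⁻⁹, 50] per unit height, log-spaced grid of 24 plus seeded random
starts, local refinement from the best three) or over r (∈ [−10, 0] per
unit height), and a small L-BFGS-B search over log rate ratios for
multi-rate BM (overall scale profiled; 5 seeded starts).  An α estimate
within a factor ~3 of either bound is flagged `alpha_at_bound`.

The Wald standard error of α comes from the curvature of the profile
log-likelihood at the optimum (central differences at ±0.1% of α̂); the
profile curvature equals the (α, α) entry of the inverse full-Hessian
covariance, and a test verifies agreement with an explicit full-Hessian
computation.  α is "significant" when the 95% Wald lower bound exceeds
10⁻⁶ per unit tree height; boundary fits and fits without a usable
curvature are never significant, and intervals whose upper/lower ratio
exceeds 10⁴ are flagged implausibly wide.  A profile-likelihood interval
would be the natural refinement; Wald was chosen as the simplest defensible
default.

AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) exactly; Akaike weights
w_i = e^(−Δ_i/2)/Σe^(−Δ_j/2).

## Stochastic character mapping

The equal-rates Mk likelihood is computed by Felsenstein pruning with the
closed-form ER transition matrix and a uniform root prior (a stationary
prior is the obvious alternative; uniform is the package default).  q is
optimized on a log grid with bounded refinement; a monomorphic character
returns a flagged boundary fit.

Histories are sampled by the standard two-pass scheme: node states
root-down from the pruning conditionals, then each branch's path
conditional on its endpoints — by rejection sampling of forward Mk
realizations (cap 10,000 attempts) with an exact uniformization sampler as
fallback (jump count from the Poisson–R^n mixture, intermediate states by
forward–backward sampling, jump times as uniform order statistics; the
uniformized ER jump chain has no virtual jumps).  Sampled maps tile every
branch exactly and reproduce the observed tips by construction.

`fit_across_maps` fits regime-free models once and regime-dependent models
on every map (three-regime models first collapse fossorial + generalist
into a shared background regime); AICc and parameters are arithmetic means
over maps, weights come from the mean AICc, and the best model is the
lowest mean AICc with exact ties broken toward fewer parameters.  Maps in
which a regime required by the model never occurs are dropped from that
model's average; losing more than half the maps marks the model
unreliable.  For mapped OU models the α flag is the majority vote of the
per-map screenings.  The reference design uses 500 maps; validation suites
use 10–50, where the mean AICc is already stable to well under one AICc
unit.

## Pipeline

`run_pipeline` drives geometry → species means → gated ANOVA → RRPP + PLS
→ mapping → model comparison → best-model summary from one YAML config and
writes TSV tables plus a JSON manifest of the configuration.  Every
stochastic stage derives its seed from the master seed through a stable
CRC32 hash of the task identity (stage, bone, trait, increment), so
results are independent of execution order.

## Validation problem sizes

The shipped validation (tests and `scripts/acceptance.py`) uses: raster
oracles at 0.05 mm spacing; 50 random ≤8-taxon fixtures against
brute-force likelihood constructions (tolerance 10⁻⁶); σ² recovery over
200 datasets at 128 tips (median within 10%); θ-ordering recovery over
30–40 datasets at 64 tips under αT = 8; model selection over 10–20
end-to-end replicates with 25–50 maps; RRPP type-I error over 300–500
null datasets at 199 permutations; and 3,000–5,000 sampled maps against an
exact 4-tip enumeration posterior.  These sizes keep a full run at a few
minutes on one core while leaving the Monte-Carlo bands far from the
pass/fail boundaries.

## Known limitations

* Single-trait models only; no multivariate or measurement-error variants
  (OUMV/OUMA-style per-regime α or σ² are likewise out of scope).
* Wald-based α screening can be anticonservative at small n; profile
  intervals are not yet implemented.
* The PLS block construction fixes one of several equivalent embeddings.
* The geometry path assumes pre-oriented, isotropic, segmented slices;
  there is no DICOM ingestion or density calibration.
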