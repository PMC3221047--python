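# Methods

## Model

The data are summary activation estimates for N trials over P voxels,
arranged as **Y** ∈ ℝ^(N×P). Each trial is a linear combination of Q
hidden pattern components plus noise:

    Y = Z U + E

**Z** (N × Q) holds per-trial loadings (indicator columns for categorical
designs). The components **U** (Q × P) are treated as random effects over
voxels: each voxel's component vector u_p is multivariate normal with
mean **a** and covariance **G**, and the noise entries are i.i.d.
N(0, σ_ε²) over trials within each voxel. Marginally, after mean removal,
the voxel columns of Y are i.i.d. N(0, V) with

    V = Z G Zᵀ + I σ_ε².

Estimating **G** rather than the patterns themselves converts an
underdetermined estimation problem (Q + N unknown patterns from N
observations) into a well-posed covariance-estimation problem whose
difficulty does not grow with P. Given estimates (Ĝ, σ̂_ε²), the patterns
are recovered by the best linear unbiased predictor
Û = G Zᵀ V⁻¹ Y.

Key assumptions: trials are independent given the components (violations
such as within-run covariance of estimation errors are modelled
explicitly by extra run components, not ignored); voxels are exchangeable
draws from the component distribution (the spatial extension below relaxes
independence but not exchangeability of variances); the mean activation
per component is a nuisance removed up front.

## Constrained covariance via factor bases

G must be positive-semidefinite and often structured: a common activation
component uncorrelated with stimulus components, equal variances across
the levels of a factor, a covariance shared only by matching levels.
Both requirements are met by writing G = A Aᵀ and constraining the factor,
A(θ) = Σ_h θ_h B_h, with a fixed catalogue of basis matrices B_h:

- `build_one_factorial(K, n)` — unconstrained lower-triangular A,
  H = K(K+1)/2 parameters; G is an arbitrary PSD matrix.
- `build_common_pattern(K, n, control_trials, anchor_pairs)` — a common
  component loading on every trial (and measured alone in control
  trials), block-diagonal A so the common component is exactly
  uncorrelated with the K stimulus components. Without control trials
  the common/shared-covariance split is unidentified; the model then
  requires at least one anchored (structurally uncorrelated) stimulus
  pair, implemented by dropping the corresponding factor element.
- `build_factorial(C, L, runs)` — per-condition common components
  (lower-triangular C × C factor), level components as one C × C factor
  replicated across levels (equal variances per condition, matched-level
  covariance γ_β, zero otherwise), and optionally per-run components as
  the same replication across runs (uncorrelated across runs).

Only G = A Aᵀ is reported, so the sign/rotation indeterminacy of A is
irrelevant; the lower-triangular convention makes the parameterization
canonical.

## Estimation

Parameters are estimated by maximum likelihood on mean-removed data. The
component means satisfy a = Z⁺ ȳ (ȳ the voxel-averaged trial vector)
independently of G, and Z a is subtracted before fitting. ML rather than
REML is used; the intended regime is large P, where the single
voxel-mean degree of freedom removed per component is negligible.

EM operates on the reparameterization y_p = Z A w_p + ε_p with
w_p ~ N(0, I_Q):

- E-step: Σ_w = (Aᵀ Zᵀ Z A / σ_ε² + I)⁻¹, Ŵ = Σ_w Aᵀ Zᵀ Y / σ_ε²,
  and sufficient statistics S₁ = Zᵀ Y Ŵᵀ, S₂ = Ŵ Ŵᵀ + P Σ_w.
- M-step: the expected complete-data objective is exactly quadratic in θ
  (A is linear in θ), so θ solves the H × H system
  M θ = c with M_hg = ⟨B_h, Zᵀ Z B_g S₂⟩ and c_h = ⟨B_h, S₁⟩; σ_ε² is then
  updated in closed form from the expected residual sum of squares
  (including the P·tr(Σ_w) term). Because the θ-minimizer does not
  depend on σ_ε², this is an exact joint M-step and the marginal
  log-likelihood is non-decreasing every iteration.

Everything is reduced to the Q-dimensional statistics Zᵀ Z, Zᵀ Y Yᵀ Z and
tr(Y Yᵀ), so per-iteration cost is independent of both P and N. The same
core runs on a stack of replicate datasets sharing one design
(`em_fit_replicates`), which is how the Monte-Carlo grids are computed.

Numerical choices:

- Likelihood and BLUP use the Woodbury/determinant-lemma reduction to
  Q-dimensional solves; a dense O(N³) path exists for validation and for
  σ_ε² = 0, and both agree to 1e−8 relative.
- Initialisation: method of moments. Ĝ₀ = (Z⁺Y)(Z⁺Y)ᵀ/P − σ̂₀²(ZᵀZ)⁻¹
  with σ̂₀² from the OLS residual; Ĝ₀ is projected onto the PSD cone with
  its eigenvalues floored at 0.05·σ̂₀² (θ = 0 is a stationary point of
  EM, so starts must stay away from the zero factor), factored, and
  projected onto the basis span by least squares. Optional restarts
  perturb the start multiplicatively with a seeded generator.
- Convergence: relative log-likelihood change < 1e−8 (default),
  max_iter = 1000; non-convergence is reported via a flag, not an error.
- σ_ε² is floored at 1e−12 of the mean data variance to keep V
  invertible.
- All randomness flows through explicit seeds; results are reproducible
  bitwise given (inputs, seed).

For the unconstrained balanced one-factorial design the moment start is
already the ML fixed point and EM converges in one step; constrained
models typically need tens of iterations. The EM optimum matches direct
numerical maximization of the marginal likelihood to better than 1e−3
log-likelihood units on randomized small instances (tested).

## Similarity estimators

`corrected_correlations` returns ρ_ij = γ_ij/(σ_i σ_j) from an estimated
G. Components whose variance falls below a relative stability floor
(default 1e−6 of the mean diagonal) have their correlations reported as
undefined (NaN) rather than clipped: normalizing by a near-zero variance
produces estimates with unbounded sampling variance, and masking is the
honest summary. Because G = A Aᵀ is PSD by construction, defined entries
always lie in [−1, 1].

Three naive estimators are provided as baselines, each with its known
bias direction (all verified by simulation in the test suite):

- sample correlations between condition-mean patterns shrink toward zero
  with noise; expectation γ_ij/√((σ_i² + σ_ε²/n)(σ_j² + σ_ε²/n)). The
  general-variance product-of-square-roots denominator is used; the
  equal-variance form σ_i σ_j + σ_ε²/n is its special case (the two
  printed forms in the source literature differ for unequal variances;
  this package documents and uses the general one, which is also what
  the matched/non-matched cross-condition expectations use).
- subtracting a measured control pattern (fixed-effects common-pattern
  correction) shares the control's noise across all residuals: low
  correlations are biased upward, increasingly so with noise. For pairs
  whose true correlation is high the same mechanism pulls the estimate
  down toward the common bias level, so "biased upward" applies to the
  low-correlation pairs.
- subtracting each condition's mean pattern induces a negative bias
  (residuals within a condition are anti-correlated by construction)
  that grows with noise.

Mean-of-ratio caveat: the per-replicate corrected correlation is a
bounded ratio statistic; at small P and high noise its Monte-Carlo mean
sits slightly inside the true value (e.g. ≈ 0.76 for a true 0.8 at
σ_ε² = 10, P = 100 in the common-activation design) even though the
underlying Ĝ is unbiased. This is a property of the summary, not of the
estimator; grid-averaged summaries in the validation suite stay within
±0.05 of truth.

`mds_embed` performs classical (Torgerson) scaling of d = 1 − ρ with the
full eigenvalue spectrum returned for dimensionality assessment;
reflections are fixed by making the first stimulus's coordinates
nonnegative.

## Spatial structure

Each component block j may have its own spatial covariance Σ_j over
voxels, giving the separable model var(vec U) = blockdiag(G_j ⊗ Σ_j) with
a squared-exponential correlation exp(−δ²/(2 s_j²)) at voxel distance δ;
the noise field has its own kernel. Full joint inversion of the Kronecker
model is deliberately out of scope (it destroys the P-independence of the
fit); instead the approximate two-step procedure is used:

1. fit the component model ignoring spatial structure (the marginal
   trial covariance is unchanged because the kernels have unit average
   variance, so Ĝ remains consistent);
2. predict Û by BLUP, pool the binned spatial autocorrelation over each
   block's rows (rows mean-centred over voxels, every voxel pair
   weighted equally, unordered pairs counted once), fit s by weighted
   least squares of exp(−δ²/(2s²)) on the binned values (raw values, not
   log-transformed, so negative sample ACF values are tolerated; bounded
   scalar minimization on [0, max distance] after a deterministic grid
   scan), and report FWHM = 2√(ln 2)·s — the width of the Gaussian
   smoothing kernel (SD s/√2) that would induce autocorrelation SD s on
   white noise.

Default distance bins are adapted to a unit lattice (face neighbours,
diagonal neighbours, then equal-width bins); they are fully
user-configurable, and empty bins are excluded from the fit.

Known biases of the two-step estimates (all reproduced in the tests):
the level-block kernel estimate is pulled toward the condition-block
value when the true widths differ; a smooth noise field is partially
absorbed into the BLUP patterns, so the residual-based noise-kernel
estimate underestimates strongly smooth noise (ŝ_ε ≈ 1.35 for a true 2)
and the level variances σ̂_β² are biased downward once the component FWHM
approaches the ROI radius. Within FWHM < 3 voxels on the radius-3.5
sphere, component variances and correlations stay within 0.1 of truth.

## Synthetic data

The generators draw each block's component rows from a unit-variance
Gaussian field over voxels (i.i.d., or with the squared-exponential
kernel via a jittered Cholesky factor when coordinates are given), colour
them by the Cholesky factor of the block's G, mix with Z and add noise.
Because the model is separable (G ⊗ Σ), field-then-colour sampling is
exact. Uninformative voxels are emulated by zeroing the level-block rows
at a random voxel subset, i.e. a per-voxel variance of zero for that
block.

Scenario defaults are the study conditions used throughout validation:

- one-factorial: 3 stimuli, n = 5 trials each, P = 100, unit component
  variances, correlations (0, −0.2, 0.8), noise grid {0.5, 2, 5, 10};
- common activation: adds a common component of variance 4 and a 5-trial
  control condition;
- two-factorial: 2 × 4 design, σ_α² = 2, σ_β² = 1, γ_β = 0.5, grids over
  σ_ε² ∈ {0.5, 4, 8} and γ_α/σ_α² ∈ {0, 0.45, 0.9}; n = 5 trials per
  cell and P = 100 are adopted from the one-factorial study (the later
  studies leave them unstated);
- voxel selection: the two-factorial truth with σ_ε² = 4, γ_α = 0 and an
  uninformative fraction ∈ {0, 0.25, 0.5, 0.75};
- spatial: the factorial design on the lattice sphere of radius 3.5
  voxels (179 voxels by exhaustive enumeration; ROI constructions that
  trim boundary voxels give slightly smaller counts, so the radius — not
  the count — is the configurable quantity), σ_ε² = 3, σ_α² = σ_β² = 1,
  γ_α = 0.3, γ_β = 0.5, s_α = 1, s_β and s_ε ∈ {0, 1, 2}.

What the generators do *not* emulate: first-level time-series estimation
(HRF convolution, temporal autocorrelation, drift), non-Gaussian voxel
distributions, heterogeneous per-voxel noise variances, and run-to-run
nonstationarity. Passing the validation suite therefore shows that the
estimator recovers the generating structure under the model's own
assumptions and the stated perturbations (spatial correlation, voxel
mixtures, common components) — not that those assumptions hold in any
particular real dataset.

Monte-Carlo sizes: the validation grids use 500 replicates per cell
(100 for the spatial study), chosen to bring the Monte-Carlo standard
error of grid-cell means to roughly 0.01–0.02, well inside the
assessment tolerances.

## Interfaces

Datasets are tab-separated text (data matrix with a header row; trial
metadata with `trial`, `condition`, optional `run`; coordinates with
`voxel_id`, `x`, `y`, `z`); models and fit results are JSON. Output files
carry a provenance comment (version, seed, config hash) and are written
atomically. The `pcmodel` CLI is a thin layer over the library:
`simulate`, `fit`, `similarity`, `spatial`, and `grid` (scenario-grid
driver configured by JSON). Continuous (parametric) design columns are
accepted by the types but no builder constructs them; neuroimaging volume
formats are out of scope (the model consumes extracted trial × voxel
matrices).

## Limitations

- ML, not REML; a ReML flag is reserved but unimplemented (negligible
  difference in the intended large-P regime).
- Model comparison by marginal likelihood, priors/variational schemes,
  and corrected Euclidean distances are not implemented.
- The anchoring mechanism in the common-pattern model guarantees an
  exact structural zero for pairs anchored to the first stimulus
  component; anchors between later pairs remove a degree of freedom but
  interact with the triangular parameterization.
- The two-step spatial procedure is approximate by design; see the bias
  notes above.
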