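# pcmodel — pattern-component modelling of multivariate activity patterns

Representational similarity analysis asks how similar the distributed
activity patterns evoked by different stimuli or tasks are within a brain
region. The standard practice — Pearson correlations between
condition-mean patterns over voxels — is quantitatively uninterpretable:
sample correlations shrink with measurement noise, inflate with shared
nonspecific activation, and change with the mix of informative and
uninformative voxels, so they cannot be compared between regions,
sessions, or people.

`pcmodel` implements a random-effects decomposition that fixes this. The
trial-by-voxel data matrix **Y** (N trials × P voxels) is modelled as a
linear mixture of Q hidden *pattern components* plus i.i.d. trial noise,

    Y = Z U + E,          u_p ~ N(a, G),   e_p ~ N(0, I σ_ε²),

where **Z** (N × Q) encodes the design and the columns of **U** (one per
voxel) are random draws with component covariance **G** (Q × Q). The
diagonal of **G** measures each component's strength ("energy") over
voxels; the off-diagonals measure component similarity. The *corrected
correlation*

    ρ_ij = γ_ij / (σ_i σ_j)

computed from the estimated **G** is invariant to noise level, common
activation, and voxel selection — the quantity that *can* be compared
across regions.

What the package provides:

- **Structured component models** (`build_one_factorial`,
  `build_common_pattern`, `build_factorial`): G is parameterized as
  **G = A Aᵀ** with **A(θ) = Σ_h θ_h B_h** a linear combination of basis
  matrices, so structural constraints (a common activation component
  uncorrelated with stimulus components; equal level variances; a
  matched-level covariance; per-run components) are exact by
  construction and G is always positive-semidefinite.
- **Maximum-likelihood estimation by EM** (`em_fit`): because A is linear
  in θ, the M-step is a small linear solve; per-iteration cost is
  independent of the number of voxels and trials. `em_fit_replicates`
  fits whole Monte-Carlo batches in one vectorized run.
- **Similarity estimators** (`corrected_correlations`, plus the naive
  baselines `sample_corr_mean_patterns`, `control_subtracted_corr`,
  `condition_mean_subtracted_corr`, their closed-form expectations, and
  classical MDS embedding `mds_embed`).
- **BLUP pattern prediction and spatial analysis** (`blup_patterns`,
  `component_acf`, `fit_sq_exp`, `fwhm_from_s`): per-component spatial
  autocorrelation of the predicted patterns, summarized by the SD *s* of
  a squared-exponential kernel and the equivalent smoothing-kernel FWHM
  = 2√(ln 2)·s.
- **Synthetic-data generators** (`scenario_*`, `sample_dataset`,
  `smooth_field`) reproducing the validation studies, and a grid driver
  (`run_scenario_grid`) plus a thin `pcmodel` CLI
  (`simulate` / `fit` / `similarity` / `spatial` / `grid`).

## Worked example

`examples/01_noise_invariant_correlations.py` simulates a 3-stimulus
design (5 trials per stimulus, 100 voxels, component correlations
0, −0.2, 0.8), fits the unconstrained model at four noise levels
(100 replicates each), and prints:

```
noise   corrected rho23   sample rho23   analytic sample rho23
  0.5             0.799          0.724                   0.727
  2.0             0.803          0.559                   0.571
  5.0             0.822          0.404                   0.400
 10.0             0.767          0.274                   0.267
```

The corrected correlation stays at the generating value 0.8 across a
20-fold change in noise variance, while the sample correlation between
condition means falls from 0.72 to 0.27 — exactly tracking its analytic
expectation γ/(σ² + σ_ε²/n). The other example scripts demonstrate the
common-activation correction, the 2 × 4 factorial design, robustness to
uninformative voxels, and the spatial-smoothness estimates.

## Layout

- `src/pcmodel/models.py` — domain types and model builders
- `src/pcmodel/estimation.py` — mean removal, marginal likelihood, EM, BLUP
- `src/pcmodel/similarity.py` — corrected and naive similarity estimators, MDS
- `src/pcmodel/spatial.py` — distance binning, spatial ACF, kernel fits
- `src/pcmodel/simulate.py` — generators and scenario builders
- `src/pcmodel/driver.py`, `io.py`, `cli.py` — grid driver, text I/O, CLI
- `docs/methods.md` — model, estimation details, design choices, limitations
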