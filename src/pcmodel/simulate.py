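"""Synthetic pattern data with the statistical structure the model assumes.

The generator draws hidden pattern components per block from a Gaussian
field over voxels (optionally with squared-exponential spatial
correlation), colours them with the Cholesky factor of the block's
component covariance, mixes them through the design matrix and adds i.i.d.
(or spatially coloured) Gaussian trial noise.  Because the component model
is separable in components and space (``G (x) Sigma``), drawing the
spatial field first and colouring afterwards produces the exact joint
distribution.

The ``scenario_*`` builders package the simulation studies used throughout
the package's validation: a one-factorial design with 3 stimuli, the same
design with a common activation component and a control condition, a 2 x 4
condition-by-level design, a voxel-selection variant where a fraction of
voxels carries no level information, and a spherical-ROI variant with
per-block spatial smoothness.  Their default parameters ARE the study
conditions; tests and the acceptance runs use them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .exceptions import InvalidDesignError
from .models import (
    ComponentModel,
    PatternDataset,
    assemble_G,
    build_common_pattern,
    build_factorial,
    build_one_factorial,
    theta_from_G,
)

__all__ = [
    "SpatialFieldSpec",
    "ScenarioTruth",
    "smooth_field",
    "sample_dataset",
    "sphere_coords",
    "canonical_labels",
    "scenario_one_factorial",
    "scenario_common_activation",
    "scenario_two_factorial",
    "scenario_voxel_selection",
    "scenario_spatial",
    "ONEFACT_NOISE_GRID",
    "TWOFACT_NOISE_GRID",
    "TWOFACT_GAMMA_RATIO_GRID",
    "VOXEL_FRACTION_GRID",
    "SPATIAL_S_GRID",
]

# study-condition grids
ONEFACT_NOISE_GRID = (0.5, 2.0, 5.0, 10.0)
TWOFACT_NOISE_GRID = (0.5, 4.0, 8.0)
TWOFACT_GAMMA_RATIO_GRID = (0.0, 0.45, 0.9)
VOXEL_FRACTION_GRID = (0.0, 0.25, 0.5, 0.75)
SPATIAL_S_GRID = (0.0, 1.0, 2.0)

_ONEFACT_CORR = {"rho12": (0, 1, 0.0), "rho13": (0, 2, -0.2), "rho23": (1, 2, 0.8)}


@dataclass
class SpatialFieldSpec:
    """Per-block spatial autocorrelation SDs for the generator.

    ``s_per_block`` maps block names to the SD of the squared-exponential
    spatial correlation (0 = spatially independent); ``noise_s`` does the
    same for the trial noise field.  ``jitter`` regularizes the Cholesky of
    near-singular spatial covariance matrices.
    """

    s_per_block: Mapping[str, float] = field(default_factory=dict)
    noise_s: float = 0.0
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.noise_s < 0 or any(v < 0 for v in self.s_per_block.values()):
            raise InvalidDesignError("spatial SDs must be >= 0")


@dataclass
class ScenarioTruth:
    """Ground truth of a simulation scenario."""

    model: ComponentModel
    theta_true: np.ndarray
    noise_var_true: float
    target_correlations: dict[str, tuple[int, int, float]]
    spatial: SpatialFieldSpec | None = None
    uninformative_fraction: float = 0.0
    uninformative_block: str = "level"
    coords: np.ndarray | None = None
    name: str = "custom"

    def G(self) -> np.ndarray:
        return assemble_G(self.model, self.theta_true)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def smooth_field(
    coords: np.ndarray,
    s: float,
    n_rows: int,
    seed=0,
    jitter: float = 1e-8,
) -> np.ndarray:
    """Unit-variance Gaussian rows with correlation exp(-delta^2 / 2 s^2).

    ``s = 0`` yields i.i.d. standard-normal entries.
    """
    if s < 0:
        raise InvalidDesignError("s must be >= 0")
    rng = _rng(seed)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    p = coords.shape[0]
    white = rng.standard_normal((n_rows, p))
    if s == 0 or p == 1:
        return white
    d = squareform(pdist(coords))
    cov = np.exp(-(d**2) / (2.0 * s**2)) + jitter * np.eye(p)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise InvalidDesignError("spatial covariance not PSD after jitter") from err
    return white @ L.T


def _psd_factor(G: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(G + 1e-12 * max(np.trace(G), 1.0) / len(G) * np.eye(len(G)))
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(G)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def canonical_labels(model: ComponentModel) -> tuple[np.ndarray, np.ndarray | None]:
    """Condition (and run) labels matching the builders' canonical Z ordering."""
    info = model.meta
    if "builder" not in info:
        raise InvalidDesignError("model has no builder provenance")
    args = info["args"]
    if info["builder"] == "one_factorial":
        k, t = args["n_levels"], args["trials_per_level"]
        return np.repeat([f"s{i + 1}" for i in range(k)], t), None
    if info["builder"] == "common_pattern":
        k, t, ctrl = args["n_levels"], args["trials_per_level"], args["control_trials"]
        cond = ["control"] * ctrl + [f"s{i + 1}" for i in range(k) for _ in range(t)]
        return np.array(cond), None
    if info["builder"] == "factorial":
        c, l, t = args["n_conditions"], args["n_levels"], args["trials_per_cell"]
        runs = args["runs"]
        cells = [f"c{ci + 1}l{li + 1}" for ci in range(c) for li in range(l)]
        if runs is None:
            return np.repeat(cells, t), None
        cond = np.tile(np.repeat(cells, t), len(runs))
        run = np.repeat(runs, len(cells) * t)
        return cond, run
    raise InvalidDesignError(f"unknown builder {info['builder']!r}")


def sample_dataset(
    truth: ScenarioTruth, P: int | None = None, seed=0
) -> tuple[PatternDataset, ScenarioTruth]:
    """Draw one dataset from a scenario's generative model.

    When the truth carries voxel coordinates, P is fixed by them;
    otherwise ``P`` voxels with no spatial structure are generated.  The
    draw is fully reproducible from ``seed``.
    """
    rng = _rng(seed)
    model = truth.model
    q = model.n_components
    if truth.coords is not None:
        coords = np.atleast_2d(truth.coords)
        p = coords.shape[0]
    else:
        if P is None or P < 2:
            raise InvalidDesignError("P >= 2 required when no coordinates are given")
        coords, p = None, int(P)

    G = truth.G()
    # blocks must be independent for block-wise generation
    mask = np.zeros((q, q), dtype=bool)
    for idx in model.blocks.values():
        mask[np.ix_(idx, idx)] = True
    if np.any(np.abs(G[~mask]) > 1e-10 * max(np.abs(G).max(), 1.0)):
        raise InvalidDesignError("G has cross-block covariance; cannot factor by block")

    spatial = truth.spatial or SpatialFieldSpec()
    U = np.zeros((q, p))
    for name, idx in model.blocks.items():
        s = float(spatial.s_per_block.get(name, 0.0))
        if coords is not None and s > 0:
            F = smooth_field(coords, s, len(idx), seed=rng, jitter=spatial.jitter)
        else:
            F = rng.standard_normal((len(idx), p))
        U[idx] = _psd_factor(G[np.ix_(idx, idx)]) @ F

    if not 0.0 <= truth.uninformative_fraction < 1.0:
        raise InvalidDesignError("uninformative_fraction must be in [0, 1)")
    if truth.uninformative_fraction > 0:
        block = truth.uninformative_block
        if block not in model.blocks:
            raise InvalidDesignError(f"no block named {block!r}")
        k = int(round(truth.uninformative_fraction * p))
        dead = rng.choice(p, size=k, replace=False)
        U[np.ix_(model.blocks[block], dead)] = 0.0

    sd = np.sqrt(truth.noise_var_true)
    if coords is not None and spatial.noise_s > 0:
        E = sd * smooth_field(coords, spatial.noise_s, model.Z.shape[0],
                              seed=rng, jitter=spatial.jitter)
    else:
        E = sd * rng.standard_normal((model.Z.shape[0], p))
    Y = model.Z @ U + E
    cond, run = canonical_labels(model)
    data = PatternDataset(Y=Y, condition=cond, run=run, coords=coords)
    return data, truth


def sphere_coords(radius: float) -> np.ndarray:
    """All integer lattice points with Euclidean norm <= radius, origin-centred.

    Radius 3.5 yields 179 voxels on the exhaustive lattice enumeration; ROI
    constructions that trim boundary voxels will give slightly smaller
    counts, so the radius (or an explicit coordinate list) is the
    configurable quantity, not the voxel count.
    """
    if radius <= 0:
        raise InvalidDesignError("radius must be positive")
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()]).astype(float)
    keep = np.einsum("ij,ij->i", pts, pts) <= radius**2 + 1e-12
    return pts[keep]


def scenario_one_factorial(
    noise_var: float = 0.5,
    seed=0,
    n_trials: int = 5,
    P: int = 100,
) -> tuple[PatternDataset, ScenarioTruth]:
    """One factor, 3 stimuli: unit variances, correlations (0, -0.2, 0.8).

    n = 5 trials per condition over P = 100 voxels by default, with the
    noise variance as the swept parameter.
    """
    model = build_one_factorial(3, n_trials)
    G = np.array([[1.0, 0.0, -0.2], [0.0, 1.0, 0.8], [-0.2, 0.8, 1.0]])
    truth = ScenarioTruth(
        model=model,
        theta_true=theta_from_G(model, G),
        noise_var_true=float(noise_var),
        target_correlations=dict(_ONEFACT_CORR),
        name="one_factorial",
    )
    return sample_dataset(truth, P=P, seed=seed)[0], truth


def scenario_common_activation(
    noise_var: float = 0.5,
    seed=0,
    common_var: float = 4.0,
    n_trials: int = 5,
    control_trials: int = 5,
    P: int = 100,
) -> tuple[PatternDataset, ScenarioTruth]:
    """One-factorial scenario plus a shared activation component.

    A common component of variance 4 is added to every trial and measured
    alone in 5 control trials; the fitting model constrains it to be
    uncorrelated with the stimulus components.
    """
    model = build_common_pattern(3, n_trials, control_trials=control_trials)
    G = np.zeros((4, 4))
    G[0, 0] = common_var
    G[1:, 1:] = np.array([[1.0, 0.0, -0.2], [0.0, 1.0, 0.8], [-0.2, 0.8, 1.0]])
    targets = {k: (i + 1, j + 1, v) for k, (i, j, v) in _ONEFACT_CORR.items()}
    truth = ScenarioTruth(
        model=model,
        theta_true=theta_from_G(model, G),
        noise_var_true=float(noise_var),
        target_correlations=targets,
        name="common_activation",
    )
    return sample_dataset(truth, P=P, seed=seed)[0], truth


def _factorial_truth(
    sigma_alpha_sq: float,
    sigma_beta_sq: float,
    gamma_alpha: float,
    gamma_beta: float,
    noise_var: float,
    n_trials: int,
    name: str,
    **kw,
) -> ScenarioTruth:
    model = build_factorial(2, 4, runs=None, trials_per_cell=n_trials)
    q = model.n_components
    G = np.zeros((q, q))
    G[:2, :2] = [[sigma_alpha_sq, gamma_alpha], [gamma_alpha, sigma_alpha_sq]]
    for f in range(4):
        i, j = 2 + f, 6 + f
        G[i, i] = G[j, j] = sigma_beta_sq
        G[i, j] = G[j, i] = gamma_beta
    rho = gamma_beta / sigma_beta_sq
    return ScenarioTruth(
        model=model,
        theta_true=theta_from_G(model, G),
        noise_var_true=float(noise_var),
        target_correlations={
            "rho_alpha": (0, 1, gamma_alpha / sigma_alpha_sq),
            "rho_beta": (2, 6, rho),
        },
        name=name,
        **kw,
    )


def scenario_two_factorial(
    noise_var: float = 0.5,
    gamma_alpha: float = 0.0,
    seed=0,
    n_trials: int = 5,
    P: int = 100,
) -> tuple[PatternDataset, ScenarioTruth]:
    """2 x 4 condition-by-level design.

    Level variances 1 with matched-level covariance 0.5 (true r = 0.5),
    condition variances 2 with covariance ``gamma_alpha``; noise variance
    and gamma_alpha are the swept parameters.  n = 5 trials per cell over
    P = 100 voxels by default.
    """
    truth = _factorial_truth(2.0, 1.0, gamma_alpha, 0.5, noise_var, n_trials,
                             "two_factorial")
    return sample_dataset(truth, P=P, seed=seed)[0], truth


def scenario_voxel_selection(
    fraction: float = 0.0,
    seed=0,
    noise_var: float = 4.0,
    n_trials: int = 5,
    P: int = 100,
) -> tuple[PatternDataset, ScenarioTruth]:
    """Two-factorial design with a fraction of level-uninformative voxels.

    In the given fraction of voxels the level components are zeroed; the
    remaining parameters are sigma_alpha^2 = 2, sigma_beta^2 = 1,
    gamma_alpha = 0, gamma_beta = 0.5, noise variance 4.
    """
    truth = _factorial_truth(2.0, 1.0, 0.0, 0.5, noise_var, n_trials,
                             "voxel_selection",
                             uninformative_fraction=float(fraction))
    return sample_dataset(truth, P=P, seed=seed)[0], truth


def scenario_spatial(
    s_beta: float = 1.0,
    s_eps: float = 1.0,
    seed=0,
    radius: float = 3.5,
    n_trials: int = 5,
) -> tuple[PatternDataset, ScenarioTruth]:
    """Two-factorial design on a lattice sphere with spatial smoothness.

    sigma_eps^2 = 3, sigma_alpha^2 = sigma_beta^2 = 1, gamma_alpha = 0.3,
    gamma_beta = 0.5; the condition components have spatial autocorrelation
    SD 1, the level and noise fields the given SDs.
    """
    truth = _factorial_truth(
        1.0, 1.0, 0.3, 0.5, 3.0, n_trials, "spatial",
        spatial=SpatialFieldSpec({"condition": 1.0, "level": float(s_beta)},
                                 noise_s=float(s_eps)),
        coords=sphere_coords(radius),
    )
    return sample_dataset(truth, seed=seed)[0], truth
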