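"""Domain types and component-model builders.

A component model describes how N observed activity patterns (trials x
voxels) arise as a linear mixture ``Y = Z U + E`` of Q hidden pattern
components, where the columns of U (one per voxel) are drawn from a
multivariate normal with covariance G.  G itself is constrained through a
factor ``A`` with ``G = A A'``, and A is a linear combination of fixed basis
matrices ``A(theta) = sum_h theta_h B_h``.  Choosing the basis catalogue is
how structural hypotheses (a shared activation component, equal variances
across factor levels, matched-level covariances, run effects) are encoded.

The builders in this module produce the standard designs:

* :func:`build_one_factorial` -- one factor with K levels, unconstrained G.
* :func:`build_common_pattern` -- the one-factorial design plus a common
  activation component uncorrelated with the stimulus components.
* :func:`build_factorial` -- a condition x level design with per-condition
  common components, level components with matched-level covariance, and an
  optional per-run component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InvalidDesignError, UnidentifiableModelError

__all__ = [
    "PatternDataset",
    "ComponentModel",
    "ParameterVector",
    "build_one_factorial",
    "build_common_pattern",
    "build_factorial",
    "assemble_G",
    "assemble_A",
    "theta_from_G",
    "design_for_trials",
]


@dataclass
class PatternDataset:
    """A trial-by-voxel matrix of activation estimates with trial metadata.

    Parameters
    ----------
    Y
        (N, P) array of activation estimates (e.g. first-level regression
        coefficients), one row per trial, one column per voxel.
    condition
        Length-N sequence of condition labels.
    run
        Optional length-N sequence of run labels.
    coords
        Optional (P, 3) array of voxel coordinates (mm or voxel units),
        needed only for spatial analyses.
    """

    Y: np.ndarray
    condition: np.ndarray
    run: np.ndarray | None = None
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise InvalidDesignError("Y must be a 2-D trials x voxels matrix")
        n, p = self.Y.shape
        if n < 2 or p < 2:
            raise InvalidDesignError(f"need N >= 2 and P >= 2, got {self.Y.shape}")
        if not np.all(np.isfinite(self.Y)):
            raise InvalidDesignError("Y contains non-finite values")
        self.condition = np.asarray(self.condition)
        if self.condition.shape != (n,):
            raise InvalidDesignError(
                f"condition labels have length {self.condition.shape}, expected {n}"
            )
        if self.run is not None:
            self.run = np.asarray(self.run)
            if self.run.shape != (n,):
                raise InvalidDesignError("run labels must have length N")
        if self.coords is not None:
            self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
            if self.coords.shape[0] != p:
                raise InvalidDesignError(
                    f"coords has {self.coords.shape[0]} rows, expected P = {p}"
                )

    @property
    def n_trials(self) -> int:
        return self.Y.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.Y.shape[1]

    def condition_order(self) -> list:
        """Condition labels in order of first appearance."""
        seen: dict = {}
        for c in self.condition:
            seen.setdefault(c, None)
        return list(seen)


@dataclass
class ComponentModel:
    """Design matrix plus the basis-matrix catalogue defining A(theta).

    Attributes
    ----------
    Z
        (N, Q) design matrix; each row gives the loading of one trial on the
        Q pattern components.
    basis
        (H, Q, Q) array; ``A(theta) = sum_h theta[h] * basis[h]``.
    param_names
        Length-H labels for the entries of theta.
    blocks
        Partition of the Q component indices into named sets; spatial
        kernels and reporting operate per block.
    component_names
        Length-Q labels for the pattern components.
    meta
        Builder provenance (name and arguments) used for serialization and
        for constructing Z for arbitrarily ordered trials.
    """

    Z: np.ndarray
    basis: np.ndarray
    param_names: list[str]
    blocks: dict[str, list[int]]
    component_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        if self.Z.ndim != 2:
            raise InvalidDesignError("Z must be 2-D")
        q = self.Z.shape[1]
        if self.basis.ndim != 3 or self.basis.shape[1:] != (q, q):
            raise InvalidDesignError(
                f"basis must be (H, {q}, {q}), got {self.basis.shape}"
            )
        if self.basis.shape[0] < 1:
            raise InvalidDesignError("need at least one basis matrix")
        if len(self.param_names) != self.basis.shape[0]:
            raise InvalidDesignError("param_names length must equal H")
        if len(self.component_names) != q:
            raise InvalidDesignError("component_names length must equal Q")
        flat = self.basis.reshape(self.basis.shape[0], -1)
        if np.linalg.matrix_rank(flat) < self.basis.shape[0]:
            raise InvalidDesignError("basis matrices are linearly dependent")
        assigned = sorted(i for idx in self.blocks.values() for i in idx)
        if assigned != list(range(q)):
            raise InvalidDesignError(
                "blocks must partition the component indices exactly once"
            )

    @property
    def n_components(self) -> int:
        return self.Z.shape[1]

    @property
    def n_params(self) -> int:
        return self.basis.shape[0]


@dataclass
class ParameterVector:
    """Square-root-scale parameters theta of A plus the noise variance."""

    theta: np.ndarray
    noise_var: float

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        self.noise_var = float(self.noise_var)
        if self.noise_var < 0:
            raise InvalidDesignError("noise_var must be >= 0")


def _elem(q: int, i: int, j: int) -> np.ndarray:
    b = np.zeros((q, q))
    b[i, j] = 1.0
    return b


def _lower_tri_basis(q: int, indices: Sequence[int]) -> tuple[list[np.ndarray], list[str]]:
    """Basis elements for an unconstrained lower-triangular factor block.

    Ordered column-major: (0,0), (1,0), ..., (1,1), (2,1), ... over the given
    component ``indices``.
    """
    mats, names = [], []
    k = len(indices)
    for j in range(k):
        for i in range(j, k):
            mats.append(_elem(q, indices[i], indices[j]))
            names.append(f"a[{indices[i]},{indices[j]}]")
    return mats, names


def build_one_factorial(n_levels: int, trials_per_level: int) -> ComponentModel:
    """One-factorial design with K levels and an unconstrained G.

    Z is the (K * trials_per_level, K) indicator matrix; A is a free lower
    triangular K x K factor, so G = A A' can be any positive-semidefinite
    matrix (H = K(K+1)/2 parameters).
    """
    if n_levels < 2:
        raise InvalidDesignError("need at least 2 levels")
    if trials_per_level < 1:
        raise InvalidDesignError("need at least 1 trial per level")
    k = n_levels
    Z = np.kron(np.eye(k), np.ones((trials_per_level, 1)))
    mats, names = _lower_tri_basis(k, list(range(k)))
    comp = [f"s{i + 1}" for i in range(k)]
    model = ComponentModel(
        Z=Z,
        basis=np.stack(mats),
        param_names=names,
        blocks={"stimulus": list(range(k))},
        component_names=comp,
        meta={
            "builder": "one_factorial",
            "args": {"n_levels": n_levels, "trials_per_level": trials_per_level},
        },
    )
    return model


def build_common_pattern(
    n_levels: int,
    trials_per_level: int,
    control_trials: int = 0,
    anchor_pairs: Sequence[tuple[int, int]] = (),
) -> ComponentModel:
    """One-factorial design plus a common activation component.

    The common component (index 0) loads on every trial; ``control_trials``
    extra trials load on it alone.  The basis constrains the common
    component to be uncorrelated with the K stimulus components, so the
    first row/column of G is zero off the diagonal.

    Without control trials the split between common variance and shared
    stimulus covariance is not identified; at least one ``anchor_pair``
    (1-based stimulus indices) must then be declared uncorrelated.  An
    anchored pair (i, j), i < j, removes the factor element A[j, i]; this
    pins gamma_ij to exactly zero whenever i is the first stimulus (the
    usual anchoring choice) and otherwise removes one degree of freedom
    from the covariance structure.
    """
    if n_levels < 2:
        raise InvalidDesignError("need at least 2 levels")
    if control_trials == 0 and len(anchor_pairs) == 0:
        raise UnidentifiableModelError(
            "a common-pattern model without control trials needs at least one "
            "anchor pair to fix the common/stimulus variance split"
        )
    k = n_levels
    q = k + 1
    n = control_trials + k * trials_per_level
    Z = np.zeros((n, q))
    Z[:, 0] = 1.0  # every trial carries the common component
    for lev in range(k):
        rows = slice(control_trials + lev * trials_per_level,
                     control_trials + (lev + 1) * trials_per_level)
        Z[rows, 1 + lev] = 1.0

    dropped = set()
    for (i, j) in anchor_pairs:
        if not (1 <= i <= k and 1 <= j <= k and i != j):
            raise InvalidDesignError(f"bad anchor pair {(i, j)}")
        lo, hi = sorted((i, j))
        dropped.add((hi, lo))  # component indices == stimulus indices here

    mats = [_elem(q, 0, 0)]
    names = ["a_common"]
    for j in range(1, q):
        for i in range(j, q):
            if (i, j) in dropped:
                continue
            mats.append(_elem(q, i, j))
            names.append(f"a[{i},{j}]")
    comp = ["common"] + [f"s{i + 1}" for i in range(k)]
    return ComponentModel(
        Z=Z,
        basis=np.stack(mats),
        param_names=names,
        blocks={"common": [0], "stimulus": list(range(1, q))},
        component_names=comp,
        meta={
            "builder": "common_pattern",
            "args": {
                "n_levels": n_levels,
                "trials_per_level": trials_per_level,
                "control_trials": control_trials,
                "anchor_pairs": [list(p) for p in anchor_pairs],
            },
        },
    )


def _factorial_layout(n_conditions: int, n_levels: int, run_labels: list | None):
    """Component index layout for the factorial model."""
    c, l = n_conditions, n_levels
    alpha = list(range(c))
    beta = [c + ci * l + li for ci in range(c) for li in range(l)]
    q = c + c * l
    delta: dict = {}
    if run_labels is not None:
        for r, lab in enumerate(run_labels):
            for ci in range(c):
                delta[(ci, lab)] = q
                q += 1
    return alpha, beta, delta, q


def build_factorial(
    n_conditions: int = 2,
    n_levels: int = 4,
    runs: int | Sequence | None = None,
    trials_per_cell: int = 1,
) -> ComponentModel:
    """Condition x level design (e.g. movement/stimulation x fingers).

    Components: per-condition common components u_alpha[c] with free
    variances and covariance gamma_alpha; per-condition, per-level
    components u_beta[c, l] with one variance per condition (shared across
    levels) and a matched-level covariance gamma_beta (zero for
    non-matching levels).  With ``runs`` given, adds one component per run
    and condition with shared variances sigma_delta[c]^2 and a within-run
    cross-condition covariance gamma_delta, uncorrelated across runs.

    Trials are laid out condition-major within each run: for each run (or
    once, without runs), all (condition, level) cells in order, each
    repeated ``trials_per_cell`` times.
    """
    if n_conditions < 2:
        raise InvalidDesignError("need at least 2 conditions")
    if n_levels < 2:
        raise InvalidDesignError("need at least 2 levels")
    if runs is None:
        run_labels = None
    elif isinstance(runs, (int, np.integer)):
        if runs < 1:
            raise InvalidDesignError("runs must be positive")
        run_labels = [f"r{i + 1}" for i in range(int(runs))]
    else:
        run_labels = list(runs)
        if len(run_labels) == 0 or len(set(run_labels)) != len(run_labels):
            raise InvalidDesignError("run labels must be non-empty and unique")

    c, l = n_conditions, n_levels
    alpha, beta, delta, q = _factorial_layout(c, l, run_labels)

    rows = []
    for lab in (run_labels if run_labels is not None else [None]):
        for ci in range(c):
            for li in range(l):
                z = np.zeros(q)
                z[alpha[ci]] = 1.0
                z[beta[ci * l + li]] = 1.0
                if lab is not None:
                    z[delta[(ci, lab)]] = 1.0
                rows.extend([z] * trials_per_cell)
    Z = np.array(rows)

    mats: list[np.ndarray] = []
    names: list[str] = []
    # alpha block: free lower-triangular C x C factor
    for j in range(c):
        for i in range(j, c):
            mats.append(_elem(q, alpha[i], alpha[j]))
            names.append(f"alpha[{i + 1},{j + 1}]")
    # beta block: one C x C lower-triangular factor replicated over levels
    for j in range(c):
        for i in range(j, c):
            b = np.zeros((q, q))
            for li in range(l):
                b[beta[i * l + li], beta[j * l + li]] = 1.0
            mats.append(b)
            names.append(f"beta[{i + 1},{j + 1}]")
    # delta block: one C x C factor replicated over runs
    if run_labels is not None:
        for j in range(c):
            for i in range(j, c):
                b = np.zeros((q, q))
                for lab in run_labels:
                    b[delta[(i, lab)], delta[(j, lab)]] = 1.0
                mats.append(b)
                names.append(f"delta[{i + 1},{j + 1}]")

    comp = [f"alpha[{ci + 1}]" for ci in range(c)]
    comp += [f"beta[{ci + 1},{li + 1}]" for ci in range(c) for li in range(l)]
    blocks = {"condition": alpha, "level": beta}
    if run_labels is not None:
        comp += [f"delta[{ci + 1},{lab}]" for (ci, lab) in delta]
        blocks["run"] = list(delta.values())
    return ComponentModel(
        Z=Z,
        basis=np.stack(mats),
        param_names=names,
        blocks=blocks,
        component_names=comp,
        meta={
            "builder": "factorial",
            "args": {
                "n_conditions": n_conditions,
                "n_levels": n_levels,
                "runs": run_labels,
                "trials_per_cell": trials_per_cell,
            },
        },
    )


def assemble_A(model: ComponentModel, params: ParameterVector | np.ndarray) -> np.ndarray:
    """A(theta) = sum_h theta_h B_h."""
    theta = params.theta if isinstance(params, ParameterVector) else np.asarray(params, float)
    if theta.shape != (model.n_params,):
        raise InvalidDesignError(
            f"theta has shape {theta.shape}, expected ({model.n_params},)"
        )
    return np.tensordot(theta, model.basis, axes=(0, 0))


def assemble_G(model: ComponentModel, params: ParameterVector | np.ndarray) -> np.ndarray:
    """G = A A' -- symmetric positive-semidefinite by construction."""
    a = assemble_A(model, params)
    return a @ a.T


def theta_from_G(model: ComponentModel, G: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    """Invert assemble_G for a G that conforms to the model's structure.

    Computes a lower-triangular-style factor of G and projects it onto the
    basis span by least squares.  Raises if the projection residual is
    large, i.e. G is not representable by this basis catalogue.
    """
    G = np.asarray(G, dtype=float)
    q = model.n_components
    if G.shape != (q, q):
        raise InvalidDesignError(f"G must be ({q}, {q})")
    try:
        L = np.linalg.cholesky(G + 1e-12 * np.trace(G) / q * np.eye(q))
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh((G + G.T) / 2)
        L = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    bmat = model.basis.reshape(model.n_params, -1).T  # (Q^2, H)
    theta, *_ = np.linalg.lstsq(bmat, L.ravel(), rcond=None)
    resid = np.abs(assemble_G(model, theta) - G).max()
    scale = max(np.abs(G).max(), 1.0)
    if resid > max(rtol * scale, 1e-6):
        raise InvalidDesignError(
            f"G is not representable by this model's basis (residual {resid:.3g})"
        )
    return theta


def design_for_trials(
    model: ComponentModel,
    condition: Sequence,
    run: Sequence | None = None,
) -> np.ndarray:
    """Build a design matrix for trials in arbitrary order.

    Uses the builder provenance in ``model.meta`` to map each trial's
    condition (and run) label onto a row of Z.  Canonical labels are
    ``s1..sK`` and ``control`` for the one-factorial builders and
    ``c{c}l{l}`` for the factorial builder.
    """
    info = model.meta
    if "builder" not in info:
        raise InvalidDesignError("model has no builder provenance; supply Z directly")
    name = info["builder"]
    args = info["args"]
    q = model.n_components
    rows = []
    if name in ("one_factorial", "common_pattern"):
        offset = 1 if name == "common_pattern" else 0
        k = args["n_levels"]
        for lab in condition:
            z = np.zeros(q)
            if name == "common_pattern":
                z[0] = 1.0
            if str(lab) == "control":
                if name != "common_pattern":
                    raise InvalidDesignError("'control' label needs a common-pattern model")
            else:
                idx = int(str(lab).lstrip("s")) - 1
                if not 0 <= idx < k:
                    raise InvalidDesignError(f"unknown condition label {lab!r}")
                z[offset + idx] = 1.0
            rows.append(z)
    elif name == "factorial":
        c, l = args["n_conditions"], args["n_levels"]
        run_labels = args["runs"]
        alpha, beta, delta, _ = _factorial_layout(c, l, run_labels)
        if run_labels is not None and run is None:
            raise InvalidDesignError("this model requires per-trial run labels")
        for t, lab in enumerate(condition):
            s = str(lab)
            try:
                ci, li = s.split("l")
                ci, li = int(ci.lstrip("c")) - 1, int(li) - 1
            except ValueError as err:
                raise InvalidDesignError(f"cannot parse condition label {lab!r}") from err
            if not (0 <= ci < c and 0 <= li < l):
                raise InvalidDesignError(f"condition label {lab!r} out of range")
            z = np.zeros(q)
            z[alpha[ci]] = 1.0
            z[beta[ci * l + li]] = 1.0
            if run_labels is not None:
                key = (ci, run[t])
                if key not in delta:
                    raise InvalidDesignError(f"unknown run label {run[t]!r}")
                z[delta[key]] = 1.0
            rows.append(z)
    else:  # pragma: no cover - future builders
        raise InvalidDesignError(f"unknown builder {name!r}")
    return np.array(rows)
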