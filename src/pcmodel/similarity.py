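"""Corrected correlations, naive sample-correlation estimators, and MDS.

The corrected correlation ``rho_ij = gamma_ij / (sigma_i sigma_j)`` computed
from an estimated component covariance G is the model's noise-, common-
activation- and voxel-selection-invariant similarity measure.  The naive
estimators implemented here (sample correlations between condition means,
control-pattern subtraction, condition-mean subtraction) are the
comparison baselines; each carries a documented bias:

* plain sample correlations shrink toward zero as the trial noise grows
  (expected value ``gamma / sqrt((s_i^2 + noise/n)(s_j^2 + noise/n))``);
* subtracting a fixed-effects estimate of a control pattern leaks the
  control condition's measurement noise into every residual and biases
  low correlations upward, increasingly so with noise;
* subtracting each condition's mean pattern induces a negative bias that
  grows with noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidDesignError
from .models import PatternDataset

__all__ = [
    "SimilarityResult",
    "corrected_correlations",
    "sample_corr_mean_patterns",
    "control_subtracted_corr",
    "condition_mean_subtracted_corr",
    "expected_sample_corr",
    "expected_cross_condition_corr",
    "mds_embed",
]


@dataclass
class SimilarityResult:
    """Component variances, covariances, and corrected correlations.

    Entries of ``corrected`` are NaN where a component variance fell below
    the stability floor (``unstable`` marks those components): correlations
    normalized by a near-zero variance have exploding sampling variance, so
    they are reported as undefined rather than clipped.
    """

    variances: np.ndarray
    covariances: np.ndarray
    corrected: np.ndarray
    unstable: np.ndarray
    component_names: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        names = self.component_names or [f"u{i+1}" for i in range(len(self.variances))]
        return pd.DataFrame(self.corrected, index=names, columns=names)


def corrected_correlations(
    G: np.ndarray,
    floor: float = 1e-6,
    component_names: list[str] | None = None,
) -> SimilarityResult:
    """Corrected correlations rho_ij = gamma_ij / (sigma_i sigma_j) from G.

    ``floor`` is a relative variance threshold: components whose variance is
    below ``floor * mean(diag(G))`` are flagged unstable and their
    correlations returned as NaN.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise InvalidDesignError("G must be square")
    if not np.allclose(G, G.T, atol=1e-8 * max(np.abs(G).max(), 1.0)):
        raise InvalidDesignError("G must be symmetric")
    var = np.diag(G).copy()
    unstable = var < floor * max(var.mean(), 0.0)
    sd = np.sqrt(np.where(unstable, np.nan, var))
    corr = G / np.outer(sd, sd)
    np.fill_diagonal(corr, np.where(unstable, np.nan, 1.0))
    return SimilarityResult(
        variances=var,
        covariances=G - np.diag(var),
        corrected=corr,
        unstable=unstable,
        component_names=component_names,
    )


def _condition_means(data: PatternDataset) -> tuple[list, np.ndarray]:
    order = data.condition_order()
    means = np.stack([data.Y[data.condition == c].mean(axis=0) for c in order])
    return order, means


def _pearson_rows(M: np.ndarray) -> np.ndarray:
    """Pearson correlation over voxels between rows; NaN for zero-variance rows."""
    Mc = M - M.mean(axis=1, keepdims=True)
    ss = np.sqrt(np.sum(Mc * Mc, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.outer(ss, ss)
        corr = (Mc @ Mc.T) / denom
    corr[:, ss == 0] = np.nan
    corr[ss == 0, :] = np.nan
    return corr


def sample_corr_mean_patterns(data: PatternDataset) -> pd.DataFrame:
    """Pearson correlations over voxels between per-condition mean patterns."""
    order, means = _condition_means(data)
    return pd.DataFrame(_pearson_rows(means), index=order, columns=order)


def control_subtracted_corr(data: PatternDataset, control_label="control") -> pd.DataFrame:
    """Correlations between condition means after subtracting a control mean.

    Implements the fixed-effects correction for a common activation: the
    control condition's mean pattern is subtracted from every other
    condition's mean before correlating.  The control mean contains
    measurement noise, which is then shared across all residuals -- the
    resulting estimates of low correlations are biased upward, and the bias
    grows with the noise level.
    """
    if control_label not in set(data.condition.tolist()):
        raise InvalidDesignError(f"control condition {control_label!r} not present")
    order, means = _condition_means(data)
    ctrl = means[order.index(control_label)]
    keep = [i for i, c in enumerate(order) if c != control_label]
    resid = means[keep] - ctrl
    labels = [order[i] for i in keep]
    return pd.DataFrame(_pearson_rows(resid), index=labels, columns=labels)


def condition_mean_subtracted_corr(
    data: PatternDataset,
    factors: np.ndarray | None = None,
    sep: str = "l",
) -> pd.DataFrame:
    """Correlations after removing each condition's mean pattern.

    For a condition x level design, the mean pattern over all trials of a
    condition is subtracted from that condition's level means before
    correlating.  ``factors`` may give an explicit (N, 2) array of
    (condition, level) labels; by default the trial labels are parsed as
    ``"<condition><sep><level>"`` (the factorial builders' ``c{c}l{l}``
    scheme).  The subtracted mean contains shared noise, inducing a
    negative bias that grows with the noise level.
    """
    if factors is None:
        parts = [str(c).split(sep, 1) for c in data.condition]
        if any(len(p) != 2 for p in parts):
            raise InvalidDesignError(
                f"cannot split condition labels on {sep!r}; pass factors explicitly"
            )
        factors = np.array(parts)
    else:
        factors = np.asarray(factors)
    conds = factors[:, 0]
    order, means = _condition_means(data)
    resid = []
    for i, lab in enumerate(order):
        row = np.flatnonzero(data.condition == lab)[0]
        cmean = data.Y[conds == conds[row]].mean(axis=0)
        resid.append(means[i] - cmean)
    return pd.DataFrame(_pearson_rows(np.stack(resid)), index=order, columns=order)


def expected_sample_corr(
    gamma: float, sigma_i: float, sigma_j: float, noise_var: float, n: int
) -> float:
    """Expected sample correlation between condition-mean patterns.

    ``gamma / sqrt((sigma_i^2 + noise/n)(sigma_j^2 + noise/n))``; for equal
    variances this reduces to the familiar ``gamma / (sigma^2 + noise/n)``
    attenuation with n trials per condition.
    """
    if n < 1:
        raise InvalidDesignError("n must be >= 1")
    if sigma_i <= 0 or sigma_j <= 0:
        raise InvalidDesignError("component SDs must be positive")
    e = noise_var / n
    return float(gamma / np.sqrt((sigma_i**2 + e) * (sigma_j**2 + e)))


def expected_cross_condition_corr(
    gamma_alpha: float,
    gamma_beta: float,
    sigma_alpha_sq: float | tuple[float, float],
    sigma_beta_sq: float | tuple[float, float],
    noise_var: float,
    n: int,
    matched: bool = True,
) -> float:
    """Expected cross-condition sample correlation in the factorial design.

    For matched levels the numerator is gamma_alpha + gamma_beta; for
    non-matching levels only gamma_alpha remains.  The denominator carries
    both component variances plus the noise attenuation per condition.
    """
    sa = np.broadcast_to(np.asarray(sigma_alpha_sq, float), (2,)).copy() \
        if np.ndim(sigma_alpha_sq) else np.array([sigma_alpha_sq] * 2, float)
    sb = np.broadcast_to(np.asarray(sigma_beta_sq, float), (2,)).copy() \
        if np.ndim(sigma_beta_sq) else np.array([sigma_beta_sq] * 2, float)
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise InvalidDesignError("variances must be positive")
    e = noise_var / n
    num = gamma_alpha + (gamma_beta if matched else 0.0)
    den = np.sqrt((sa[0] + sb[0] + e) * (sa[1] + sb[1] + e))
    return float(num / den)


def mds_embed(corr: np.ndarray, n_dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling of a similarity matrix.

    Uses d = 1 - rho as the distance, double-centres -d^2/2, and
    eigendecomposes.  Returns ``(coords, eigenvalues)`` with eigenvalues in
    descending order (the full spectrum, for dimensionality assessment).
    Reflection indeterminacy is resolved by making the first stimulus's
    coordinate nonnegative on every dimension.
    """
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    if corr.ndim != 2 or corr.shape != (k, k) or not np.allclose(corr, corr.T, atol=1e-8):
        raise InvalidDesignError("corr must be a symmetric square matrix")
    if n_dims < 1 or n_dims > k:
        raise InvalidDesignError("n_dims out of range")
    d = 1.0 - corr
    j = np.eye(k) - np.ones((k, k)) / k
    b = -0.5 * j @ (d * d) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1]
    w, v = w[idx], v[:, idx]
    coords = v[:, :n_dims] * np.sqrt(np.clip(w[:n_dims], 0.0, None))
    for dim in range(coords.shape[1]):
        if coords[0, dim] < 0:
            coords[:, dim] = -coords[:, dim]
    return coords, w
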