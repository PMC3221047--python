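"""Spatial smoothness of pattern components: binned autocorrelation and
squared-exponential kernel fits.

Full joint estimation of component and spatial covariance (the Kronecker
model ``G (x) Sigma``) scales poorly, so this module implements the
approximate two-step procedure: fit the component model ignoring spatial
structure, predict the hidden patterns by BLUP, then estimate per-block
spatial autocorrelation functions from the predicted rows and summarize
each with the SD ``s`` of a squared-exponential correlation kernel
``corr(delta) = exp(-delta^2 / (2 s^2))``.  The smoothness is also
expressed as the FWHM ``2 sqrt(ln 2) s`` of the Gaussian smoothing kernel
(SD ``s / sqrt(2)``) that would induce the same autocorrelation on white
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist

from .exceptions import InvalidDesignError

__all__ = [
    "SpatialEstimate",
    "pairwise_distance_bins",
    "component_acf",
    "fit_sq_exp",
    "fwhm_from_s",
    "default_lattice_edges",
    "spatial_estimates",
]

_FWHM_PER_S = 2.0 * np.sqrt(np.log(2.0))


@dataclass
class SpatialEstimate:
    """Binned spatial autocorrelation and fitted kernel width for one block."""

    bin_edges: np.ndarray
    acf: np.ndarray
    pair_counts: np.ndarray
    s: float | None = None
    fwhm: float | None = None
    rss: float | None = None
    at_bound: bool = False
    block: str | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def default_lattice_edges(max_dist: float) -> np.ndarray:
    """Distance bins adapted to a unit lattice.

    First bins isolate face neighbours (distance 1) and diagonal
    neighbours (sqrt 2, sqrt 3); beyond that, equal-width bins up to
    ``max_dist``.
    """
    if max_dist <= 2.1:
        raise InvalidDesignError("max_dist too small for lattice bins")
    edges = [0.5, 1.2, 1.8, 2.1]
    e = 2.1
    while e < max_dist:
        e += 0.7
        edges.append(round(e, 3))
    return np.array(edges)


def pairwise_distance_bins(
    coords: np.ndarray, edges: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Assign unordered voxel pairs to half-open distance bins [lo, hi).

    Returns ``(pairs, counts)``: for each bin a (k, 2) integer array of
    voxel index pairs, and the per-bin pair counts.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    p = coords.shape[0]
    if p < 2:
        raise InvalidDesignError("need at least 2 voxels")
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0) or edges[0] <= 0:
        raise InvalidDesignError("edges must be strictly increasing and start > 0")
    d = pdist(coords)
    iu = np.triu_indices(p, k=1)
    which = np.searchsorted(edges, d, side="right") - 1
    which[(d < edges[0]) | (d >= edges[-1])] = -1
    pairs = []
    counts = np.zeros(len(edges) - 1, dtype=int)
    for b in range(len(edges) - 1):
        sel = which == b
        pairs.append(np.column_stack([iu[0][sel], iu[1][sel]]))
        counts[b] = int(sel.sum())
    return pairs, counts


def component_acf(
    rows: np.ndarray,
    coords: np.ndarray,
    edges: np.ndarray,
    block: str | None = None,
) -> SpatialEstimate:
    """Binned spatial autocorrelation of a block of pattern rows.

    Rows are mean-centred over voxels; within each distance bin the
    product-moment correlation between u(x) and u(x + delta) is pooled over
    all voxel pairs in the bin and all rows of the block, weighting every
    pair equally.  Empty bins yield NaN (excluded from kernel fitting).
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[0] < 1:
        raise InvalidDesignError("block must contain at least one row")
    pairs, counts = pairwise_distance_bins(coords, edges)
    u = rows - rows.mean(axis=1, keepdims=True)
    acf = np.full(len(pairs), np.nan)
    for b, pr in enumerate(pairs):
        if len(pr) == 0:
            continue
        x = u[:, pr[:, 0]].ravel()
        y = u[:, pr[:, 1]].ravel()
        # symmetric product-moment correlation over the pooled pair sample
        sxy = float(x @ y)
        sxx = float(x @ x)
        syy = float(y @ y)
        if sxx <= 0 or syy <= 0:
            continue
        acf[b] = sxy / np.sqrt(sxx * syy)
    return SpatialEstimate(
        bin_edges=np.asarray(edges, dtype=float),
        acf=acf,
        pair_counts=counts,
        block=block,
    )


def _sq_exp(delta: np.ndarray, s: float) -> np.ndarray:
    if s <= 0:
        return np.where(delta > 0, 0.0, 1.0)
    return np.exp(-(delta**2) / (2.0 * s**2))


def fit_sq_exp(
    acf: np.ndarray,
    bin_centers: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, float, bool]:
    """Weighted least-squares fit of exp(-delta^2 / 2 s^2) to binned ACF values.

    NaN ACF entries (empty bins) are ignored.  Returns ``(s, rss,
    at_bound)``; ``at_bound`` flags solutions pinned to the search bounds
    (all-positive flat ACFs push s to the maximum distance; all-negative
    ACFs give s = 0).
    """
    acf = np.asarray(acf, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    w = np.ones_like(acf) if weights is None else np.asarray(weights, dtype=float)
    ok = np.isfinite(acf) & (w > 0)
    if ok.sum() < 2:
        raise InvalidDesignError("need at least 2 usable bins")
    a, d, w = acf[ok], bin_centers[ok], w[ok]
    upper = float(d.max())

    def rss(s: float) -> float:
        r = a - _sq_exp(d, s)
        return float(np.sum(w * r * r))

    if np.all(a <= 0):
        return 0.0, rss(0.0), True
    # coarse grid then local refinement keeps the fit deterministic
    grid = np.linspace(0.0, upper, 81)
    vals = np.array([rss(s) for s in grid])
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(rss, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    s = float(res.x)
    if rss(grid[i]) < res.fun:
        s = float(grid[i])
    at_bound = s <= 1e-6 or s >= upper - 1e-6
    return s, rss(s), at_bound


def fwhm_from_s(s: float) -> float:
    """FWHM (2 sqrt(ln 2) s) of the smoothing kernel matching autocorrelation SD s."""
    if s < 0:
        raise InvalidDesignError("s must be >= 0")
    return _FWHM_PER_S * float(s)


def spatial_estimates(
    U_hat: np.ndarray,
    residuals: np.ndarray,
    blocks: dict[str, list[int]],
    coords: np.ndarray,
    edges: np.ndarray | None = None,
) -> dict[str, SpatialEstimate]:
    """Two-step spatial summary for every component block plus the noise.

    ``U_hat`` are BLUP pattern rows, ``residuals`` the rows of
    ``Y - Z U_hat``.  Each block's rows are pooled into one binned ACF and
    one kernel fit; the noise ACF is computed identically from the
    residual rows under the key ``"noise"``.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if edges is None:
        edges = default_lattice_edges(float(pdist(coords).max()))
    out: dict[str, SpatialEstimate] = {}
    groups = dict(blocks)
    for name, rows in list(groups.items()) + [("noise", None)]:
        mat = residuals if rows is None else U_hat[list(rows)]
        est = component_acf(mat, coords, edges, block=name)
        s, rss, at_bound = fit_sq_exp(est.acf, est.bin_centers, est.pair_counts)
        est.s, est.rss, est.at_bound = s, rss, at_bound
        est.fwhm = fwhm_from_s(s)
        out[name] = est
    return out
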