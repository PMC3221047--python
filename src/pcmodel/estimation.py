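"""Maximum-likelihood estimation of the component covariance G by EM.

Columns of the mean-removed data are modelled as i.i.d. draws
``y_p ~ N(0, V)`` with ``V = Z G Z' + I sigma_eps^2`` and ``G = A A'``,
``A = sum_h theta_h B_h``.  Estimation reparameterizes each voxel column as
``y_p = Z A w_p + eps_p`` with standard-normal latent weights ``w_p``; the
E-step computes the posterior moments of W and the M-step solves an H x H
linear system for theta (the expected complete-data objective is exactly
quadratic in theta because A is linear in theta), followed by the
closed-form noise-variance update.  This is an exact EM, so the marginal
log-likelihood is non-decreasing across iterations.

All heavy quantities are reduced to Q-dimensional sufficient statistics
(Z'Z, Z'YY'Z, tr(YY')), making the per-iteration cost independent of the
number of voxels and trials.  The private batched core operates on a stack
of replicate datasets sharing one design; :func:`em_fit` is the
single-dataset entry point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import NumericalFailureError, SingularCovarianceError
from .models import ComponentModel, ParameterVector, PatternDataset, assemble_A, assemble_G

__all__ = [
    "FittedModel",
    "remove_mean",
    "marginal_loglik",
    "em_fit",
    "em_fit_replicates",
    "blup_patterns",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FittedModel:
    """Result of an EM fit."""

    params: ParameterVector
    G: np.ndarray
    mean_coef: np.ndarray
    loglik_trace: np.ndarray
    U_hat: np.ndarray | None
    n_iter: int
    converged: bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def remove_mean(
    data: PatternDataset | np.ndarray, model: ComponentModel
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate per-component mean activations and subtract them.

    The component means a satisfy ``a = Z^+ ybar`` where ybar is the
    voxel-averaged pattern per trial; the centred data are
    ``Y - (Z a) 1'``.  Because each component has its own mean, a does not
    depend on G and can be removed up front.

    Returns ``(a, Y_centred)``.
    """
    Y = data.Y if isinstance(data, PatternDataset) else np.asarray(data, float)
    ybar = Y.mean(axis=1)
    a = np.linalg.pinv(model.Z) @ ybar
    return a, Y - (model.Z @ a)[:, None]


def _woodbury_stats(K, Syy, trYY, A, sig2, n, p):
    """Marginal log-likelihood from Q-dimensional statistics (batched).

    K = Z'Z, Syy = Z'YY'Z, trYY = tr(YY'); A, sig2 may carry a leading
    replicate axis.
    """
    q = K.shape[-1]
    AtKA = np.swapaxes(A, -1, -2) @ K @ A
    M = np.eye(q) + AtKA / sig2[..., None, None]
    sign, logdetM = np.linalg.slogdet(M)
    if np.any(sign <= 0):
        raise SingularCovarianceError("capacitance matrix not positive definite")
    AtSA = np.swapaxes(A, -1, -2) @ Syy @ A
    Minv_AtSA = np.linalg.solve(M, AtSA)
    tr_inner = np.trace(Minv_AtSA, axis1=-2, axis2=-1)
    quad = (trYY - tr_inner / sig2) / sig2
    logdetV = n * np.log(sig2) + logdetM
    return -0.5 * (n * p * _LOG2PI + p * logdetV + quad)


def marginal_loglik(
    Y_centred: np.ndarray,
    model: ComponentModel,
    params: ParameterVector,
    method: str = "auto",
) -> float:
    """Marginal log-likelihood of mean-removed data under (theta, sigma_eps^2).

    ``method='dense'`` forms V = Z G Z' + I sigma^2 explicitly (O(N^3));
    ``method='woodbury'`` works in the Q-dimensional space.  Both agree to
    high relative precision and 'auto' picks woodbury when sigma^2 > 0.
    """
    Y = np.asarray(Y_centred, float)
    n, p = Y.shape
    sig2 = params.noise_var
    if method not in ("auto", "dense", "woodbury"):
        raise ValueError(f"unknown method {method!r}")
    if method == "woodbury" and sig2 <= 0:
        raise SingularCovarianceError("woodbury path requires sigma_eps^2 > 0")
    if method == "dense" or (method == "auto" and sig2 <= 0):
        G = assemble_G(model, params)
        V = model.Z @ G @ model.Z.T + sig2 * np.eye(n)
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            raise SingularCovarianceError("V = Z G Z' + I sigma^2 is singular")
        quad = float(np.sum(Y * np.linalg.solve(V, Y)))
        return -0.5 * (n * p * _LOG2PI + p * logdet + quad)
    A = assemble_A(model, params)
    K = model.Z.T @ model.Z
    SZ = model.Z.T @ Y
    Syy = SZ @ SZ.T
    trYY = float(np.sum(Y * Y))
    return float(
        _woodbury_stats(K, Syy, np.asarray(trYY), A, np.asarray(sig2, float), n, p)
    )


def _moment_init(Z, Ys, basis, rng=None, perturb=0.0):
    """Method-of-moments initialisation (batched over replicates).

    G0 = (Z^+ Y)(Z^+ Y)'/P - sigma0^2 (Z'Z)^+ from the OLS component
    estimates, projected onto the PSD cone and then onto the basis span.
    """
    r, n, p = Ys.shape
    q = Z.shape[1]
    h = basis.shape[0]
    Zp = np.linalg.pinv(Z)
    rank = np.linalg.matrix_rank(Z)
    Uh = np.einsum("qn,rnp->rqp", Zp, Ys)
    resid = Ys - np.einsum("nq,rqp->rnp", Z, Uh)
    dof = max(n - rank, 1) * p
    sig0 = np.maximum(np.einsum("rnp,rnp->r", resid, resid) / dof, 1e-8)
    if n == rank:  # saturated design: no residual degrees of freedom
        sig0 = 0.5 * Ys.var(axis=(1, 2))
    G0 = np.einsum("rqp,rsp->rqs", Uh, Uh) / p
    G0 = G0 - sig0[:, None, None] * np.linalg.pinv(Z.T @ Z)
    G0 = (G0 + np.swapaxes(G0, 1, 2)) / 2
    w, v = np.linalg.eigh(G0)
    # keep the start away from theta = 0, which is a stationary point of EM
    w = np.maximum(w, np.maximum(0.05 * sig0, 1e-8)[:, None])
    L = np.linalg.cholesky(np.einsum("rik,rk,rjk->rij", v, w, v))
    bpinv = np.linalg.pinv(basis.reshape(h, -1).T)  # (H, Q^2)
    theta0 = np.einsum("hk,rk->rh", bpinv, L.reshape(r, q * q))
    if perturb > 0.0 and rng is not None:
        theta0 = theta0 * (1.0 + perturb * rng.standard_normal(theta0.shape))
    return theta0, sig0


def _em_core(
    Ys: np.ndarray,
    Z: np.ndarray,
    basis: np.ndarray,
    theta0: np.ndarray,
    sig0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    track_trace: bool = False,
):
    """Run EM on a stack of centred datasets sharing one design.

    Parameters are batched along the leading replicate axis.  Returns
    ``(theta, sig2, loglik, n_iter, converged, traces)`` where traces is a
    list of per-replicate log-likelihood arrays when requested.
    """
    r, n, p = Ys.shape
    h, q, _ = basis.shape
    K = Z.T @ Z
    SZ = np.einsum("nq,rnp->rqp", Z, Ys)
    Syy = np.einsum("rqp,rsp->rqs", SZ, SZ)
    trYY = np.einsum("rnp,rnp->r", Ys, Ys)
    KB = np.einsum("ij,hjk->hik", K, basis)  # fixed H x Q x Q stack
    floor = np.maximum(1e-12 * trYY / (n * p), 1e-30)

    theta = theta0.copy()
    sig2 = np.maximum(sig0.astype(float).copy(), floor)
    eye_q = np.eye(q)
    ll_prev = np.full(r, -np.inf)
    traces: list[list[float]] = [[] for _ in range(r)] if track_trace else []
    converged = np.zeros(r, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        A = np.einsum("rh,hij->rij", theta, basis)
        ll = _woodbury_stats(K, Syy, trYY, A, sig2, n, p)
        if not np.all(np.isfinite(ll)):
            bad = int(np.argmin(np.isfinite(ll)))
            raise NumericalFailureError(
                f"non-finite log-likelihood in replicate {bad}", iteration=it
            )
        if track_trace:
            for i in range(r):
                traces[i].append(float(ll[i]))
        converged = np.abs(ll - ll_prev) <= tol * (np.abs(ll) + 1.0)
        if np.all(converged):
            ll_prev = ll
            break
        ll_prev = ll

        # E-step posterior moments of the latent weights W (Q x P per voxel)
        At = np.swapaxes(A, 1, 2)
        M = eye_q + At @ K @ A / sig2[:, None, None]
        Sw = np.linalg.inv(M)  # posterior covariance * sigma^0 scale
        ASw = A @ Sw
        # S1 = Z'Y What' = Syy A Sw / sig2 ;  S2 = What What' + P Sw
        S1 = Syy @ ASw / sig2[:, None, None]
        SwA_Syy_ASw = np.swapaxes(ASw, 1, 2) @ Syy @ ASw
        S2 = SwA_Syy_ASw / (sig2**2)[:, None, None] + p * Sw
        S2 = (S2 + np.swapaxes(S2, 1, 2)) / 2

        # M-step: quadratic in theta -> H x H linear solve
        C = np.einsum("hij,rjk->rhik", KB, S2)
        Mh = np.einsum("gij,rhij->rgh", basis, C)
        ch = np.einsum("hij,rij->rh", basis, S1)
        Mh = Mh + 1e-12 * (
            np.trace(Mh, axis1=1, axis2=2)[:, None, None] / h + 1e-300
        ) * np.eye(h)
        try:
            theta = np.linalg.solve(Mh, ch[..., None])[..., 0]
        except np.linalg.LinAlgError:
            theta = np.einsum("rhg,rg->rh", np.linalg.pinv(Mh), ch)

        A = np.einsum("rh,hij->rij", theta, basis)
        cross = np.einsum("rij,rij->r", A, S1)
        AtKA = np.swapaxes(A, 1, 2) @ K @ A
        quad = np.einsum("rij,rij->r", AtKA, S2)
        sig2 = np.maximum((trYY - 2 * cross + quad) / (n * p), floor)

    if not np.all(converged):
        # hit max_iter after an update: report the likelihood of the final params
        A = np.einsum("rh,hij->rij", theta, basis)
        ll_prev = _woodbury_stats(K, Syy, trYY, A, sig2, n, p)
        if track_trace:
            for i in range(r):
                traces[i].append(float(ll_prev[i]))
    return theta, sig2, ll_prev, it, converged, traces


def em_fit(
    data: PatternDataset | np.ndarray,
    model: ComponentModel,
    init: tuple[np.ndarray, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = 0,
    n_restarts: int = 0,
    compute_blup: bool = True,
) -> FittedModel:
    """Fit theta and sigma_eps^2 by maximum likelihood via EM.

    Parameters
    ----------
    data
        Dataset (or raw Y matrix); the mean is removed internally.
    init
        Optional explicit ``(theta0, noise_var0)``; by default a
        method-of-moments start is used.
    n_restarts
        Additional EM runs from multiplicatively perturbed starts (seeded);
        the run with the highest final log-likelihood wins.
    """
    a, Yc = remove_mean(data, model)
    Ys = Yc[None]
    rng = np.random.default_rng(seed)
    if init is not None:
        theta0 = np.asarray(init[0], float)[None]
        sig0 = np.array([float(init[1])])
    else:
        theta0, sig0 = _moment_init(model.Z, Ys, model.basis)

    best = None
    for restart in range(n_restarts + 1):
        t0, s0 = theta0, sig0
        if restart > 0:
            t0, s0 = _moment_init(model.Z, Ys, model.basis, rng=rng, perturb=0.3)
        theta, sig2, ll, n_iter, conv, traces = _em_core(
            Ys, model.Z, model.basis, t0, s0,
            tol=tol, max_iter=max_iter, track_trace=True,
        )
        cand = (float(ll[0]), theta[0], float(sig2[0]),
                np.array(traces[0]), n_iter, bool(conv[0]))
        if best is None or cand[0] > best[0]:
            best = cand

    _, theta, sig2, trace, n_iter, conv = best
    params = ParameterVector(theta=theta, noise_var=sig2)
    G = assemble_G(model, params)
    fitted = FittedModel(
        params=params,
        G=G,
        mean_coef=a,
        loglik_trace=trace,
        U_hat=None,
        n_iter=n_iter,
        converged=conv,
    )
    if compute_blup:
        fitted.U_hat = blup_patterns(fitted, Yc, model)
    return fitted


def em_fit_replicates(
    Ys: np.ndarray,
    model: ComponentModel,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit a stack of replicate datasets sharing one design in one EM run.

    ``Ys`` is (R, N, P); every replicate is mean-removed, initialised by
    the method of moments and iterated jointly (identical to R separate
    :func:`em_fit` calls up to the shared stopping rule).  Returns
    ``(theta (R, H), noise_var (R,), loglik (R,), converged (R,))``.
    """
    Ys = np.asarray(Ys, dtype=float)
    if Ys.ndim != 3:
        raise ValueError("Ys must be (replicates, trials, voxels)")
    ybar = Ys.mean(axis=2)
    a = np.einsum("qn,rn->rq", np.linalg.pinv(model.Z), ybar)
    Yc = Ys - np.einsum("nq,rq->rn", model.Z, a)[:, :, None]
    theta0, sig0 = _moment_init(model.Z, Yc, model.basis)
    theta, sig2, ll, _, conv, _ = _em_core(
        Yc, model.Z, model.basis, theta0, sig0, tol=tol, max_iter=max_iter
    )
    return theta, sig2, np.asarray(ll), conv


def blup_patterns(
    fitted: FittedModel, Y_centred: np.ndarray, model: ComponentModel
) -> np.ndarray:
    """Best linear unbiased predictor of the hidden patterns.

    ``U_hat = G Z' (Z G Z' + I sigma_eps^2)^{-1} Y`` computed in the
    Q-dimensional space when sigma_eps^2 > 0 (identical to the dense form
    to numerical precision).
    """
    Y = np.asarray(Y_centred, float)
    n = Y.shape[0]
    G = fitted.G
    sig2 = fitted.params.noise_var
    Z = model.Z
    if sig2 <= 0:
        V = Z @ G @ Z.T
        # explicit singularity check: a PSD V with tiny eigenvalues is not invertible
        w = np.linalg.eigvalsh(V)
        if w.min() <= 1e-10 * max(w.max(), 1.0):
            raise SingularCovarianceError(
                "Z G Z' is rank-deficient and sigma_eps^2 = 0"
            )
        return G @ Z.T @ np.linalg.solve(V, Y)
    # Q-space reduction: G Z' V^{-1} = [G Z'Y - G K (sig2 I + G K)^{-1} G Z'Y] / sig2
    K = Z.T @ Z
    M = sig2 * np.eye(G.shape[0]) + G @ K
    SZ = Z.T @ Y
    inner = np.linalg.solve(M, G @ SZ)
    return (G @ SZ - G @ (K @ inner)) / sig2
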