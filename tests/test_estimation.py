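"""EM estimation: mean removal, likelihood paths, oracle equivalence, BLUP."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from pcmodel import (
    ParameterVector,
    SingularCovarianceError,
    assemble_G,
    blup_patterns,
    build_one_factorial,
    em_fit,
    em_fit_replicates,
    marginal_loglik,
    remove_mean,
)
from pcmodel.models import ComponentModel


def _identity_model(n):
    return ComponentModel(
        Z=np.eye(n),
        basis=np.eye(n)[None],
        param_names=["s"],
        blocks={"all": list(range(n))},
        component_names=[f"u{i}" for i in range(n)],
    )


class TestRemoveMean:
    def test_constant_data_single_component(self):
        m = ComponentModel(Z=np.ones((4, 1)), basis=np.ones((1, 1, 1)),
                           param_names=["s"], blocks={"all": [0]},
                           component_names=["u"])
        a, Yc = remove_mean(np.full((4, 6), 3.5), m)
        assert a == pytest.approx([3.5])
        assert np.allclose(Yc, 0.0)

    def test_identity_design_removes_per_trial_means(self, rng):
        m = _identity_model(5)
        Y = rng.standard_normal((5, 30))
        a, Yc = remove_mean(Y, m)
        assert np.allclose(a, Y.mean(axis=1))
        assert np.allclose(Yc.mean(axis=1), 0.0, atol=1e-12)

    def test_normal_equations_oracle(self, rng):
        m = build_one_factorial(3, 4)
        Y = rng.standard_normal((12, 20)) + 2.0
        a, Yc = remove_mean(Y, m)
        ybar = Y.mean(axis=1)
        a_ls, *_ = np.linalg.lstsq(m.Z, ybar, rcond=None)
        assert np.allclose(m.Z @ a, m.Z @ a_ls, atol=1e-10)
        # centred voxel-mean vector lies in the null space of Z^+
        assert np.allclose(np.linalg.pinv(m.Z) @ Yc.mean(axis=1), 0.0, atol=1e-10)


class TestMarginalLoglik:
    def test_pure_noise_unit_variance_zero_data(self):
        m = build_one_factorial(2, 2)
        Y = np.zeros((4, 3))
        p = ParameterVector(np.zeros(3), 1.0)
        expected = -0.5 * 4 * 3 * np.log(2 * np.pi)
        assert marginal_loglik(Y, m, p) == pytest.approx(expected)

    def test_pure_noise_matches_elementwise_gaussian(self, rng):
        m = build_one_factorial(2, 3)
        Y = rng.standard_normal((6, 4))
        s = 2.7
        p = ParameterVector(np.zeros(3), s)
        expected = np.sum(-0.5 * np.log(2 * np.pi * s) - Y**2 / (2 * s))
        assert marginal_loglik(Y, m, p) == pytest.approx(expected, rel=1e-12)

    def test_dense_mvn_oracle(self, rng):
        m = build_one_factorial(3, 2)
        Y = rng.standard_normal((6, 5))
        p = ParameterVector(rng.standard_normal(6), 0.8)
        V = m.Z @ assemble_G(m, p) @ m.Z.T + 0.8 * np.eye(6)
        oracle = sum(
            multivariate_normal.logpdf(Y[:, j], mean=np.zeros(6), cov=V)
            for j in range(5)
        )
        assert marginal_loglik(Y, m, p) == pytest.approx(oracle, rel=1e-10)

    def test_woodbury_matches_dense(self, rng):
        m = build_one_factorial(3, 5)
        Y = rng.standard_normal((15, 40))
        for _ in range(5):
            p = ParameterVector(rng.standard_normal(6), float(rng.uniform(0.1, 5)))
            dense = marginal_loglik(Y, m, p, method="dense")
            wood = marginal_loglik(Y, m, p, method="woodbury")
            assert wood == pytest.approx(dense, rel=1e-8)

    def test_singular_covariance_raises(self):
        m = _identity_model(3)
        with pytest.raises(SingularCovarianceError):
            marginal_loglik(np.ones((3, 4)), m, ParameterVector(np.zeros(1), 0.0),
                            method="dense")


class TestEMFit:
    def test_loglik_trace_monotone(self, rng):
        m = build_one_factorial(3, 5)
        for _ in range(5):
            Y = rng.standard_normal((15, 60)) * rng.uniform(0.5, 3)
            f = em_fit(Y, m, init=(rng.standard_normal(6) * 0.3, 1.0))
            assert np.all(np.diff(f.loglik_trace) >= -1e-6)

    def test_matches_numeric_optimizer_on_small_instances(self, rng):
        # independent oracle: direct maximization of the marginal likelihood
        m = build_one_factorial(2, 3)
        failures = 0
        for _ in range(20):
            Y = rng.standard_normal((6, 4)) * rng.uniform(0.5, 2)
            f = em_fit(Y, m, tol=1e-13, max_iter=50000)
            _, Yc = remove_mean(Y, m)

            def nll(x):
                return -marginal_loglik(
                    Yc, m, ParameterVector(x[:3], np.exp(x[3])), method="dense"
                )

            best = np.inf
            for s in range(3):
                r2 = np.random.default_rng(s)
                res = minimize(
                    nll, np.r_[r2.standard_normal(3) * 0.5, 0.0],
                    method="Nelder-Mead",
                    options=dict(maxiter=8000, maxfev=16000,
                                 xatol=1e-10, fatol=1e-12),
                )
                best = min(best, res.fun)
            if abs(f.loglik - (-best)) > 1e-3:
                failures += 1
        assert failures == 0

    def test_recovers_generating_covariance_at_large_p(self, rng):
        # truth is the simulation input; tolerance from replicate spread
        m = build_one_factorial(3, 5)
        G_true = np.array([[1.0, 0.0, -0.2], [0.0, 1.0, 0.8], [-0.2, 0.8, 1.0]])
        L = np.linalg.cholesky(G_true)
        P, reps = 10_000, 6
        Gs, sig2s = [], []
        for _ in range(reps):
            U = L @ rng.standard_normal((3, P))
            Y = m.Z @ U + np.sqrt(2.0) * rng.standard_normal((15, P))
            f = em_fit(Y, m)
            Gs.append(f.G)
            sig2s.append(f.params.noise_var)
        Gs = np.array(Gs)
        se = Gs.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(Gs.mean(axis=0) - G_true) < 3 * np.maximum(se, 0.01))
        # noise-variance bias below 2 percent at P = 10000
        assert abs(np.mean(sig2s) / 2.0 - 1.0) < 0.02

    def test_batched_fit_matches_single_fits(self, rng):
        m = build_one_factorial(3, 5)
        Ys = rng.standard_normal((4, 15, 30))
        theta, sig2, ll, conv = em_fit_replicates(Ys, m)
        for r in range(4):
            f = em_fit(Ys[r], m)
            assert assemble_G(m, theta[r]) == pytest.approx(f.G, abs=1e-4)
            assert sig2[r] == pytest.approx(f.params.noise_var, rel=1e-4)

    def test_max_iter_returns_unconverged_result(self, rng):
        m = build_one_factorial(3, 5)
        Y = rng.standard_normal((15, 30))
        f = em_fit(Y, m, init=(np.ones(6), 5.0), max_iter=2)
        assert f.converged is False
        assert np.isfinite(f.loglik)


class TestBlup:
    def test_zero_g_gives_zero_patterns(self, rng):
        m = build_one_factorial(3, 2)
        f = em_fit(rng.standard_normal((6, 10)), m, init=(np.zeros(6), 1.0),
                   max_iter=1, compute_blup=False)
        f.params = ParameterVector(np.zeros(6), 1.0)
        f.G = np.zeros((3, 3))
        assert np.allclose(blup_patterns(f, rng.standard_normal((6, 10)), m), 0.0)

    def test_identity_limits(self, rng):
        m = _identity_model(4)
        Y = rng.standard_normal((4, 8))
        f = em_fit(Y, m, max_iter=1, compute_blup=False)
        f.G = np.eye(4)
        f.params = ParameterVector(np.ones(1), 0.0)
        assert np.allclose(blup_patterns(f, Y, m), Y)
        f.params = ParameterVector(np.ones(1), 1.0)
        assert np.allclose(blup_patterns(f, Y, m), Y / 2.0)

    def test_woodbury_matches_dense_form(self, rng):
        m = build_one_factorial(3, 5)
        Y = rng.standard_normal((15, 20))
        f = em_fit(Y, m)
        dense = f.G @ m.Z.T @ np.linalg.solve(
            m.Z @ f.G @ m.Z.T + f.params.noise_var * np.eye(15), Y
        )
        assert np.allclose(blup_patterns(f, Y, m), dense, rtol=1e-8, atol=1e-10)

    def test_small_noise_limit_returns_data(self, rng):
        m = _identity_model(3)
        Y = rng.standard_normal((3, 6))
        f = em_fit(Y, m, max_iter=1, compute_blup=False)
        f.G = np.eye(3)
        f.params = ParameterVector(np.ones(1), 1e-8)
        assert np.allclose(blup_patterns(f, Y, m), Y, atol=1e-6)

    def test_singular_system_raises(self, rng):
        m = build_one_factorial(3, 2)
        f = em_fit(rng.standard_normal((6, 10)), m, compute_blup=False)
        f.G = np.zeros((3, 3))
        f.params = ParameterVector(np.zeros(6), 0.0)
        with pytest.raises(SingularCovarianceError):
            blup_patterns(f, rng.standard_normal((6, 10)), m)
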