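"""Corrected and naive similarity estimators, closed forms, and MDS."""

import numpy as np
import pytest

from pcmodel import (
    InvalidDesignError,
    PatternDataset,
    condition_mean_subtracted_corr,
    control_subtracted_corr,
    corrected_correlations,
    expected_cross_condition_corr,
    expected_sample_corr,
    mds_embed,
    sample_corr_mean_patterns,
)


class TestCorrectedCorrelations:
    def test_identity_gives_zero_offdiagonals(self):
        res = corrected_correlations(np.eye(3))
        assert np.allclose(res.corrected, np.eye(3))
        assert not res.unstable.any()

    def test_two_by_two(self):
        res = corrected_correlations(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert res.corrected[0, 1] == pytest.approx(0.5)

    def test_unstable_entries_flagged_not_clipped(self):
        G = np.diag([1.0, 1e-12, 1.0])
        res = corrected_correlations(G, floor=1e-6)
        assert res.unstable[1]
        assert np.isnan(res.corrected[0, 1])
        assert np.isnan(res.corrected[1, 1])
        assert res.corrected[0, 2] == pytest.approx(0.0)

    def test_psd_input_keeps_entries_in_unit_interval(self, rng):
        for _ in range(20):
            a = rng.standard_normal((4, 4))
            res = corrected_correlations(a @ a.T)
            vals = res.corrected[np.isfinite(res.corrected)]
            assert np.all(np.abs(vals) <= 1 + 1e-12)

    def test_asymmetric_rejected(self):
        with pytest.raises(InvalidDesignError):
            corrected_correlations(np.array([[1.0, 0.2], [0.5, 1.0]]))


def _one_factorial_dataset(rng, corr, noise_var, n=5, P=2000):
    K = len(corr)
    L = np.linalg.cholesky(corr)
    U = L @ rng.standard_normal((K, P))
    Z = np.kron(np.eye(K), np.ones((n, 1)))
    Y = Z @ U + np.sqrt(noise_var) * rng.standard_normal((K * n, P))
    cond = np.repeat([f"s{i+1}" for i in range(K)], n)
    return PatternDataset(Y=Y, condition=cond)


class TestSampleCorr:
    def test_identical_patterns_no_noise(self, rng):
        P = 50
        u = rng.standard_normal(P)
        Y = np.vstack([u, u, u, u])
        d = PatternDataset(Y=Y, condition=["a", "a", "b", "b"])
        c = sample_corr_mean_patterns(d)
        assert c.loc["a", "b"] == pytest.approx(1.0)

    def test_orthogonal_patterns_large_p(self, rng):
        d = _one_factorial_dataset(rng, np.eye(2), 0.0, n=2, P=20000)
        c = sample_corr_mean_patterns(d)
        assert abs(c.loc["s1", "s2"]) < 0.03

    def test_matches_noise_attenuation_closed_form(self, rng):
        # high noise shrinks the sample correlation to gamma/(sigma^2+noise/n)
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        reps, vals = 300, []
        for _ in range(reps):
            d = _one_factorial_dataset(rng, corr, 10.0, n=5, P=100)
            vals.append(sample_corr_mean_patterns(d).loc["s1", "s2"])
        expected = expected_sample_corr(0.8, 1.0, 1.0, 10.0, 5)
        se = np.std(vals, ddof=1) / np.sqrt(reps)
        assert expected == pytest.approx(0.8 / 3.0, abs=1e-12)
        assert abs(np.mean(vals) - expected) < max(3 * se, 0.02)

    def test_zero_variance_condition_undefined(self):
        Y = np.vstack([np.ones(5), np.ones(5), np.arange(5.0), np.arange(5.0)])
        d = PatternDataset(Y=Y, condition=["a", "a", "b", "b"])
        c = sample_corr_mean_patterns(d)
        assert np.isnan(c.loc["a", "b"])


class TestExpectedSampleCorr:
    def test_zero_noise_limit(self):
        assert expected_sample_corr(0.8, 1, 1, 0, 5) == pytest.approx(0.8)

    def test_zero_covariance(self):
        assert expected_sample_corr(0.0, 2.0, 3.0, 7.0, 4) == 0.0

    def test_printed_equal_variance_value(self):
        assert expected_sample_corr(0.8, 1, 1, 10, 5) == pytest.approx(0.2667, abs=5e-5)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidDesignError):
            expected_sample_corr(0.5, 1, 1, 1, 0)
        with pytest.raises(InvalidDesignError):
            expected_sample_corr(0.5, 0, 1, 1, 2)


class TestExpectedCrossConditionCorr:
    def test_matched_direct_substitution(self):
        v = expected_cross_condition_corr(0.0, 0.5, 2.0, 1.0, 0.0, 5, matched=True)
        assert v == pytest.approx(0.5 / 3.0)

    def test_no_matched_covariance_equalizes(self):
        m = expected_cross_condition_corr(0.4, 0.0, 2.0, 1.0, 3.0, 5, matched=True)
        nm = expected_cross_condition_corr(0.4, 0.0, 2.0, 1.0, 3.0, 5, matched=False)
        assert m == nm

    def test_difference_decreases_with_noise(self):
        diffs = [
            expected_cross_condition_corr(0.5, 0.5, 2.0, 1.0, nv, 5, True)
            - expected_cross_condition_corr(0.5, 0.5, 2.0, 1.0, nv, 5, False)
            for nv in (0.5, 4.0, 8.0)
        ]
        assert diffs[0] > diffs[1] > diffs[2] > 0


class TestControlSubtracted:
    def test_recovers_truth_without_noise(self, rng):
        P = 20000
        common = 2.0 * rng.standard_normal(P)
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        U = np.linalg.cholesky(corr) @ rng.standard_normal((2, P))
        Y = np.vstack([common, common + U[0], common + U[1]])
        d = PatternDataset(Y=Y, condition=["control", "s1", "s2"])
        c = control_subtracted_corr(d, "control")
        assert c.loc["s1", "s2"] == pytest.approx(0.8, abs=0.02)

    def test_pure_noise_control_induces_positive_bias(self, rng):
        # Monte-Carlo sign test: independent patterns + noisy control
        reps, vals = 200, []
        for _ in range(reps):
            d = _one_factorial_dataset(rng, np.eye(2), 4.0, n=5, P=100)
            ctrl = np.sqrt(4.0) * rng.standard_normal((5, 100))
            Y = np.vstack([ctrl, d.Y])
            dd = PatternDataset(Y=Y, condition=np.r_[["control"] * 5, d.condition])
            vals.append(control_subtracted_corr(dd).loc["s1", "s2"])
        assert np.mean(vals) > 3 * np.std(vals, ddof=1) / np.sqrt(reps)

    def test_missing_control_raises(self, rng):
        d = _one_factorial_dataset(rng, np.eye(2), 1.0)
        with pytest.raises(InvalidDesignError):
            control_subtracted_corr(d, "control")


class TestConditionMeanSubtracted:
    def _factorial_dataset(self, rng, noise_var, P=200, n=5):
        from pcmodel import build_factorial, sample_dataset, theta_from_G
        from pcmodel.simulate import ScenarioTruth

        m = build_factorial(2, 4, trials_per_cell=n)
        G = np.zeros((10, 10))
        G[:2, :2] = np.diag([2.0, 2.0])
        for f in range(4):
            G[2 + f, 2 + f] = G[6 + f, 6 + f] = 1.0
            G[2 + f, 6 + f] = G[6 + f, 2 + f] = 0.5
        truth = ScenarioTruth(model=m, theta_true=theta_from_G(m, G),
                              noise_var_true=noise_var, target_correlations={})
        return sample_dataset(truth, P=P, seed=rng)[0]

    def test_negative_bias_grows_with_noise(self, rng):
        means = []
        for nv in (0.5, 8.0):
            vals = []
            for _ in range(60):
                d = self._factorial_dataset(rng, nv, P=100)
                c = condition_mean_subtracted_corr(d)
                vals.append(np.mean([c.loc[f"c1l{i}", f"c2l{i}"] for i in range(1, 5)]))
            means.append(np.mean(vals))
        assert means[0] > means[1]  # estimates decrease as noise grows
        assert means[1] < 0.5

    def test_identical_level_patterns_residual_structure(self, rng):
        # pure noise in the level residuals: within-condition correlation -1/(K-1)
        n, P, K = 5, 300, 4
        reps, within = 150, []
        for _ in range(reps):
            base = rng.standard_normal(P)
            rows, labels = [], []
            for c in (1, 2):
                for lev in range(1, K + 1):
                    for _t in range(n):
                        rows.append(base + rng.standard_normal(P))
                        labels.append(f"c{c}l{lev}")
            d = PatternDataset(Y=np.array(rows), condition=labels)
            c = condition_mean_subtracted_corr(d)
            within.append(np.mean([c.loc["c1l1", f"c1l{j}"] for j in range(2, K + 1)]))
        assert np.mean(within) == pytest.approx(-1.0 / (K - 1), abs=0.03)


class TestMDS:
    def test_one_dimensional_structure_dominates(self):
        corr = np.array([[1.0, 0.0, -0.2], [0.0, 1.0, 0.8], [-0.2, 0.8, 1.0]])
        coords, w = mds_embed(corr, n_dims=2)
        assert w[1] / w[0] < 0.35
        assert coords[0, 0] >= 0  # reflection fixed

    def test_equidistant_stimuli_equal_eigenvalues(self):
        coords, w = mds_embed(np.eye(3), n_dims=2)
        pos = w[w > 1e-12]
        assert np.allclose(pos, pos[0])

    def test_two_points_distance_preserved(self):
        corr = np.array([[1.0, 0.4], [0.4, 1.0]])
        coords, _ = mds_embed(corr, n_dims=1)
        assert abs(coords[0, 0] - coords[1, 0]) == pytest.approx(0.6)

    def test_rank_one_similarity_second_eigenvalue_small(self):
        # exact corrected correlations from a rank-1-structure G
        v = np.array([1.0, 0.8, -0.6, 0.3])
        G = np.outer(v, v) + 1e-9 * np.eye(4)
        corr = G / np.sqrt(np.outer(np.diag(G), np.diag(G)))
        _, w = mds_embed(corr, n_dims=2)
        assert w[1] / w[0] < 0.05

    def test_asymmetric_rejected(self):
        with pytest.raises(InvalidDesignError):
            mds_embed(np.array([[1.0, 0.2], [0.3, 1.0]]))
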