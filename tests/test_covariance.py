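"""Covariance constructions, PSD guarantees, and second-order consistency.

The central property: every structure must yield a positive semidefinite
contrast covariance, which on the SD scale is the triangle inequality
tau_AC <= tau_AB + tau_BC for every treatment triple.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from hetnma import (
    ContrastCovariance,
    SphericalAngles,
    conditional_factors,
    contrast_variance,
    sigma_arm_based,
    sigma_common,
    sigma_proportional,
    spherical_to_correlation,
    trial_contrast_covariance,
)
from hetnma.covariance import build_spherical_cholesky, pair_order


class TestSphericalToCorrelation:
    def test_near_zero_cosines_give_identity(self):
        n = 4
        angles = SphericalAngles(n, np.full(6, 1e-9))
        R = spherical_to_correlation(angles).R
        assert np.allclose(R, np.eye(n), atol=1e-8)

    def test_three_treatment_closed_form(self, rng):
        for _ in range(20):
            c = rng.uniform(0.05, 0.95, 3)
            angles = SphericalAngles(3, c)
            R = spherical_to_correlation(angles).R
            c12, c13, c23 = c
            s12, s13 = math.sqrt(1 - c12**2), math.sqrt(1 - c13**2)
            assert R[0, 1] == pytest.approx(c12)
            assert R[0, 2] == pytest.approx(c13)
            assert R[1, 2] == pytest.approx(c12 * c13 + s12 * s13 * c23)

    def test_degenerate_rank_one(self):
        # cos(phi_12) = cos(phi_13) -> 1 forces rho_23 -> 1
        angles = SphericalAngles(3, np.array([1 - 1e-12, 1 - 1e-12, 0.3]))
        R = spherical_to_correlation(angles).R
        assert R[1, 2] == pytest.approx(1.0, abs=1e-5)

    def test_psd_by_construction_bulk(self, rng):
        n = 6
        n_pairs = n * (n - 1) // 2
        cos = rng.uniform(1e-6, 1 - 1e-6, size=(10_000, n_pairs))
        L = build_spherical_cholesky(cos, n)
        R = np.einsum("cki,ckj->cij", L, L)
        ev = np.linalg.eigvalsh(R)
        assert ev[:, 0].min() >= -1e-10

    def test_cholesky_consistency(self, rng):
        angles = SphericalAngles(5, rng.uniform(0.01, 0.99, 10))
        cm = spherical_to_correlation(angles)
        assert np.allclose(cm.L.T @ cm.L, cm.R, atol=1e-12)
        assert np.allclose(np.diag(cm.R), 1.0)


class TestSigmaCommon:
    def test_every_contrast_variance_is_tau2(self):
        cov = sigma_common(1.0, 3)
        for k, l in itertools.combinations(range(4), 2):
            assert contrast_variance(cov, k, l) == pytest.approx(1.0)

    def test_zero_variance_is_psd(self):
        cov = sigma_common(0.0, 4)
        assert np.all(cov.Sigma == 0)
        assert cov.is_psd()

    def test_p_matrix_eigenvalues(self):
        # eigenvalues of the 1/0.5 pattern matrix are (p+1)/2 (once) and 1/2
        cov = sigma_common(1.0, 7)
        ev = np.sort(cov.eigenvalues())
        assert ev[:-1] == pytest.approx(np.full(6, 0.5))
        assert ev[-1] == pytest.approx(4.0)

    def test_negative_tau2_rejected(self):
        with pytest.raises(ValueError):
            sigma_common(-0.1, 3)


class TestSigmaProportional:
    def test_zero_offsets_reduce_to_common(self):
        offsets = {pr: 0.0 for pr in itertools.combinations(range(4), 2)}
        cov = sigma_proportional(0.3, offsets)
        assert np.allclose(cov.Sigma, sigma_common(0.3, 3).Sigma)

    def test_smoking_offsets_psd(self):
        # control reference, three active arms, different offsets by type
        offsets = {}
        for k, l in itertools.combinations(range(4), 2):
            offsets[(k, l)] = -2.92 if k == 0 else -2.26
        cov = sigma_proportional(1.0, offsets)
        assert cov.is_psd()

    def test_psd_verdict_scale_invariant(self):
        offsets = {}
        for k, l in itertools.combinations(range(4), 2):
            offsets[(k, l)] = -2.92 if k == 0 else -2.26
        e1 = sigma_proportional(1.0, offsets).eigenvalues()
        e2 = sigma_proportional(17.3, offsets).eigenvalues()
        assert np.allclose(e2, 17.3 * e1)

    def test_invalid_offsets_raise_with_eigenvalue(self):
        offsets = {(0, 1): 0.0, (0, 2): 0.0, (1, 2): 5.0}
        with pytest.raises(ValueError, match="eigenvalue"):
            sigma_proportional(1.0, offsets)

    def test_incomplete_offsets_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            sigma_proportional(1.0, {(0, 1): 0.0, (0, 2): 0.0})


class TestSigmaArmBased:
    def test_equal_arms_half_correlation_is_common(self):
        tau = np.full(4, 0.7)
        R = np.full((4, 4), 0.5)
        np.fill_diagonal(R, 1.0)
        cov = sigma_arm_based(tau, R)
        assert np.allclose(cov.Sigma, sigma_common(0.49, 3).Sigma)

    def test_contrast_variance_matches_arm_formula(self, rng):
        n = 5
        tau = rng.uniform(0.1, 1.5, n)
        angles = SphericalAngles(n, rng.uniform(0.05, 0.95, 10))
        R = spherical_to_correlation(angles)
        cov = sigma_arm_based(tau, R)
        for k, l in itertools.combinations(range(n), 2):
            expected = tau[k] ** 2 + tau[l] ** 2 - 2 * R.R[k, l] * tau[k] * tau[l]
            assert contrast_variance(cov, k, l) == pytest.approx(expected, abs=1e-12)

    def test_psd_bulk(self, rng):
        n = 4
        failures = 0
        cos = rng.uniform(1e-6, 1 - 1e-6, size=(10_000, 6))
        taus = rng.uniform(0, 2, size=(10_000, 4))
        L = build_spherical_cholesky(cos, n)
        R = np.einsum("cki,ckj->cij", L, L)
        V = R * taus[:, :, None] * taus[:, None, :]
        Sig = V[:, 1:, 1:] - V[:, 1:, :1] - V[:, :1, 1:] + V[:, :1, :1]
        ev = np.linalg.eigvalsh(Sig)
        assert ev[:, 0].min() >= -1e-10

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            sigma_arm_based([1.0, 1.0], np.eye(3))


class TestContrastVariance:
    def test_identity_sigma(self):
        cov = ContrastCovariance(np.eye(2))
        assert contrast_variance(cov, 1, 2) == pytest.approx(2.0)
        assert contrast_variance(cov, 0, 1) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        A = rng.standard_normal((3, 3))
        cov = ContrastCovariance(A @ A.T)
        for k, l in itertools.combinations(range(4), 2):
            assert contrast_variance(cov, k, l) == contrast_variance(cov, l, k)

    def test_same_treatment_errors(self):
        with pytest.raises(ValueError):
            contrast_variance(ContrastCovariance(np.eye(2)), 1, 1)


class TestTrialContrastCovariance:
    def test_two_arm_trial_is_scalar(self):
        cov = sigma_common(0.25, 4)
        C = trial_contrast_covariance(cov, [1, 3])
        assert C.shape == (1, 1)
        assert C[0, 0] == pytest.approx(0.25)

    def test_equal_variance_off_diagonal(self):
        cov = sigma_common(1.0, 4)
        C = trial_contrast_covariance(cov, [0, 1, 2])
        assert C[0, 1] == pytest.approx(0.5)  # (tau^2 + tau^2 - tau^2) / 2

    def test_rebasing_invariance(self, rng):
        # Var(delta_bY - delta_bX) must equal the contrast variance for (X, Y)
        tau = rng.uniform(0.2, 1.0, 4)
        angles = SphericalAngles(4, rng.uniform(0.05, 0.95, 6))
        cov = sigma_arm_based(tau, spherical_to_correlation(angles))
        C = trial_contrast_covariance(cov, [1, 2, 3], baseline=1)
        implied = C[0, 0] + C[1, 1] - 2 * C[0, 1]
        assert implied == pytest.approx(contrast_variance(cov, 2, 3), abs=1e-12)


class TestConditionalFactors:
    def test_bivariate_equal_variance(self):
        tau2 = 0.64
        cov = np.array([[tau2, tau2 / 2], [tau2 / 2, tau2]])
        factors = conditional_factors([0.0, 0.0], cov)
        assert factors[0][2] == pytest.approx(tau2)
        assert factors[1][2] == pytest.approx(0.75 * tau2)  # tau^2 - (tau^2/2)^2 / tau^2

    def test_diagonal_gives_independent_conditionals(self):
        factors = conditional_factors([1.0, 2.0, 3.0], np.diag([1.0, 2.0, 3.0]))
        for i, (_, coef, v) in enumerate(factors):
            assert np.allclose(coef, 0.0)
            assert v == pytest.approx(float(i + 1))

    def test_product_of_conditionals_is_joint_density(self, rng):
        for _ in range(10):
            A = rng.standard_normal((3, 3))
            cov = A @ A.T + 0.1 * np.eye(3)
            mean = rng.standard_normal(3)
            x = rng.standard_normal(3)
            factors = conditional_factors(mean, cov)
            total = 0.0
            for i, (mu_i, coef, v) in enumerate(factors):
                cm = mu_i + coef @ (x[:i] - mean[:i])
                total += -0.5 * ((x[i] - cm) ** 2 / v + math.log(2 * math.pi * v))
            expected = multivariate_normal(mean, cov).logpdf(x)
            assert total == pytest.approx(expected, abs=1e-10)

    def test_singular_leading_block_degenerates(self):
        cov = np.array([[1.0, 1.0], [1.0, 1.0]])
        factors = conditional_factors([0.0, 0.0], cov)
        assert factors[1][2] == pytest.approx(0.0)
        assert factors[1][1][0] == pytest.approx(1.0)


class TestSecondOrderConsistency:
    """PSD of Sigma implies tau_AC <= tau_AB + tau_BC on the SD scale."""

    @staticmethod
    def _check_triangles(cov):
        n_t = cov.p + 1
        for a, b, c in itertools.combinations(range(n_t), 3):
            t_ab = math.sqrt(contrast_variance(cov, a, b))
            t_bc = math.sqrt(contrast_variance(cov, b, c))
            t_ac = math.sqrt(contrast_variance(cov, a, c))
            assert t_ac <= t_ab + t_bc + 1e-9

    def test_common(self, rng):
        for _ in range(20):
            self._check_triangles(sigma_common(rng.uniform(0, 2), 4))

    def test_arm_based(self, rng):
        for _ in range(200):
            tau = rng.uniform(0, 1.5, 5)
            angles = SphericalAngles(5, rng.uniform(0.01, 0.99, 10))
            self._check_triangles(sigma_arm_based(tau, spherical_to_correlation(angles)))

    def test_proportional_when_psd(self, rng):
        for _ in range(100):
            offsets = {
                pr: rng.uniform(-1, 1) for pr in itertools.combinations(range(4), 2)
            }
            try:
                cov = sigma_proportional(rng.uniform(0.1, 2.0), offsets)
            except ValueError:
                continue  # rejected as non-PSD: nothing to check
            self._check_triangles(cov)
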