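"""Contrast covariance matrices under the four heterogeneity structures.

The random effects of study j are the contrasts with the overall reference
treatment, delta_j = (delta_j01, ..., delta_j0p) ~ N(d, Sigma).  The diagonal
of Sigma holds the heterogeneity variances of the reference contrasts; the
variance for a comparison of two non-reference treatments k, l is

    tau_kl^2 = Sigma_kk + Sigma_ll - 2 Sigma_kl.

Keeping Sigma positive semidefinite guarantees second-order consistency: for
any treatment triple the heterogeneity standard deviations satisfy the
triangle inequality.  Each constructor here either guarantees PSD by
construction (common variance, arm-based with a valid correlation matrix) or
checks it explicitly (proportional variances).

Correlation matrices are built from spherical angles through their Cholesky
factor: R = L^T L with unit-norm upper-triangular columns, so R is PSD for
any angles.  Column j of L uses the angles (phi_1j, ..., phi_{j-1,j}) in
lexicographic order; for three treatments this reduces to the closed forms
rho_12 = cos(phi_12), rho_13 = cos(phi_13),
rho_23 = cos(phi_12)cos(phi_13) + sin(phi_12)sin(phi_13)cos(phi_23).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .priors import BetaPrior, LogNormalPrior, ProportionalPriorSpec, ScaledWishartSpec

__all__ = [
    "SphericalAngles",
    "CorrelationMatrix",
    "ContrastCovariance",
    "CommonVariance",
    "ProportionalVariances",
    "ArmBased",
    "ScaledWishart",
    "pair_order",
    "spherical_to_correlation",
    "sigma_common",
    "sigma_proportional",
    "sigma_arm_based",
    "contrast_variance",
    "trial_contrast_covariance",
    "conditional_factors",
]

#: relative PSD tolerance: eigenvalues above -1e-8 * max(1, largest) pass
PSD_RTOL = 1e-8


def pair_order(n_treatments: int) -> list[tuple[int, int]]:
    """Unordered pairs (i, j), i < j, grouped by column of the Cholesky factor:
    (0,1), (0,2), (1,2), (0,3), (1,3), (2,3), ...  This is the order in which
    ``SphericalAngles`` stores its cosines."""
    return [(i, j) for j in range(1, n_treatments) for i in range(j)]


@dataclass(frozen=True)
class SphericalAngles:
    """Angles of the spherical correlation parameterization, stored as cosines.

    ``cosines[k]`` is cos(phi_ij) in (0, 1) for the k-th pair of
    ``pair_order(n_treatments)``.  Restricting the cosines to (0, 1) keeps the
    first-row correlations positive (arm random effects are expected to be
    positively correlated); correlations between non-first treatments can
    still take any achievable value.
    """

    n_treatments: int
    cosines: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cosines, dtype=float)
        object.__setattr__(self, "cosines", c)
        n_pairs = self.n_treatments * (self.n_treatments - 1) // 2
        if c.shape != (n_pairs,):
            raise ValueError(f"expected {n_pairs} cosines, got shape {c.shape}")
        if np.any(c <= 0) or np.any(c >= 1):
            raise ValueError("cosines must lie strictly in (0, 1)")

    @classmethod
    def from_mapping(cls, n_treatments: int, values: dict[tuple[int, int], float]) -> "SphericalAngles":
        order = pair_order(n_treatments)
        return cls(n_treatments, np.array([values[p] for p in order]))


@dataclass(frozen=True)
class CorrelationMatrix:
    """A correlation matrix R = L^T L with unit-norm Cholesky columns."""

    R: np.ndarray
    L: np.ndarray

    @property
    def n(self) -> int:
        return self.R.shape[0]

    def __getitem__(self, idx) -> float:
        return self.R[idx]


@dataclass(frozen=True)
class ContrastCovariance:
    """The p x p covariance Sigma of the reference contrasts (delta_j01..delta_j0p)."""

    Sigma: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.Sigma, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("Sigma must be square")
        if not np.allclose(S, S.T, atol=1e-12, rtol=0):
            raise ValueError("Sigma must be symmetric")
        object.__setattr__(self, "Sigma", S)

    @property
    def p(self) -> int:
        return self.Sigma.shape[0]

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.Sigma)

    def min_eigenvalue(self) -> float:
        return float(self.eigenvalues()[0])

    def is_psd(self, rtol: float = PSD_RTOL) -> bool:
        ev = self.eigenvalues()
        scale = max(1.0, float(ev[-1]))
        return bool(ev[0] >= -rtol * scale)


def build_spherical_cholesky(cosines: np.ndarray, n_treatments: int) -> np.ndarray:
    """Upper-triangular L with unit-norm columns from angle cosines.

    ``cosines`` may be batched: shape (..., n_pairs); returns (..., n, n).
    """
    c = np.asarray(cosines, dtype=float)
    n = n_treatments
    batch = c.shape[:-1]
    L = np.zeros(batch + (n, n))
    L[..., 0, 0] = 1.0
    idx = 0
    for j in range(1, n):
        sin_prod = np.ones(batch)
        for i in range(j):
            ck = c[..., idx]
            idx += 1
            L[..., i, j] = ck * sin_prod
            sin_prod = sin_prod * np.sqrt(1.0 - ck * ck)
        L[..., j, j] = sin_prod
    return L


def spherical_to_correlation(angles: SphericalAngles) -> CorrelationMatrix:
    """Correlation matrix from spherical angles; PSD by construction."""
    L = build_spherical_cholesky(angles.cosines, angles.n_treatments)
    R = L.T @ L
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R=R, L=L)


def sigma_common(tau2: float, p: int) -> ContrastCovariance:
    """Sigma = tau^2 P with unit diagonal and 0.5 off-diagonal: every
    comparison then has heterogeneity variance tau^2 exactly."""
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    P = np.full((p, p), 0.5)
    np.fill_diagonal(P, 1.0)
    return ContrastCovariance(tau2 * P)


def sigma_proportional(
    tau2: float,
    offsets: dict[tuple[int, int], float] | ProportionalPriorSpec,
    check_psd: bool = True,
) -> ContrastCovariance:
    """Sigma implied by proportional heterogeneity variances
    tau_kl^2 = tau^2 exp(m_kl).

    ``offsets`` maps every unordered treatment pair over 0..p (reference
    included) to its log offset m_kl.  Off-diagonal entries are recovered by
    inverting tau_kl^2 = Sigma_kk + Sigma_ll - 2 Sigma_kl.  The result is not
    automatically PSD; an invalid configuration raises with the offending
    eigenvalue unless ``check_psd`` is disabled.
    """
    if isinstance(offsets, ProportionalPriorSpec):
        offsets = offsets.offsets
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    pairs = {(min(k, l), max(k, l)): v for (k, l), v in offsets.items()}
    n_t = max(max(k, l) for k, l in pairs) + 1
    p = n_t - 1
    tau_kl2 = np.zeros((n_t, n_t))
    for (k, l), m in pairs.items():
        tau_kl2[k, l] = tau_kl2[l, k] = tau2 * math.exp(m)
    expected = p * (p + 1) // 2
    if len(pairs) != expected:
        raise ValueError(f"offsets must cover all {expected} pairs over treatments 0..{p}")
    diag = tau_kl2[0, 1:]
    Sigma = (diag[:, None] + diag[None, :] - tau_kl2[1:, 1:]) / 2.0
    np.fill_diagonal(Sigma, diag)
    cov = ContrastCovariance(Sigma)
    if check_psd and tau2 > 0 and not cov.is_psd():
        raise ValueError(
            "proportional offsets give a non-positive-semidefinite Sigma "
            f"(min eigenvalue {cov.min_eigenvalue():.3e}); "
            "use the arm-based or scaled-Wishart structure instead"
        )
    return cov


def sigma_arm_based(tau_arm: Sequence[float], R: CorrelationMatrix | np.ndarray) -> ContrastCovariance:
    """Sigma from arm-level SDs tau_k (k = 0..p) and arm correlation matrix R.

    Interpreting tau_k as the SD of a latent arm effect theta_jk,
    Sigma_kl = Cov(theta_jk - theta_j0, theta_jl - theta_j0); PSD is
    guaranteed whenever R is PSD.
    """
    tau = np.asarray(tau_arm, dtype=float)
    if np.any(tau < 0):
        raise ValueError("arm SDs must be >= 0")
    Rm = R.R if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    n_t = tau.shape[0]
    if Rm.shape != (n_t, n_t):
        raise ValueError(f"R must be {n_t}x{n_t} to match {n_t} arm SDs")
    V = Rm * np.outer(tau, tau)  # Cov(theta_k, theta_l)
    Sigma = V[1:, 1:] - V[1:, :1] - V[:1, 1:] + V[0, 0]
    return ContrastCovariance((Sigma + Sigma.T) / 2.0)


def contrast_variance(Sigma: ContrastCovariance | np.ndarray, k: int, l: int) -> float:
    """Heterogeneity variance tau_kl^2 of the comparison of treatments k and l
    (treatment indices over 0..p, 0 = reference)."""
    S = Sigma.Sigma if isinstance(Sigma, ContrastCovariance) else np.asarray(Sigma)
    if k == l:
        raise ValueError("contrast requires two distinct treatments")
    if k > l:
        k, l = l, k
    if k == 0:
        return float(S[l - 1, l - 1])
    return float(S[k - 1, k - 1] + S[l - 1, l - 1] - 2.0 * S[k - 1, l - 1])


def trial_contrast_covariance(
    Sigma: ContrastCovariance | np.ndarray, arms: Sequence[int], baseline: int | None = None
) -> np.ndarray:
    """Covariance of a trial's own contrasts (delta_jbk for non-baseline arms k).

    Var(delta_jbk) = tau_bk^2 and Cov(delta_jbk, delta_jbl) =
    (tau_bk^2 + tau_bl^2 - tau_kl^2)/2, which is the re-basing of Sigma to the
    trial's baseline treatment.
    """
    arms = sorted(arms)
    if baseline is None:
        baseline = arms[0]
    if baseline not in arms:
        raise ValueError("baseline must be one of the trial's arms")
    others = [a for a in arms if a != baseline]
    m = len(others)
    C = np.empty((m, m))
    for i, k in enumerate(others):
        C[i, i] = contrast_variance(Sigma, baseline, k)
    for i, k in enumerate(others):
        for j in range(i + 1, m):
            l = others[j]
            C[i, j] = C[j, i] = (C[i, i] + C[j, j] - contrast_variance(Sigma, k, l)) / 2.0
    return C


def conditional_factors(
    mean: Sequence[float], cov: np.ndarray
) -> list[tuple[float, np.ndarray, float]]:
    """Sequential decomposition of a multivariate normal into univariate
    conditionals.

    Returns one triple per coordinate i: (marginal mean mu_i, coefficient
    vector c_i over the preceding coordinates, conditional variance v_i) such
    that  x_i | x_{<i} ~ N(mu_i + c_i . (x_{<i} - mu_{<i}), v_i).  The product
    of the conditionals equals the joint density.  A singular leading
    submatrix is handled by pseudo-inverse, giving a degenerate (zero
    variance) conditional.
    """
    mu = np.asarray(mean, dtype=float)
    C = np.asarray(cov, dtype=float)
    n = mu.shape[0]
    factors: list[tuple[float, np.ndarray, float]] = []
    for i in range(n):
        if i == 0:
            factors.append((float(mu[0]), np.zeros(0), float(C[0, 0])))
            continue
        A = C[:i, :i]
        b = C[:i, i]
        coef = np.linalg.pinv(A, hermitian=True) @ b
        v = float(C[i, i] - b @ coef)
        factors.append((float(mu[i]), coef, max(v, 0.0)))
    return factors


# ---------------------------------------------------------------------------
# Heterogeneity structures (the tagged union selecting approach 1/2/3/4)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommonVariance:
    """Approach 1: a single heterogeneity variance tau^2 for every comparison.

    ``prior`` is a log-normal prior for tau^2; if None, tau ~ Uniform(0, upper)
    on the SD scale (the vague default, with upper = 2 suited to log
    odds-ratio analyses).
    """

    prior: LogNormalPrior | None = None
    upper: float = 2.0

    @property
    def vague(self) -> bool:
        return self.prior is None


@dataclass(frozen=True)
class ProportionalVariances:
    """Approach 2: tau_kl^2 = tau^2 exp(m_kl) with fixed offsets per contrast.

    Informative form: offsets from comparison-type priors and
    log(tau^2) ~ N(0, s^2).  Vague form (``vague=True``): tau ~ Uniform(0,
    upper) and a single free offset m ~ N(0, free_offset_sd^2) shared by the
    contrasts listed in ``free_pairs`` (typically the active-vs-active ones),
    the remaining offsets being zero.
    """

    offsets: tuple[tuple[tuple[int, int], float], ...] = ()
    s: float = 0.5
    vague: bool = False
    free_pairs: tuple[tuple[int, int], ...] = ()
    free_offset_sd: float = 0.5
    upper: float = 2.0

    @classmethod
    def from_spec(cls, spec: ProportionalPriorSpec) -> "ProportionalVariances":
        return cls(offsets=tuple(sorted(spec.offsets.items())), s=spec.s)

    def offset_map(self) -> dict[tuple[int, int], float]:
        return {(min(k, l), max(k, l)): v for (k, l), v in self.offsets}


@dataclass(frozen=True)
class ArmBased:
    """Approach 3: unequal variances via arm-level SDs and spherical angles.

    ``arm_prior`` is a log-normal prior for each tau_k^2 (moment-matched to a
    target comparison-level prior); if None, tau_k ~ Uniform(0, upper).
    ``angle_prior`` is the Beta prior for the angle cosines.
    """

    n_treatments: int
    angle_prior: BetaPrior
    arm_prior: LogNormalPrior | None = None
    upper: float = 2.0

    @property
    def vague(self) -> bool:
        return self.arm_prior is None


@dataclass(frozen=True)
class ScaledWishart:
    """Approach 4: Sigma = lambda M^{-1} with M ~ Wishart(S, t) and log-normal lambda."""

    spec: ScaledWishartSpec


HeterogeneityStructure = CommonVariance | ProportionalVariances | ArmBased | ScaledWishart
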