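"""Posterior sampling for the random-effects network meta-analysis model.

Model
-----
For arm k of study j with baseline treatment b_j:

    r_jk ~ Binomial(pi_jk, n_jk),
    logit(pi_jk) = mu_j + delta_jbk [k > b_j],   delta_jbb = 0,

with study baselines mu_j ~ N(0, 10^4), basic parameters
d_01..d_0p ~ N(0, 10^4), and the study's contrast vector drawn from the
restriction of N(d, Sigma) to its arms.  Multi-arm trials enter through the
sequential conditional decomposition of that multivariate normal, ordered by
treatment index.  Sigma is governed by one of the four heterogeneity
structures (common, proportional, arm-based, scaled inverse-Wishart).

Sampler
-------
Component-wise adaptive random-walk Metropolis within Gibbs, with all chains
advanced simultaneously as vectorized numpy operations:

* mu_j and the per-study random-effect vectors are Metropolis-updated with
  per-study step sizes adapted towards 0.44 acceptance during burn-in only;
* the basic parameters d are updated by an exact Gibbs draw (their full
  conditional given the random effects is Gaussian for every structure);
* heterogeneity parameters are Metropolis-updated component-wise on
  unconstrained scales (log for variances and the Wishart Cholesky diagonal,
  logit for bounded standard deviations and angle cosines, identity for
  offsets and log lambda).

Draws are reproducible given the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import betaln, expit, gammaln, multigammaln

from .covariance import (
    ArmBased,
    CommonVariance,
    ContrastCovariance,
    HeterogeneityStructure,
    ProportionalVariances,
    ScaledWishart,
    build_spherical_cholesky,
    conditional_factors,
    pair_order,
    sigma_common,
    sigma_proportional,
    trial_contrast_covariance,
)
from .network import NetworkDataset

__all__ = [
    "MCMCConfig",
    "ParameterState",
    "PosteriorSamples",
    "functional_contrasts",
    "log_likelihood",
    "log_prior",
    "sample_posterior",
]

_VAGUE_VAR = 1e4  # N(0, 10^4) variance for study baselines and basic parameters


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler run lengths.  ``iterations`` counts all iterations per chain;
    the first ``burn_in`` are discarded (and are the only ones during which
    proposal step sizes adapt)."""

    chains: int = 4
    iterations: int = 100_000
    burn_in: int = 20_000
    thin: int = 1
    seed: int = 0
    adapt_window: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class ParameterState:
    """One point in parameter space (used by the density functions and tests).

    ``delta`` is aligned with the dataset's non-baseline arms in study order
    (studies as listed, arms by treatment index).  ``het`` is the
    heterogeneity block in the sampler's unconstrained coordinates.
    """

    mu: np.ndarray
    d: np.ndarray
    delta: np.ndarray
    het: np.ndarray


def functional_contrasts(d_basic: np.ndarray) -> np.ndarray:
    """All pairwise contrasts d_kl = d_0l - d_0k from the basic parameters.

    Accepts batched input (..., p); returns (..., p+1, p+1) with
    out[..., k, l] = d_kl (antisymmetric, zero diagonal).
    """
    d = np.asarray(d_basic, dtype=float)
    full = np.concatenate([np.zeros(d.shape[:-1] + (1,)), d], axis=-1)
    return full[..., None, :] - full[..., :, None]


# ---------------------------------------------------------------------------
# Dataset precomputation
# ---------------------------------------------------------------------------


class _ModelData:
    """Flat index arrays for vectorized likelihood and random-effect terms."""

    def __init__(self, ds: NetworkDataset):
        self.ds = ds
        self.p = ds.p
        self.J = len(ds.studies)
        arm_study, arm_r, arm_n, arm_delta = [], [], [], []
        d_k, d_b, d_study = [], [], []
        self.study_delta_slices: list[tuple[int, int]] = []
        pos = 0
        for j, s in enumerate(ds.studies):
            b = s.baseline
            start = pos
            for a in s.arms:
                arm_study.append(j)
                arm_r.append(a.events)
                arm_n.append(a.total)
                if a.treatment == b:
                    arm_delta.append(-1)
                else:
                    arm_delta.append(pos)
                    d_k.append(a.treatment)
                    d_b.append(b)
                    d_study.append(j)
                    pos += 1
            self.study_delta_slices.append((start, pos))
        self.A = len(arm_study)
        self.D = pos
        self.arm_study = np.array(arm_study)
        self.arm_r = np.array(arm_r, dtype=float)
        self.arm_n = np.array(arm_n, dtype=float)
        self.arm_delta = np.array(arm_delta)
        self.nb_mask = self.arm_delta >= 0
        self.d_k = np.array(d_k)
        self.d_b = np.array(d_b)
        self.d_study = np.array(d_study)
        # design matrix: row i of X maps d -> E[delta_i]
        X = np.zeros((self.D, self.p))
        for i, (k, b) in enumerate(zip(self.d_k, self.d_b)):
            X[i, k - 1] += 1.0
            if b > 0:
                X[i, b - 1] -= 1.0
        self.X = X
        self.two_arm = np.array(
            [j for j, (a, b) in enumerate(self.study_delta_slices) if b - a == 1]
        )
        self.multi_arm = [
            (j, a, b) for j, (a, b) in enumerate(self.study_delta_slices) if b - a > 1
        ]
        self.two_arm_delta = np.array(
            [self.study_delta_slices[j][0] for j in self.two_arm], dtype=int
        )
        # reduceat boundaries over arms per study (arms are study-contiguous)
        starts = [0]
        for s in ds.studies:
            starts.append(starts[-1] + len(s.arms))
        self.arm_starts = np.array(starts[:-1])
        self.binom_const = float(
            np.sum(gammaln(self.arm_n + 1) - gammaln(self.arm_r + 1) - gammaln(self.arm_n - self.arm_r + 1))
        )

    # --- likelihood -------------------------------------------------------

    def arm_loglik_by_study(self, mu: np.ndarray, delta: np.ndarray) -> np.ndarray:
        """Binomial log likelihood summed per study (constant dropped); (C, J)."""
        eta = mu[:, self.arm_study]
        eta = eta + np.where(self.nb_mask, delta[:, np.clip(self.arm_delta, 0, None)], 0.0)
        ll = self.arm_r * eta - self.arm_n * np.logaddexp(0.0, eta)
        return np.add.reduceat(ll, self.arm_starts, axis=1)

    def delta_mean(self, d: np.ndarray) -> np.ndarray:
        """Prior mean of each random effect, d_0k - d_0b; (C, D)."""
        mean = d[:, self.d_k - 1].copy()
        mask = self.d_b > 0
        if mask.any():
            mean[:, mask] -= d[:, self.d_b[mask] - 1]
        return mean

    def _pair_variance(self, Sigma: np.ndarray, k: np.ndarray, b: np.ndarray) -> np.ndarray:
        """tau_bk^2 for arrays of pairs (b < k); Sigma is (C, p, p)."""
        km = k - 1
        v = Sigma[:, km, km].copy()
        mask = b > 0
        if mask.any():
            bm = b[mask] - 1
            v[:, mask] = (
                Sigma[:, bm, bm] + Sigma[:, km[mask], km[mask]] - 2.0 * Sigma[:, bm, km[mask]]
            )
        return v

    def re_logpdf_by_study(
        self, delta: np.ndarray, mean: np.ndarray, Sigma: np.ndarray
    ) -> np.ndarray:
        """Random-effect log density per study; (C, J).  -inf where invalid."""
        C = delta.shape[0]
        out = np.zeros((C, self.J))
        if self.two_arm.size:
            idx = self.two_arm_delta
            var = self._pair_variance(Sigma, self.d_k[idx], self.d_b[idx])
            with np.errstate(divide="ignore", invalid="ignore"):
                resid = delta[:, idx] - mean[:, idx]
                lp = -0.5 * (resid * resid / var + np.log(2.0 * np.pi * var))
            lp = np.where(var > 0, lp, np.where(np.abs(resid) < 1e-12, 0.0, -np.inf))
            out[:, self.two_arm] = lp
        for j, a, b in self.multi_arm:
            cov = self._trial_cov(Sigma, a, b)
            resid = delta[:, a:b] - mean[:, a:b]
            m = b - a
            try:
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                out[:, j] = -np.inf
                continue
            z = np.linalg.solve(L, resid[..., None])[..., 0]
            logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
            out[:, j] = -0.5 * (np.sum(z * z, axis=1) + logdet + m * math.log(2.0 * math.pi))
        return out

    def _trial_cov(self, Sigma: np.ndarray, a: int, b: int) -> np.ndarray:
        """Trial contrast covariance for the delta slice [a:b); (C, m, m)."""
        ks = self.d_k[a:b]
        bl = self.d_b[a:b]
        m = b - a
        C = Sigma.shape[0]
        cov = np.empty((C, m, m))
        var = self._pair_variance(Sigma, ks, bl)
        for i in range(m):
            cov[:, i, i] = var[:, i]
        for i in range(m):
            for jj in range(i + 1, m):
                tkl = self._pair_variance(
                    Sigma, np.array([max(ks[i], ks[jj])]), np.array([min(ks[i], ks[jj])])
                )[:, 0]
                cov[:, i, jj] = cov[:, jj, i] = 0.5 * (var[:, i] + var[:, jj] - tkl)
        return cov


# ---------------------------------------------------------------------------
# Heterogeneity blocks: unconstrained parameterizations per structure
# ---------------------------------------------------------------------------


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


class _HetBlock:
    n_params: int
    names: list[str]

    def init(self, rng: np.random.Generator, chains: int) -> np.ndarray:
        raise NotImplementedError

    def sigma_and_logprior(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map unconstrained (C, H) to (Sigma (C, p, p), log prior (C,))."""
        raise NotImplementedError

    def natural(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Interpretable parameter values from unconstrained coordinates."""
        raise NotImplementedError

    def sample_prior(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Forward draws of Sigma from the prior; (n, p, p)."""
        raise NotImplementedError

    def from_natural(self, values: Mapping[str, float | np.ndarray]) -> np.ndarray | None:
        """Unconstrained coordinates for natural-scale values; None if outside
        the prior's support."""
        raise NotImplementedError


class _CommonBlock(_HetBlock):
    def __init__(self, structure: CommonVariance, p: int):
        self.structure = structure
        self.p = p
        self.n_params = 1
        self.names = ["tau"]
        P = np.full((p, p), 0.5)
        np.fill_diagonal(P, 1.0)
        self.P = P

    def _tau2(self, x: np.ndarray) -> np.ndarray:
        if self.structure.vague:
            return (self.structure.upper * expit(x[:, 0])) ** 2
        return np.exp(x[:, 0])

    def init(self, rng, chains):
        if self.structure.vague:
            x0 = np.log(0.1 / (self.structure.upper - 0.1))
        else:
            x0 = self.structure.prior.m
        return x0 + 0.1 * rng.standard_normal((chains, 1))

    def sigma_and_logprior(self, x):
        tau2 = self._tau2(x)
        Sigma = tau2[:, None, None] * self.P
        if self.structure.vague:
            # tau ~ U(0, upper) through tau = upper * sigmoid(x)
            lp = _log_sigmoid(x[:, 0]) + _log_sigmoid(-x[:, 0])
        else:
            pr = self.structure.prior
            lp = -0.5 * ((x[:, 0] - pr.m) / pr.s) ** 2 - math.log(pr.s) - 0.5 * math.log(2 * math.pi)
        return Sigma, lp

    def natural(self, x):
        return {"tau": np.sqrt(self._tau2(x))}

    def sample_prior(self, rng, n):
        if self.structure.vague:
            tau = rng.uniform(0.0, self.structure.upper, n)
            tau2 = tau**2
        else:
            tau2 = np.exp(rng.normal(self.structure.prior.m, self.structure.prior.s, n))
        return tau2[:, None, None] * self.P

    def from_natural(self, values):
        tau = float(values["tau"])
        if self.structure.vague:
            if not 0.0 < tau < self.structure.upper:
                return None
            u = tau / self.structure.upper
            return np.array([math.log(u / (1.0 - u))])
        if tau <= 0:
            return None
        return np.array([2.0 * math.log(tau)])


class _ProportionalBlock(_HetBlock):
    def __init__(self, structure: ProportionalVariances, p: int):
        self.structure = structure
        self.p = p
        offsets = structure.offset_map()
        n_t = p + 1
        pairs = pair_order(n_t)
        if structure.vague:
            self.n_params = 2
            self.names = ["tau", "m"]
            base = {pr: 0.0 for pr in pairs}
            base.update({(min(k, l), max(k, l)): 0.0 for (k, l) in structure.free_pairs})
            self.base_offsets = np.array([0.0 for _ in pairs])
            free = {(min(k, l), max(k, l)) for (k, l) in structure.free_pairs}
            self.free_mask = np.array([pr in free for pr in pairs])
        else:
            missing = [pr for pr in pairs if pr not in offsets]
            if missing:
                raise ValueError(f"proportional offsets missing for pairs {missing}")
            self.n_params = 1
            self.names = ["tau"]
            self.base_offsets = np.array([offsets[pr] for pr in pairs])
            self.free_mask = np.zeros(len(pairs), dtype=bool)
        self.pairs = pairs

    def _sigma_unit(self, offs: np.ndarray) -> np.ndarray:
        """Sigma at tau^2 = 1 from per-pair offsets; offs is (C, n_pairs)."""
        C = offs.shape[0]
        n_t = self.p + 1
        F = np.zeros((C, n_t, n_t))
        for idx, (k, l) in enumerate(self.pairs):
            F[:, k, l] = F[:, l, k] = np.exp(offs[:, idx])
        diag = F[:, 0, 1:]
        Sig = 0.5 * (diag[:, :, None] + diag[:, None, :] - F[:, 1:, 1:])
        ii = np.arange(self.p)
        Sig[:, ii, ii] = diag
        return Sig

    def _params(self, x):
        if self.structure.vague:
            tau2 = (self.structure.upper * expit(x[:, 0])) ** 2
            m = x[:, 1]
        else:
            tau2 = np.exp(x[:, 0])
            m = None
        return tau2, m

    def init(self, rng, chains):
        if self.structure.vague:
            x0 = np.array([math.log(0.1 / (self.structure.upper - 0.1)), 0.0])
        else:
            x0 = np.array([0.0])
        return x0 + 0.1 * rng.standard_normal((chains, self.n_params))

    def sigma_and_logprior(self, x):
        tau2, m = self._params(x)
        offs = np.broadcast_to(self.base_offsets, (x.shape[0], len(self.pairs))).copy()
        if m is not None:
            offs[:, self.free_mask] += m[:, None]
        Sig = self._sigma_unit(offs) * tau2[:, None, None]
        if self.structure.vague:
            lp = _log_sigmoid(x[:, 0]) + _log_sigmoid(-x[:, 0])
            sd = self.structure.free_offset_sd
            lp = lp - 0.5 * (m / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)
        else:
            s = self.structure.s
            lp = -0.5 * (x[:, 0] / s) ** 2 - math.log(s) - 0.5 * math.log(2 * math.pi)
        # reject configurations whose Sigma loses positive semidefiniteness
        ev = np.linalg.eigvalsh(Sig)
        bad = ev[:, 0] < -1e-10 * np.maximum(1.0, ev[:, -1])
        lp = np.where(bad, -np.inf, lp)
        return Sig, lp

    def natural(self, x):
        tau2, m = self._params(x)
        out = {"tau": np.sqrt(tau2)}
        if m is not None:
            out["m"] = m
        return out

    def sample_prior(self, rng, n):
        if self.structure.vague:
            tau2 = rng.uniform(0.0, self.structure.upper, n) ** 2
            m = rng.normal(0.0, self.structure.free_offset_sd, n)
            offs = np.broadcast_to(self.base_offsets, (n, len(self.pairs))).copy()
            offs[:, self.free_mask] += m[:, None]
        else:
            tau2 = np.exp(rng.normal(0.0, self.structure.s, n))
            offs = np.broadcast_to(self.base_offsets, (n, len(self.pairs))).copy()
        return self._sigma_unit(offs) * tau2[:, None, None]

    def from_natural(self, values):
        tau = float(values["tau"])
        if tau <= 0:
            return None
        if self.structure.vague:
            if tau >= self.structure.upper:
                return None
            u = tau / self.structure.upper
            return np.array([math.log(u / (1.0 - u)), float(values.get("m", 0.0))])
        return np.array([2.0 * math.log(tau)])


class _ArmBasedBlock(_HetBlock):
    def __init__(self, structure: ArmBased, p: int):
        if structure.n_treatments != p + 1:
            raise ValueError(
                f"arm-based structure declares {structure.n_treatments} treatments "
                f"but the network has {p + 1}"
            )
        self.structure = structure
        self.p = p
        self.n_t = p + 1
        self.n_pairs = self.n_t * (self.n_t - 1) // 2
        self.n_params = self.n_t + self.n_pairs
        self.names = [f"tau_arm_{k}" for k in range(self.n_t)] + [
            f"cos_{i}{j}" for i, j in pair_order(self.n_t)
        ]

    def _split(self, x):
        return x[:, : self.n_t], x[:, self.n_t :]

    def _tau(self, xt):
        if self.structure.vague:
            return self.structure.upper * expit(xt)
        return np.exp(xt / 2.0)

    def init(self, rng, chains):
        if self.structure.vague:
            t0 = math.log(0.5 / (self.structure.upper - 0.5))
        else:
            t0 = self.structure.arm_prior.m
        x0 = np.concatenate([np.full(self.n_t, t0), np.zeros(self.n_pairs)])
        return x0 + 0.1 * rng.standard_normal((chains, self.n_params))

    def _sigma_from(self, tau, cos):
        L = build_spherical_cholesky(cos, self.n_t)
        R = np.einsum("cki,ckj->cij", L, L)
        V = R * tau[:, :, None] * tau[:, None, :]
        return V[:, 1:, 1:] - V[:, 1:, :1] - V[:, :1, 1:] + V[:, :1, :1]

    def sigma_and_logprior(self, x):
        xt, xc = self._split(x)
        tau = self._tau(xt)
        cos = expit(xc)
        Sigma = self._sigma_from(tau, cos)
        if self.structure.vague:
            lp = np.sum(_log_sigmoid(xt) + _log_sigmoid(-xt), axis=1)
        else:
            pr = self.structure.arm_prior
            lp = np.sum(
                -0.5 * ((xt - pr.m) / pr.s) ** 2 - math.log(pr.s) - 0.5 * math.log(2 * math.pi),
                axis=1,
            )
        ap = self.structure.angle_prior
        # Beta(a, b) density of c plus the logit-transform Jacobian c(1-c)
        lcos = _log_sigmoid(xc)
        l1m = _log_sigmoid(-xc)
        lp = lp + np.sum(ap.a * lcos + ap.b * l1m - betaln(ap.a, ap.b), axis=1)
        return Sigma, lp

    def natural(self, x):
        xt, xc = self._split(x)
        return {"tau_arm": self._tau(xt), "cos": expit(xc)}

    def sample_prior(self, rng, n):
        if self.structure.vague:
            tau = rng.uniform(0.0, self.structure.upper, (n, self.n_t))
        else:
            pr = self.structure.arm_prior
            tau = np.exp(rng.normal(pr.m, pr.s, (n, self.n_t)) / 2.0)
        ap = self.structure.angle_prior
        cos = rng.beta(ap.a, ap.b, (n, self.n_pairs))
        return self._sigma_from(tau, cos)

    def from_natural(self, values):
        tau = np.asarray(values["tau_arm"], dtype=float)
        cos = np.asarray(values["cos"], dtype=float)
        if tau.shape != (self.n_t,) or cos.shape != (self.n_pairs,):
            raise ValueError("tau_arm / cos have the wrong length")
        if np.any(cos <= 0) or np.any(cos >= 1) or np.any(tau <= 0):
            return None
        if self.structure.vague:
            if np.any(tau >= self.structure.upper):
                return None
            u = tau / self.structure.upper
            xt = np.log(u / (1.0 - u))
        else:
            xt = 2.0 * np.log(tau)
        return np.concatenate([xt, np.log(cos / (1.0 - cos))])


class _ScaledWishartBlock(_HetBlock):
    """Sigma = lambda M^{-1}, M ~ Wishart(S, t) parameterized by its Cholesky
    factor (log diagonal, free off-diagonal), plus log lambda."""

    def __init__(self, structure: ScaledWishart, p: int):
        spec = structure.spec
        if spec.p != p:
            raise ValueError(f"scaled-Wishart spec has p={spec.p} but network has p={p}")
        self.spec = spec
        self.p = p
        self.n_off = p * (p - 1) // 2
        self.n_params = p + self.n_off + 1
        self.names = (
            [f"logdiag_{i}" for i in range(p)]
            + [f"off_{i}{j}" for i, j in self._lower_pairs()]
            + ["log_lambda"]
        )
        self.S = spec.S
        # Wishart(S, t) normalizing constant in the rate convention
        sign, logdetS = np.linalg.slogdet(self.S)
        self.log_norm = 0.5 * spec.t * logdetS - 0.5 * spec.t * p * math.log(2.0) - multigammaln(
            spec.t / 2.0, p
        )

    def _lower_pairs(self):
        return [(i, j) for i in range(1, self.p) for j in range(i)]

    def _build_T(self, x):
        C = x.shape[0]
        T = np.zeros((C, self.p, self.p))
        ii = np.arange(self.p)
        T[:, ii, ii] = np.exp(x[:, : self.p])
        for idx, (i, j) in enumerate(self._lower_pairs()):
            T[:, i, j] = x[:, self.p + idx]
        return T

    def init(self, rng, chains):
        T0 = np.linalg.cholesky(self.spec.t * np.linalg.inv(self.S))
        x0 = np.concatenate(
            [
                np.log(np.diag(T0)),
                np.array([T0[i, j] for i, j in self._lower_pairs()]),
                [self.spec.m_lambda],
            ]
        )
        return x0 + 0.1 * rng.standard_normal((chains, self.n_params))

    def sigma_and_logprior(self, x):
        spec = self.spec
        T = self._build_T(x)
        M = T @ np.swapaxes(T, 1, 2)
        lam = np.exp(x[:, -1])
        Sigma = lam[:, None, None] * np.linalg.inv(M)
        logdiag = x[:, : self.p]  # log T_ii
        logdetM = 2.0 * np.sum(logdiag, axis=1)
        trSM = np.einsum("ij,cji->c", self.S, M)
        lw = self.log_norm + 0.5 * (spec.t - self.p - 1) * logdetM - 0.5 * trSM
        # Jacobian of M = T T' w.r.t. T, then of the log-diagonal transform
        powers = np.arange(self.p, 0, -1, dtype=float)
        jac = self.p * math.log(2.0) + np.sum((powers + 1.0) * logdiag, axis=1)
        ll = x[:, -1]
        lp_lam = (
            -0.5 * ((ll - spec.m_lambda) ** 2) / spec.s_lambda2
            - 0.5 * math.log(2 * math.pi * spec.s_lambda2)
        )
        return Sigma, lw + jac + lp_lam

    def natural(self, x):
        return {"lambda": np.exp(x[:, -1])}

    def sample_prior(self, rng, n):
        spec = self.spec
        # Bartlett decomposition of Wishart(S, t) in the rate convention:
        # M = A W A' with W standard Wishart and A = chol(S^{-1})
        A = np.linalg.cholesky(np.linalg.inv(self.S))
        p = self.p
        Tb = np.zeros((n, p, p))
        ii = np.arange(p)
        chis = np.array([rng.chisquare(spec.t - i, n) for i in range(p)]).T
        Tb[:, ii, ii] = np.sqrt(chis)
        for i in range(1, p):
            for j in range(i):
                Tb[:, i, j] = rng.standard_normal(n)
        F = A @ Tb
        M = F @ np.swapaxes(F, 1, 2)
        lam = np.exp(rng.normal(spec.m_lambda, math.sqrt(spec.s_lambda2), n))
        return lam[:, None, None] * np.linalg.inv(M)

    def from_natural(self, values):
        M = np.asarray(values["M"], dtype=float)
        lam = float(values["lambda"])
        if lam <= 0:
            return None
        try:
            T = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return None
        off = [T[i, j] for i, j in self._lower_pairs()]
        return np.concatenate([np.log(np.diag(T)), off, [math.log(lam)]])


def make_het_block(structure: HeterogeneityStructure, p: int) -> _HetBlock:
    if isinstance(structure, CommonVariance):
        return _CommonBlock(structure, p)
    if isinstance(structure, ProportionalVariances):
        return _ProportionalBlock(structure, p)
    if isinstance(structure, ArmBased):
        return _ArmBasedBlock(structure, p)
    if isinstance(structure, ScaledWishart):
        return _ScaledWishartBlock(structure, p)
    raise TypeError(f"unknown heterogeneity structure {structure!r}")


# ---------------------------------------------------------------------------
# Public density functions
# ---------------------------------------------------------------------------


def log_likelihood(ds: NetworkDataset, state: ParameterState) -> float:
    """Exact binomial log likelihood (including combinatorial constants)."""
    md = _ModelData(ds)
    mu = np.atleast_2d(state.mu)
    delta = np.atleast_2d(state.delta)
    ll = md.arm_loglik_by_study(mu, delta).sum()
    return float(ll + md.binom_const)


def log_prior(
    state: ParameterState, structure: HeterogeneityStructure, ds: NetworkDataset
) -> float:
    """Joint log prior at ``state`` (heterogeneity block in unconstrained
    coordinates, Jacobians included).

    Sums the vague N(0, 10^4) priors on mu_j and the basic parameters, the
    random-effect density evaluated through the sequential conditional
    decomposition of each study's contrast vector, and the structure-specific
    hyperprior.
    """
    md = _ModelData(ds)
    block = make_het_block(structure, ds.p)
    het = state.het
    if isinstance(het, Mapping):
        x1 = block.from_natural(het)
        if x1 is None:
            return -np.inf
        x = np.atleast_2d(x1)
    else:
        x = np.atleast_2d(het)
    Sigma, het_lp = block.sigma_and_logprior(x)
    if not np.isfinite(het_lp[0]):
        return -np.inf
    total = float(het_lp[0])
    for v in np.concatenate([state.mu, state.d]):
        total += -0.5 * v * v / _VAGUE_VAR - 0.5 * math.log(2 * math.pi * _VAGUE_VAR)
    d2 = np.atleast_2d(state.d)
    mean = md.delta_mean(d2)[0]
    S0 = Sigma[0]
    for j, (a, b) in enumerate(md.study_delta_slices):
        arms = [md.d_b[a]] + list(md.d_k[a:b])
        cov = trial_contrast_covariance(S0, arms, md.d_b[a])
        factors = conditional_factors(mean[a:b], cov)
        x_j = state.delta[a:b]
        for i, (mu_i, coef, v) in enumerate(factors):
            cond_mean = mu_i + coef @ (x_j[:i] - mean[a:b][:i])
            if v <= 0:
                if abs(x_j[i] - cond_mean) > 1e-9:
                    return -np.inf
                continue
            total += -0.5 * (x_j[i] - cond_mean) ** 2 / v - 0.5 * math.log(2 * math.pi * v)
    return total


# ---------------------------------------------------------------------------
# Posterior samples container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """Per-chain posterior draws with provenance.

    ``d`` has shape (chains, draws, p); ``het`` holds the heterogeneity block
    in unconstrained coordinates, shape (chains, draws, H).  Derived
    quantities (heterogeneity SDs, functional contrasts) are computed on
    demand.
    """

    d: np.ndarray
    het: np.ndarray
    structure: HeterogeneityStructure
    config: MCMCConfig
    treatment_labels: list[str]
    acceptance: dict[str, float] = field(default_factory=dict)
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.d.shape[2]

    @property
    def n_chains(self) -> int:
        return self.d.shape[0]

    @property
    def n_draws(self) -> int:
        return self.d.shape[1]

    def _block(self) -> _HetBlock:
        return make_het_block(self.structure, self.p)

    def d_pooled(self) -> np.ndarray:
        return self.d.reshape(-1, self.p)

    def contrast_samples(self, k: int, l: int) -> np.ndarray:
        """Draws of d_kl = d_0l - d_0k; shape (chains, draws)."""
        full = np.concatenate([np.zeros(self.d.shape[:2] + (1,)), self.d], axis=2)
        return full[..., l] - full[..., k]

    def sigma_samples(self, max_draws: int | None = None) -> np.ndarray:
        """Draws of Sigma reconstructed from the heterogeneity block."""
        block = self._block()
        x = self.het.reshape(-1, self.het.shape[2])
        if max_draws is not None and x.shape[0] > max_draws:
            step = x.shape[0] // max_draws
            x = x[::step]
        Sigma, _ = block.sigma_and_logprior(x)
        return Sigma

    def tau_samples(self, k: int, l: int, max_draws: int | None = None) -> np.ndarray:
        """Pooled draws of the heterogeneity SD tau_kl."""
        if k == l:
            raise ValueError("k and l must differ")
        if k > l:
            k, l = l, k
        Sigma = self.sigma_samples(max_draws)
        if k == 0:
            v = Sigma[:, l - 1, l - 1]
        else:
            v = Sigma[:, k - 1, k - 1] + Sigma[:, l - 1, l - 1] - 2 * Sigma[:, k - 1, l - 1]
        return np.sqrt(np.clip(v, 0.0, None))

    def het_natural(self) -> dict[str, np.ndarray]:
        block = self._block()
        x = self.het.reshape(-1, self.het.shape[2])
        return block.natural(x)

    def monitored(self) -> dict[str, np.ndarray]:
        """Pooled named scalar series for summarizing: basic parameters,
        every pairwise heterogeneity SD, and structure hyperparameters."""
        labels = self.treatment_labels
        out: dict[str, np.ndarray] = {}
        for k in range(1, self.p + 1):
            out[f"d_{labels[0]}{labels[k]}"] = self.d_pooled()[:, k - 1]
        Sigma = self.sigma_samples()
        n_t = self.p + 1
        for a in range(n_t):
            for b in range(a + 1, n_t):
                if a == 0:
                    v = Sigma[:, b - 1, b - 1]
                else:
                    v = Sigma[:, a - 1, a - 1] + Sigma[:, b - 1, b - 1] - 2 * Sigma[:, a - 1, b - 1]
                out[f"tau_{labels[a]}{labels[b]}"] = np.sqrt(np.clip(v, 0.0, None))
        for name, val in self.het_natural().items():
            if val.ndim == 1:
                out[name] = val
        return out

    def per_chain(self, name: str) -> np.ndarray:
        """A monitored series reshaped back to (chains, draws)."""
        series = self.monitored()[name]
        return series.reshape(self.n_chains, self.n_draws)

    def save(self, path) -> None:
        import json

        meta = {
            "treatment_labels": self.treatment_labels,
            "structure": repr(self.structure),
            "config": {
                "chains": self.config.chains,
                "iterations": self.config.iterations,
                "burn_in": self.config.burn_in,
                "thin": self.config.thin,
                "seed": self.config.seed,
            },
            "acceptance": self.acceptance,
        }
        np.savez_compressed(
            path, d=self.d, het=self.het, meta=np.array(json.dumps(meta)), **self.extras
        )


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


def _initial_state(md: _ModelData, block: _HetBlock, rng: np.random.Generator, C: int):
    r, n = md.arm_r, md.arm_n
    logit_emp = np.log((r + 0.5) / (n - r + 0.5))
    mu0 = np.array([logit_emp[md.arm_starts[j]] for j in range(md.J)])
    mu = mu0 + 0.2 * rng.standard_normal((C, md.J))
    nb_idx = np.where(md.nb_mask)[0]
    delta0 = logit_emp[nb_idx] - mu0[md.arm_study[nb_idx]]
    delta = delta0 + 0.2 * rng.standard_normal((C, md.D))
    d = 0.1 * rng.standard_normal((C, md.p))
    het = block.init(rng, C)
    return mu, delta, d, het


def sample_posterior(
    ds: NetworkDataset,
    structure: HeterogeneityStructure,
    cfg: MCMCConfig = MCMCConfig(),
    likelihood: bool = True,
    store_arm_params: bool = False,
    rhat_threshold: float = 1.01,
    check_convergence: bool = True,
) -> PosteriorSamples:
    """Draw from the joint posterior of the NMA model under ``structure``.

    Setting ``likelihood=False`` samples from the prior instead (used to
    verify the implied heterogeneity priors against forward simulation).
    Non-convergence by split R-hat on the basic parameters is reported via a
    warning, never silently ignored.
    """
    if not ds.is_connected():
        raise ValueError("refusing to fit a disconnected network")
    md = _ModelData(ds)
    block = make_het_block(structure, ds.p)
    rng = np.random.default_rng(cfg.seed)
    C = cfg.chains
    mu, delta, d, het = _initial_state(md, block, rng, C)

    Sigma, het_lp = block.sigma_and_logprior(het)
    if not np.all(np.isfinite(het_lp)):
        raise RuntimeError("heterogeneity block initialized outside its support")
    mean = md.delta_mean(d)
    if likelihood:
        cur_ll = md.arm_loglik_by_study(mu, delta)
    else:
        cur_ll = np.zeros((C, md.J))
    cur_re = md.re_logpdf_by_study(delta, mean, Sigma)

    # adaptive step sizes (log scale) per chain and block component
    ls_mu = np.full((C, md.J), math.log(0.5))
    ls_delta = np.full((C, md.J), math.log(0.5))
    ls_het = np.full((C, block.n_params), math.log(0.3))
    acc_mu = np.zeros((C, md.J))
    acc_delta = np.zeros((C, md.J))
    acc_het = np.zeros((C, block.n_params))
    target = 0.44

    n_keep = cfg.n_draws
    d_out = np.empty((C, n_keep, md.p))
    het_out = np.empty((C, n_keep, block.n_params))
    mu_out = np.empty((C, n_keep, md.J)) if store_arm_params else None
    delta_out = np.empty((C, n_keep, md.D)) if store_arm_params else None

    delta_slices = md.study_delta_slices
    study_of_delta = md.d_study
    X = md.X
    prior_prec = np.eye(md.p) / _VAGUE_VAR
    two_arm = md.two_arm
    two_idx = md.two_arm_delta

    kept = 0
    for it in range(cfg.iterations):
        adapting = it < cfg.burn_in

        # --- mu update (per-study, all chains) ----------------------------
        if likelihood:
            prop_mu = mu + np.exp(ls_mu) * rng.standard_normal((C, md.J))
            prop_ll = md.arm_loglik_by_study(prop_mu, delta)
            dprior = (mu**2 - prop_mu**2) / (2 * _VAGUE_VAR)
            log_acc = prop_ll - cur_ll + dprior
            accept = np.log(rng.random((C, md.J))) < log_acc
            mu = np.where(accept, prop_mu, mu)
            cur_ll = np.where(accept, prop_ll, cur_ll)
            acc_mu += accept

        # --- delta update (per-study joint proposal) ----------------------
        step_d = np.exp(ls_delta)[:, study_of_delta]
        prop_delta = delta + step_d * rng.standard_normal((C, md.D))
        if likelihood:
            prop_ll = md.arm_loglik_by_study(mu, prop_delta)
        else:
            prop_ll = cur_ll
        prop_re = md.re_logpdf_by_study(prop_delta, mean, Sigma)
        log_acc = (prop_ll - cur_ll) + (prop_re - cur_re)
        accept = np.log(rng.random((C, md.J))) < log_acc
        acc_delta += accept
        accept_d = accept[:, study_of_delta]
        delta = np.where(accept_d, prop_delta, delta)
        cur_ll = np.where(accept, prop_ll, cur_ll)
        cur_re = np.where(accept, prop_re, cur_re)

        # --- d update: exact Gibbs ----------------------------------------
        Lam = np.broadcast_to(prior_prec, (C, md.p, md.p)).copy()
        bvec = np.zeros((C, md.p))
        if two_arm.size:
            var = md._pair_variance(Sigma, md.d_k[two_idx], md.d_b[two_idx])
            w = 1.0 / var
            X2 = X[two_idx]
            Lam += np.einsum("cd,di,dj->cij", w, X2, X2)
            bvec += np.einsum("cd,cd,di->ci", w, delta[:, two_idx], X2)
        for j, a, b in md.multi_arm:
            cov = md._trial_cov(Sigma, a, b)
            P = np.linalg.inv(cov)
            Xj = X[a:b]
            Lam += np.einsum("cab,ai,bj->cij", P, Xj, Xj)
            bvec += np.einsum("ai,cab,cb->ci", Xj, P, delta[:, a:b])
        cov_d = np.linalg.inv(Lam)
        cov_d = 0.5 * (cov_d + np.swapaxes(cov_d, 1, 2))
        mean_d = np.einsum("cij,cj->ci", cov_d, bvec)
        Lc = np.linalg.cholesky(cov_d)
        d = mean_d + np.einsum("cij,cj->ci", Lc, rng.standard_normal((C, md.p)))
        mean = md.delta_mean(d)
        cur_re = md.re_logpdf_by_study(delta, mean, Sigma)

        # --- heterogeneity block: component-wise MH -----------------------
        for h in range(block.n_params):
            prop_het = het.copy()
            prop_het[:, h] += np.exp(ls_het[:, h]) * rng.standard_normal(C)
            prop_Sigma, prop_lp = block.sigma_and_logprior(prop_het)
            with np.errstate(invalid="ignore"):
                prop_re = md.re_logpdf_by_study(delta, mean, prop_Sigma)
                log_acc = (prop_lp - het_lp) + np.sum(prop_re - cur_re, axis=1)
            log_acc = np.where(np.isfinite(prop_lp), log_acc, -np.inf)
            accept = np.log(rng.random(C)) < log_acc
            acc_het[:, h] += accept
            if accept.any():
                het[accept, h] = prop_het[accept, h]
                Sigma[accept] = prop_Sigma[accept]
                het_lp = np.where(accept, prop_lp, het_lp)
                cur_re[accept] = prop_re[accept]

        # --- adaptation during burn-in ------------------------------------
        if adapting and (it + 1) % cfg.adapt_window == 0:
            w = cfg.adapt_window
            gamma = min(0.5, 5.0 / math.sqrt(it + 1.0))
            ls_mu += gamma * (acc_mu / w - target)
            ls_delta += gamma * (acc_delta / w - target)
            ls_het += gamma * (acc_het / w - target)
            np.clip(ls_mu, -8, 3, out=ls_mu)
            np.clip(ls_delta, -8, 3, out=ls_delta)
            np.clip(ls_het, -8, 3, out=ls_het)
            acc_mu[:] = 0
            acc_delta[:] = 0
            acc_het[:] = 0

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
            d_out[:, kept] = d
            het_out[:, kept] = het
            if store_arm_params:
                mu_out[:, kept] = mu
                delta_out[:, kept] = delta
            kept += 1

    post_iters = cfg.iterations - cfg.burn_in
    acceptance = {
        "mu": float(np.mean(acc_mu)) / max(post_iters, 1),
        "delta": float(np.mean(acc_delta)) / max(post_iters, 1),
        "het": float(np.mean(acc_het)) / max(post_iters, 1),
    }
    extras = {}
    if store_arm_params:
        extras = {"mu": mu_out, "delta": delta_out}
    samples = PosteriorSamples(
        d=d_out,
        het=het_out,
        structure=structure,
        config=cfg,
        treatment_labels=[t.label for t in ds.treatments],
        acceptance=acceptance,
        extras=extras,
    )
    if check_convergence and likelihood and C >= 2 and n_keep >= 4:
        from .summary import split_rhat

        rhats = [split_rhat(samples.d[:, :, k]) for k in range(md.p)]
        worst = max(rhats)
        if worst > rhat_threshold:
            warnings.warn(
                f"split R-hat up to {worst:.3f} on the basic parameters exceeds "
                f"{rhat_threshold}; consider more iterations",
                RuntimeWarning,
                stacklevel=2,
            )
    return samples
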