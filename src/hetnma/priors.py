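"""Data-based heterogeneity priors and moment-matching machinery.

Catalogued priors
-----------------
Empirical predictive distributions for between-study heterogeneity variances,
estimated from large collections of published binary-outcome meta-analyses,
are shipped as plain-text catalogs:

* log-normal priors for the comparison-level variances tau_kl^2, indexed by
  outcome type, together with the matched arm-level priors for the tau_k^2;
* Beta priors for the cosine angles of the spherical correlation
  parameterization, indexed by network size;
* comparison-type-specific log-normal priors for two worked contexts
  (smoking-cessation counselling and localised prostate cancer), extensible
  through a user-supplied catalog file.

Moment matching
---------------
The arm-based model expresses each comparison-level variance as

    tau_kl^2 = tau_k^2 + tau_l^2 - 2 rho_kl tau_k tau_l,

with tau_k^2, tau_l^2 iid log-normal(m, s^2) and rho_kl independent of them
with mean ``m_rho`` and variance ``s_rho^2``.  ``match_arm_prior`` solves for
(m, s) so that the implied prior for tau_kl^2 has the same mean and variance
as a target log-normal(m_D, s_D^2).  The exact first two moments of the
implied prior (used by the solver and checked against a Monte-Carlo oracle in
the tests) are

    E[tau_kl^2]   = 2 e^m e^{s^2/4} (e^{s^2/4} - m_rho)
    Var[tau_kl^2] = 2 e^{2m+s^2}(e^{s^2}-1)
                    + 4[(s_rho^2+m_rho^2) e^{2m+s^2} - m_rho^2 e^{2m+s^2/2}]
                    - 8 m_rho e^{2m+3s^2/4}(e^{s^2/2}-1),

which follow from the log-normal moment formula E[X^q] = e^{qm+q^2 s^2/2} and
the independence of rho_kl from the arm variances.

For the scaled inverse-Wishart prior, Sigma^{-1} = M/lambda with
M ~ Wishart(S, t) and log(lambda) ~ N(m_lambda, s_lambda^2), the diagonal
marginals satisfy Sigma_kk ~ lambda * IG((t-p+1)/2, S_kk/2), so matching
E[log Sigma_kk] = m_D and Var[log Sigma_kk] = s_D^2 gives the closed form

    m_lambda   = m_D - log(S_kk/2) + digamma((t-p+1)/2)
    s_lambda^2 = s_D^2 - trigamma((t-p+1)/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, polygamma

from .network import ComparisonType

__all__ = [
    "LogNormalPrior",
    "BetaPrior",
    "CorrelationMoments",
    "OutcomeType",
    "ScaledWishartSpec",
    "ProportionalPriorSpec",
    "predictive_prior",
    "arm_prior",
    "angle_prior",
    "comparison_prior",
    "implied_contrast_moments",
    "match_arm_prior",
    "match_scaled_wishart",
    "proportional_spec",
]


@dataclass(frozen=True)
class LogNormalPrior:
    """log(tau^2) ~ N(m, s^2): a log-normal prior for a variance.

    ``m`` and ``s`` live on the log variance scale (log odds-ratio^2 units).
    """

    m: float
    s: float

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("log-normal prior needs s > 0")

    @property
    def median_variance(self) -> float:
        return math.exp(self.m)

    @property
    def median_sd(self) -> float:
        return math.exp(self.m / 2)

    @property
    def mean_variance(self) -> float:
        return math.exp(self.m + self.s**2 / 2)

    @property
    def var_variance(self) -> float:
        return math.exp(2 * self.m + self.s**2) * (math.exp(self.s**2) - 1)

    def quantile_variance(self, q: float) -> float:
        return math.exp(self.m + self.s * stats.norm.ppf(q))

    def sd_interval(self, level: float = 0.95) -> tuple[float, float]:
        half = (1 - level) / 2
        return (
            math.sqrt(self.quantile_variance(half)),
            math.sqrt(self.quantile_variance(1 - half)),
        )


@dataclass(frozen=True)
class BetaPrior:
    """Beta(a, b) prior, used for the cosines of the spherical angles."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta prior needs a, b > 0")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def variance(self) -> float:
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1))


@dataclass(frozen=True)
class CorrelationMoments:
    """First two moments of the prior for an arm-effect correlation rho_kl.

    The defaults (mean 0.5, variance 0.07) approximate a Uniform(0, 1)
    correlation conditional on positive semidefiniteness, and are the moments
    under which the bundled arm-level priors were matched.
    """

    mean: float = 0.5
    variance: float = 0.07

    def __post_init__(self) -> None:
        if not 0 <= self.mean <= 1:
            raise ValueError("correlation mean must be in [0, 1]")
        if self.variance < 0:
            raise ValueError("correlation variance must be >= 0")


class OutcomeType(str, Enum):
    """Outcome categories of the bundled predictive-distribution catalog."""

    ALL_CAUSE_MORTALITY = "all_cause_mortality"
    OBSTETRIC_OUTCOMES = "obstetric_outcomes"
    CAUSE_SPECIFIC_MORTALITY_MAJOR_MORBIDITY = "cause_specific_mortality_major_morbidity"
    RESOURCE_USE_HOSPITAL_STAY_PROCESS = "resource_use_hospital_stay_process"
    SURGICAL_DEVICE_SUCCESS_FAILURE = "surgical_device_success_failure"
    WITHDRAWALS_DROPOUTS = "withdrawals_dropouts"
    INTERNAL_EXTERNAL_STRUCTURE = "internal_external_structure"
    GENERAL_PHYSICAL_HEALTH = "general_physical_health"
    ADVERSE_EVENTS = "adverse_events"
    INFECTION_NEW_DISEASE = "infection_new_disease"
    SIGNS_SYMPTOMS_CONDITION = "signs_symptoms_condition"
    PAIN = "pain"
    QUALITY_OF_LIFE = "quality_of_life"
    MENTAL_HEALTH = "mental_health"
    BIOLOGICAL_MARKERS = "biological_markers"
    SUBJECTIVE_OUTCOMES = "subjective_outcomes"


@dataclass(frozen=True)
class ScaledWishartSpec:
    """Hyperparameters of the scaled inverse-Wishart prior for Sigma.

    Sigma^{-1} = M / lambda with M ~ Wishart(S, t) in the convention for which
    the diagonal marginals (at lambda = 1) are Sigma_kk ~ IG((t-p+1)/2, S_kk/2),
    and log(lambda) ~ N(m_lambda, s_lambda^2).
    """

    p: int
    t: int
    m_lambda: float
    s_lambda2: float
    s_kk: float = 1.0
    s_kl: float = 0.5

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("dimension p must be >= 1")
        if self.t < self.p:
            raise ValueError("degrees of freedom t must be >= p")
        if self.s_lambda2 <= 0:
            raise ValueError("s_lambda2 must be > 0")

    @property
    def S(self) -> np.ndarray:
        S = np.full((self.p, self.p), self.s_kl)
        np.fill_diagonal(S, self.s_kk)
        return S


@dataclass(frozen=True)
class ProportionalPriorSpec:
    """Offsets and common log-scale SD for the proportional-variances prior."""

    offsets: dict[tuple[int, int], float]
    s: float


def _load_catalog(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("hetnma").joinpath("data", name)) as p:
        return pd.read_csv(p)


_OUTCOME_CATALOG: pd.DataFrame | None = None
_ANGLE_CATALOG: pd.DataFrame | None = None
_COMPARISON_CATALOG: pd.DataFrame | None = None


def _outcome_catalog() -> pd.DataFrame:
    global _OUTCOME_CATALOG
    if _OUTCOME_CATALOG is None:
        _OUTCOME_CATALOG = _load_catalog("outcome_priors.csv").set_index("outcome")
    return _OUTCOME_CATALOG


def _angle_catalog() -> pd.DataFrame:
    global _ANGLE_CATALOG
    if _ANGLE_CATALOG is None:
        _ANGLE_CATALOG = _load_catalog("angle_priors.csv").set_index("n_treatments")
    return _ANGLE_CATALOG


def _comparison_catalog() -> pd.DataFrame:
    global _COMPARISON_CATALOG
    if _COMPARISON_CATALOG is None:
        _COMPARISON_CATALOG = _load_catalog("comparison_priors.csv")
    return _COMPARISON_CATALOG


def predictive_prior(outcome: OutcomeType | str) -> LogNormalPrior:
    """Catalogued predictive prior for a comparison-level variance tau_kl^2."""
    key = OutcomeType(outcome).value
    row = _outcome_catalog().loc[key]
    return LogNormalPrior(float(row["m_pred"]), float(row["s_pred"]))


def arm_prior(outcome: OutcomeType | str) -> LogNormalPrior:
    """Catalogued moment-matched prior for an arm-level variance tau_k^2."""
    key = OutcomeType(outcome).value
    row = _outcome_catalog().loc[key]
    return LogNormalPrior(float(row["m_arm"]), float(row["s_arm"]))


def angle_prior(n_treatments: int) -> BetaPrior:
    """Catalogued Beta prior for the spherical-angle cosines, by network size."""
    cat = _angle_catalog()
    if n_treatments not in cat.index:
        raise ValueError(
            f"no catalogued angle prior for {n_treatments} treatments "
            f"(catalog covers {cat.index.min()}..{cat.index.max()}); "
            "supply a custom BetaPrior"
        )
    row = cat.loc[n_treatments]
    return BetaPrior(float(row["a"]), float(row["b"]))


def comparison_prior(
    context: str,
    ctype: ComparisonType | str,
    catalog: str | Path | pd.DataFrame | None = None,
) -> LogNormalPrior:
    """Comparison-type-specific prior for tau_kl^2 in a named outcome context.

    The bundled catalog covers the smoking-cessation (``smoking``) and
    prostate-cancer all-cause-mortality (``prostate``) contexts; further rows
    can be supplied via ``catalog`` (a CSV path or DataFrame with columns
    ``context, comparison_type, m, s``).  A missing entry raises; nothing is
    silently substituted.
    """
    ctype = ComparisonType(ctype)
    if catalog is None:
        cat = _comparison_catalog()
    elif isinstance(catalog, pd.DataFrame):
        cat = catalog
    else:
        cat = pd.read_csv(catalog)
    hit = cat[(cat["context"] == context) & (cat["comparison_type"] == ctype.value)]
    if len(hit) == 0:
        raise KeyError(f"no catalogued prior for context {context!r}, type {ctype.value!r}")
    row = hit.iloc[0]
    return LogNormalPrior(float(row["m"]), float(row["s"]))


def implied_contrast_moments(
    m: float, s: float, rho: CorrelationMoments = CorrelationMoments()
) -> tuple[float, float]:
    """Mean and variance of tau_kl^2 = tau_k^2 + tau_l^2 - 2 rho tau_k tau_l.

    tau_k^2, tau_l^2 are iid log-normal(m, s^2), independent of rho which has
    the given first two moments.  Exact closed forms (see module docstring).
    """
    mr, sr2 = rho.mean, rho.variance
    s2 = s * s
    mean = 2.0 * math.exp(m + s2 / 4) * (math.exp(s2 / 4) - mr)
    var_sum = 2.0 * math.exp(2 * m + s2) * (math.exp(s2) - 1.0)
    var_cross = 4.0 * ((sr2 + mr * mr) * math.exp(2 * m + s2) - mr * mr * math.exp(2 * m + s2 / 2))
    cov_term = 8.0 * mr * math.exp(2 * m + 0.75 * s2) * (math.exp(s2 / 2) - 1.0)
    return mean, var_sum + var_cross - cov_term


def match_arm_prior(
    target: LogNormalPrior,
    rho: CorrelationMoments = CorrelationMoments(),
    tol: float = 1e-10,
    max_restarts: int = 5,
) -> LogNormalPrior:
    """Solve for the arm-level log-normal prior implying a target contrast prior.

    Finds (m_A, s_A) such that the implied prior for tau_kl^2 has the same mean
    and variance as ``target``.  The solve is performed in unconstrained
    (m, log s) coordinates, starting from (m_D - 0.5, log s_D), with jittered
    restarts on failure; convergence requires both relative moment residuals
    below ``tol``.
    """
    tm, tv = target.mean_variance, target.var_variance

    def resid(x: np.ndarray) -> list[float]:
        mean, var = implied_contrast_moments(x[0], math.exp(x[1]), rho)
        return [mean / tm - 1.0, var / tv - 1.0]

    rng = np.random.default_rng(0)
    x0 = np.array([target.m - 0.5, math.log(target.s)])
    last = None
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.3, 2)
        sol = optimize.root(resid, start, method="hybr", tol=1e-13)
        last = sol
        if max(abs(r) for r in resid(sol.x)) < tol:
            return LogNormalPrior(float(sol.x[0]), float(math.exp(sol.x[1])))
    res = resid(last.x)
    raise RuntimeError(
        f"moment matching failed to converge after {max_restarts} restarts; residuals {res}"
    )


def match_scaled_wishart(target: LogNormalPrior, p: int, t: int | None = None) -> ScaledWishartSpec:
    """Match a scaled inverse-Wishart prior to a target log-normal for tau_kl^2.

    Uses t = p + 1 (the smallest feasible degrees of freedom, minimizing the
    borrowing of heterogeneity information across comparisons), S_kk = 1 and
    S_kl = 1/2, so that reference and non-reference contrast variances share
    one implied distribution.  Requires s_D^2 > trigamma((t-p+1)/2); with
    t = p + 1 the bound is pi^2/6, satisfied by the whole bundled catalog.
    """
    if t is None:
        t = p + 1
    a = (t - p + 1) / 2
    trig = float(polygamma(1, a))
    s_lambda2 = target.s**2 - trig
    if s_lambda2 <= 0:
        raise ValueError(
            f"target s_D^2 = {target.s**2:.4f} <= trigamma({a}) = {trig:.4f}: "
            f"cannot match the log-variance spread with t = {t} "
            "(with t = p the bound trigamma(1/2) exceeds every catalogued s_D^2; "
            "t = p + 1 requires s_D^2 > pi^2/6)"
        )
    s_kk = 1.0
    m_lambda = target.m - math.log(s_kk / 2) + float(digamma(a))
    return ScaledWishartSpec(p=p, t=t, m_lambda=m_lambda, s_lambda2=s_lambda2, s_kk=s_kk, s_kl=s_kk / 2)


def proportional_spec(
    contrast_types: Mapping[tuple[int, int], ComparisonType],
    type_counts: Mapping[ComparisonType, int],
    context: str,
    catalog: str | Path | pd.DataFrame | None = None,
) -> ProportionalPriorSpec:
    """Build the proportional-variances prior from comparison-type priors.

    Each contrast's offset ``m_kl`` is the log-variance mean of its
    comparison type's catalogued prior; the common log-scale standard
    deviation ``s`` is the study-count-weighted average of the types' standard
    deviations.
    """
    priors = {}
    for ct in set(contrast_types.values()):
        priors[ct] = comparison_prior(context, ct, catalog)
    offsets: dict[tuple[int, int], float] = {}
    for (k, l), ct in contrast_types.items():
        key = (min(k, l), max(k, l))
        offsets[key] = priors[ct].m
    total = sum(type_counts.values())
    if total <= 0:
        raise ValueError("type_counts must contain at least one study")
    for ct in type_counts:
        if ComparisonType(ct) not in priors:
            priors[ComparisonType(ct)] = comparison_prior(context, ct, catalog)
    s = sum(priors[ComparisonType(ct)].s * n for ct, n in type_counts.items()) / total
    return ProportionalPriorSpec(offsets=offsets, s=float(s))
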