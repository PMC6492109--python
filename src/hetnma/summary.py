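"""Posterior summaries, convergence diagnostics, and prior characterization.

``summarize`` produces posterior medians with equal-tailed credible intervals
(type-7 / linearly interpolated quantiles, matching how 2-decimal published
intervals are normally computed).  ``convergence`` reports split-chain
potential scale reduction (split R-hat) and a crude effective sample size.
``prior_monte_carlo`` forward-samples the heterogeneity block of a structure
only, characterizing the implied priors for the comparison-specific
heterogeneity SDs tau_kl and the prior correlations between the log
heterogeneity variances of different comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariance import HeterogeneityStructure
from .mcmc import PosteriorSamples, make_het_block

__all__ = [
    "SummaryTable",
    "PriorCharacterization",
    "summarize",
    "convergence",
    "split_rhat",
    "effective_sample_size",
    "prior_monte_carlo",
]


@dataclass
class SummaryTable:
    """Posterior medians and equal-tailed intervals, one row per quantity."""

    table: pd.DataFrame
    level: float

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def round(self, decimals: int = 2) -> pd.DataFrame:
        return self.table.round(decimals)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.round(2).to_string()


def _quantile_summary(draws: np.ndarray, level: float) -> tuple[float, float, float]:
    half = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(draws, [half, 0.5, 1.0 - half])
    return float(med), float(lo), float(hi)


def summarize(samples: PosteriorSamples | dict[str, np.ndarray], level: float = 0.95) -> SummaryTable:
    """Pooled-chain posterior median and equal-tailed interval per quantity.

    Accepts either a :class:`PosteriorSamples` (summarizing every monitored
    quantity: basic parameters, all pairwise heterogeneity SDs, structure
    hyperparameters) or a plain mapping of named draw arrays.
    """
    if isinstance(samples, PosteriorSamples):
        series = samples.monitored()
    else:
        series = {k: np.asarray(v).ravel() for k, v in samples.items()}
    rows = {}
    for name, draws in series.items():
        if draws.size == 0:
            raise ValueError(f"no draws for quantity {name!r}")
        med, lo, hi = _quantile_summary(draws, level)
        rows[name] = {"median": med, "lower": lo, "upper": hi}
    table = pd.DataFrame.from_dict(rows, orient="index")
    return SummaryTable(table=table, level=level)


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one scalar quantity.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in half,
    and the classic between/within variance ratio is computed over the 2*m
    half-chains.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("expected (chains, draws)")
    n = x.shape[1] // 2
    if n < 2:
        return float("nan")
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W <= 0:
        return 1.0 if B <= 0 else float("inf")
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def effective_sample_size(chains: np.ndarray, max_lag: int | None = None) -> float:
    """Effective sample size via initial-positive-sequence autocorrelation."""
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    if n < 4:
        return float("nan")
    if max_lag is None:
        max_lag = min(n - 2, 1000)
    centered = x - x.mean(axis=1, keepdims=True)
    var = np.mean(centered**2)
    if var == 0:
        return float(m * n)
    rho_sum = 0.0
    for lag in range(1, max_lag):
        rho = np.mean(centered[:, :-lag] * centered[:, lag:]) / var
        if rho < 0.05:
            break
        rho_sum += rho
    return float(m * n / (1.0 + 2.0 * rho_sum))


def convergence(samples: PosteriorSamples, rhat_threshold: float = 1.01) -> pd.DataFrame:
    """Split R-hat and effective sample size for every monitored quantity.

    With a single chain, R-hat is undefined and reported as NaN.
    """
    names = list(samples.monitored().keys())
    rows = {}
    for name in names:
        per_chain = samples.per_chain(name)
        rhat = split_rhat(per_chain) if samples.n_chains >= 2 else float("nan")
        ess = effective_sample_size(per_chain)
        rows[name] = {
            "rhat": rhat,
            "ess": ess,
            "converged": bool(rhat <= rhat_threshold) if np.isfinite(rhat) else False,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class PriorCharacterization:
    """Implied-prior summaries for the heterogeneity block of a structure.

    ``tau_quantiles`` indexes per-comparison quantiles of the implied prior
    for tau_kl (rows = comparisons, columns = probabilities); ``pooled``
    holds the same quantiles for all comparisons pooled.  ``log_var_corr`` is
    the Pearson correlation matrix of log tau_kl^2 across comparisons;
    ``shared_corr`` / ``disjoint_corr`` average its entries over comparison
    pairs sharing exactly one treatment / none.
    """

    pairs: list[tuple[int, int]]
    tau_quantiles: pd.DataFrame
    pooled: pd.Series
    log_var_corr: pd.DataFrame
    shared_corr: float
    disjoint_corr: float
    n_draws: int


def prior_monte_carlo(
    structure: HeterogeneityStructure,
    n_treatments: int,
    n_draws: int = 1_000_000,
    seed: int = 0,
    probs: tuple[float, ...] = (0.025, 0.25, 0.5, 0.75, 0.975),
) -> PriorCharacterization:
    """Forward-sample the heterogeneity block and characterize implied priors.

    Draws ``n_draws`` covariance matrices Sigma from the structure's prior,
    forms every comparison variance tau_kl^2 (reference comparisons from the
    diagonal, the rest via Sigma_kk + Sigma_ll - 2 Sigma_kl), and reports
    empirical quantiles of tau_kl plus the correlation matrix of the log
    variances.  Correlations are the mechanism behind the published
    shared-treatment / disjoint-comparison prior correlation figures.
    """
    p = n_treatments - 1
    block = make_het_block(structure, p)
    rng = np.random.default_rng(seed)
    Sigma = block.sample_prior(rng, n_draws)
    pairs = [(k, l) for k in range(n_treatments) for l in range(k + 1, n_treatments)]
    tau2 = np.empty((n_draws, len(pairs)))
    for idx, (k, l) in enumerate(pairs):
        if k == 0:
            tau2[:, idx] = Sigma[:, l - 1, l - 1]
        else:
            tau2[:, idx] = (
                Sigma[:, k - 1, k - 1] + Sigma[:, l - 1, l - 1] - 2 * Sigma[:, k - 1, l - 1]
            )
    tau = np.sqrt(np.clip(tau2, 0.0, None))
    names = [f"tau_{k}{l}" for k, l in pairs]
    q = np.quantile(tau, probs, axis=0).T
    tau_q = pd.DataFrame(q, index=names, columns=[str(pr) for pr in probs])
    pooled = pd.Series(np.quantile(tau.ravel(), probs), index=[str(pr) for pr in probs])

    log_var = np.log(np.clip(tau2, 1e-300, None))
    corr = np.corrcoef(log_var.T)
    corr_df = pd.DataFrame(corr, index=names, columns=names)
    shared, disjoint = [], []
    for i, j in itertools.combinations(range(len(pairs)), 2):
        overlap = len(set(pairs[i]) & set(pairs[j]))
        if overlap == 1:
            shared.append(corr[i, j])
        elif overlap == 0:
            disjoint.append(corr[i, j])
    return PriorCharacterization(
        pairs=pairs,
        tau_quantiles=tau_q,
        pooled=pooled,
        log_var_corr=corr_df,
        shared_corr=float(np.mean(shared)) if shared else float("nan"),
        disjoint_corr=float(np.mean(disjoint)) if disjoint else float("nan"),
        n_draws=n_draws,
    )
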