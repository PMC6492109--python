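"""Bundled example networks and a generator with the model's exact structure.

``prostate_fixture`` loads the 17-trial, 8-treatment localised-prostate-cancer
network (all-cause mortality, all two-arm trials).  ``smoking_design``
describes the 24-trial smoking-cessation-counselling network skeleton
(treatments and per-comparison trial counts only; the outcome counts are not
bundled and must be loaded by the user).

``simulate_network`` draws arm-level binomial data from the generative model:
per-study baseline log-odds mu_j, a trial contrast vector drawn from the
restriction of N(d, Sigma) to the trial's arms, and binomial arm counts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .covariance import ContrastCovariance, trial_contrast_covariance
from .network import (
    ArmRecord,
    NetworkDataset,
    Study,
    Treatment,
    TreatmentClass,
    read_network_table,
)

__all__ = [
    "SimulationDesign",
    "SmokingDesign",
    "prostate_fixture",
    "smoking_design",
    "simulate_network",
    "fixture_checksums",
]


def _data_path(name: str):
    return resources.files("hetnma").joinpath("data", name)


def fixture_checksums() -> dict[str, str]:
    """SHA-256 of every bundled data file (pinned by the test suite)."""
    out = {}
    data_dir = resources.files("hetnma").joinpath("data")
    for item in sorted(data_dir.iterdir(), key=lambda p: p.name):
        if item.name.endswith(".csv"):
            out[item.name] = hashlib.sha256(item.read_bytes()).hexdigest()
    return out


def prostate_fixture() -> NetworkDataset:
    """The 17-trial network of eight treatments for localised prostate cancer.

    Outcome: all-cause mortality.  Treatments: observational management (A,
    the reference, control type), prostatectomy (B), conventional
    radiotherapy (C), conventional radiotherapy hypofractionated (D),
    conformal low-dose radiotherapy (E), conformal high-dose radiotherapy (F),
    conformal low-dose radiotherapy hypofractionated (G), cryotherapy (H); B-H
    are treated as nonpharmacological for prior selection.
    """
    with resources.as_file(_data_path("prostate_arms.csv")) as arms:
        with resources.as_file(_data_path("prostate_treatments.csv")) as trts:
            return read_network_table(arms, treatments=trts, reference="A")


@dataclass(frozen=True)
class SmokingDesign:
    """Skeleton of the smoking-cessation counselling network (no outcomes)."""

    treatments: tuple[Treatment, ...]
    comparison_counts: dict[tuple[str, str], int]
    n_trials: int
    n_three_arm: int

    def total_pairwise_counts(self) -> int:
        return sum(self.comparison_counts.values())


def smoking_design() -> SmokingDesign:
    """Design metadata for the 24-trial smoking-cessation network.

    Treatments: no intervention (A, control), self-help (B), individual
    counselling (C), group counselling (D); all active treatments are
    nonpharmacological.  The per-comparison direct-evidence trial counts are
    recorded as published; the outcome data themselves are not bundled.
    """
    treatments = (
        Treatment(0, "A", TreatmentClass.CONTROL),
        Treatment(1, "B", TreatmentClass.NONPHARMACOLOGICAL),
        Treatment(2, "C", TreatmentClass.NONPHARMACOLOGICAL),
        Treatment(3, "D", TreatmentClass.NONPHARMACOLOGICAL),
    )
    counts = {
        ("A", "B"): 3,
        ("A", "C"): 15,
        ("A", "D"): 2,
        ("B", "C"): 2,
        ("B", "D"): 2,
        ("C", "D"): 4,
    }
    return SmokingDesign(treatments=treatments, comparison_counts=counts, n_trials=24, n_three_arm=2)


@dataclass
class SimulationDesign:
    """Everything needed to simulate a network of binomial trials.

    ``study_arms`` lists, per study, the treatment ids in that study.  ``d``
    are the true basic parameters (contrasts with treatment 0) and ``Sigma``
    the true contrast covariance.  Baseline log-odds are drawn
    N(mu_mean, mu_sd^2); the default centre corresponds to a 30% baseline
    event probability, a dispersed but realistic choice since the model treats
    the mu_j as unrelated fixed effects.
    """

    treatments: list[Treatment]
    study_arms: list[Sequence[int]]
    d: np.ndarray
    Sigma: ContrastCovariance | np.ndarray
    n_per_arm: int = 100
    mu_mean: float = float(np.log(0.3 / 0.7))
    mu_sd: float = 0.5

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if isinstance(self.Sigma, np.ndarray):
            self.Sigma = ContrastCovariance(self.Sigma)
        p = len(self.treatments) - 1
        if self.d.shape != (p,):
            raise ValueError(f"d must have length p = {p}")
        if self.Sigma.p != p:
            raise ValueError(f"Sigma must be {p}x{p}")
        if not self.Sigma.is_psd():
            raise ValueError("true Sigma must be positive semidefinite")


@dataclass
class SimulationTruth:
    """True parameter record emitted alongside simulated data."""

    d: np.ndarray
    Sigma: np.ndarray
    mu: np.ndarray
    # per study: dict treatment -> true contrast delta_jbk vs the study baseline
    delta: list[dict[int, float]]


def simulate_network(
    design: SimulationDesign, seed: int | np.random.Generator = 0
) -> tuple[NetworkDataset, SimulationTruth]:
    """Draw a NetworkDataset from the generative model, plus the truth record.

    Per study j: mu_j ~ N(mu_mean, mu_sd^2); the contrast vector of the
    study's non-baseline arms is drawn from the multivariate normal with mean
    (d_0k - d_0b) and covariance ``trial_contrast_covariance``; each arm's
    event count is Binomial(n, expit(mu_j + delta_jbk)).  Deterministic under
    the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d_full = np.concatenate([[0.0], design.d])  # d_00 = 0
    Sigma = design.Sigma
    mus = rng.normal(design.mu_mean, design.mu_sd, size=len(design.study_arms))
    studies: list[Study] = []
    deltas: list[dict[int, float]] = []
    for j, arms in enumerate(design.study_arms):
        arms = sorted(arms)
        b = arms[0]
        others = arms[1:]
        mean = d_full[others] - d_full[b]
        cov = trial_contrast_covariance(Sigma, arms, b)
        # draw via eigendecomposition so singular (e.g. zero) Sigma is allowed
        w, V = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        z = rng.standard_normal(len(others))
        delta = mean + V @ (np.sqrt(w) * z)
        deltas.append({k: float(dl) for k, dl in zip(others, delta)})
        recs = []
        for k in arms:
            eta = mus[j] + (deltas[j][k] if k != b else 0.0)
            pi = 1.0 / (1.0 + np.exp(-eta))
            r = int(rng.binomial(design.n_per_arm, pi))
            recs.append(ArmRecord(str(j + 1), k, r, design.n_per_arm))
        studies.append(Study(str(j + 1), tuple(recs)))
    ds = NetworkDataset(list(design.treatments), studies)
    truth = SimulationTruth(d=design.d.copy(), Sigma=Sigma.Sigma.copy(), mu=mus, delta=deltas)
    return ds, truth
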