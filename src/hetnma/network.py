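"""Evidence-network data model: arm-level binary outcome data and validation.

The in-memory representation is arm based (one record per study arm, holding
events ``r`` out of ``n``), while the statistical model is contrast based:
each study contributes random effects for the contrasts of its non-baseline
arms against its baseline arm.  Treatments carry a class label
(pharmacological / nonpharmacological / control) used to select
comparison-type-specific heterogeneity priors.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "TreatmentClass",
    "ComparisonType",
    "Treatment",
    "ArmRecord",
    "Study",
    "NetworkDataset",
    "ValidationReport",
    "read_network_table",
    "write_network_table",
    "validate_network",
    "classify_comparison",
]


class TreatmentClass(str, Enum):
    PHARMACOLOGICAL = "pharmacological"
    NONPHARMACOLOGICAL = "nonpharmacological"
    CONTROL = "control"


class ComparisonType(str, Enum):
    """Comparison categories used to select data-based heterogeneity priors."""

    PHARM_VS_PHARM = "pharm_vs_pharm"
    PHARM_VS_NONPHARM = "pharm_vs_nonpharm"
    NONPHARM_VS_NONPHARM = "nonpharm_vs_nonpharm"
    PHARM_VS_CONTROL = "pharm_vs_control"
    NONPHARM_VS_CONTROL = "nonpharm_vs_control"


@dataclass(frozen=True)
class Treatment:
    """A treatment node; index 0 is the overall reference treatment."""

    id: int
    label: str
    klass: TreatmentClass | None = None


@dataclass(frozen=True)
class ArmRecord:
    """One study arm: ``events`` successes out of ``total`` participants."""

    study: str
    treatment: int
    events: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValueError(f"arm ({self.study}, {self.treatment}): total must be >= 1")
        if not 0 <= self.events <= self.total:
            raise ValueError(
                f"arm ({self.study}, {self.treatment}): events {self.events} outside [0, {self.total}]"
            )


@dataclass(frozen=True)
class Study:
    """A trial with >= 2 arms on distinct treatments.

    The baseline treatment (against which the study's random effects are
    defined) is the lowest treatment index present in the study.
    """

    id: str
    arms: tuple[ArmRecord, ...]

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise ValueError(f"study {self.id}: needs >= 2 arms")
        treatments = [a.treatment for a in self.arms]
        if len(set(treatments)) != len(treatments):
            raise ValueError(f"study {self.id}: duplicate treatment arms")
        # keep arms ordered by treatment index so the baseline comes first
        object.__setattr__(self, "arms", tuple(sorted(self.arms, key=lambda a: a.treatment)))

    @property
    def baseline(self) -> int:
        return self.arms[0].treatment

    @property
    def treatments(self) -> tuple[int, ...]:
        return tuple(a.treatment for a in self.arms)


@dataclass
class NetworkDataset:
    """Treatments plus studies forming a connected evidence network."""

    treatments: list[Treatment]
    studies: list[Study]

    def __post_init__(self) -> None:
        ids = [t.id for t in self.treatments]
        if ids != list(range(len(ids))):
            raise ValueError("treatment ids must be contiguous 0..p")
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ValueError("treatment labels must be unique")
        used = {a.treatment for s in self.studies for a in s.arms}
        missing = set(ids) - used
        if missing:
            raise ValueError(f"treatments never used in any study: {sorted(missing)}")
        if not used <= set(ids):
            raise ValueError("study arm refers to unknown treatment id")

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    @property
    def p(self) -> int:
        """Number of basic parameters (contrasts with the reference)."""
        return len(self.treatments) - 1

    @property
    def n_arms(self) -> int:
        return sum(len(s.arms) for s in self.studies)

    def treatment_by_label(self, label: str) -> Treatment:
        for t in self.treatments:
            if t.label == label:
                return t
        raise KeyError(label)

    def comparison_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(t.id for t in self.treatments)
        for s in self.studies:
            for a, b in itertools.combinations(s.treatments, 2):
                g.add_edge(a, b)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.comparison_graph())


@dataclass
class ValidationReport:
    """Per-comparison study counts, connectivity, and multi-arm studies."""

    comparison_counts: dict[tuple[str, str], int]
    connected: bool
    multi_arm_studies: list[str]
    n_studies: int
    n_treatments: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"{self.n_studies} studies, {self.n_treatments} treatments, "
            f"connected={self.connected}",
        ]
        for (a, b), c in sorted(self.comparison_counts.items()):
            lines.append(f"  {a} vs {b}: {c} studies")
        if self.multi_arm_studies:
            lines.append(f"  multi-arm studies: {', '.join(self.multi_arm_studies)}")
        return "\n".join(lines)


_DEFAULT_SCHEMA = {"study": "study", "treatment": "treatment", "events": "events", "total": "total"}

_CLASS_ALIASES = {
    "pharmacological": TreatmentClass.PHARMACOLOGICAL,
    "pharm": TreatmentClass.PHARMACOLOGICAL,
    "nonpharmacological": TreatmentClass.NONPHARMACOLOGICAL,
    "nonpharm": TreatmentClass.NONPHARMACOLOGICAL,
    "control": TreatmentClass.CONTROL,
    "placebo": TreatmentClass.CONTROL,
}


def _parse_class(value) -> TreatmentClass | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    key = str(value).strip().lower()
    if key in ("", "nan"):
        return None
    try:
        return _CLASS_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown treatment class {value!r}") from None


def read_treatment_table(path: str | Path) -> list[tuple[str, TreatmentClass | None]]:
    """Read a treatment table CSV with columns ``treatment,class``."""
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "treatment" not in df.columns:
        raise ValueError("treatment table: missing column 'treatment'")
    classes = df["class"] if "class" in df.columns else [None] * len(df)
    return [(str(t).strip(), _parse_class(c)) for t, c in zip(df["treatment"], classes)]


def read_network_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    treatments: Sequence[tuple[str, TreatmentClass | None]] | str | Path | None = None,
    reference: str | None = None,
) -> NetworkDataset:
    """Read a long-format arm table (one CSV row per study arm).

    Parameters
    ----------
    path
        Comma-separated file with a header row and one row per arm.
    schema
        Maps the logical column names ``study``, ``treatment``, ``events``,
        ``total`` to the column names actually present in the file.
    treatments
        Either a treatment-table CSV path (columns ``treatment,class``) or a
        sequence of ``(label, class)`` pairs; its order fixes the treatment
        indexing.  If omitted, treatments are indexed by order of first
        appearance, with classes taken from an optional inline ``class``
        column.
    reference
        Label of the treatment to place at index 0 (the overall reference);
        defaults to the first declared treatment.
    """
    schema = {**_DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    for logical, col in schema.items():
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} (for {logical})")
    if len(df) == 0:
        raise ValueError("no arm records")

    for col in (schema["events"], schema["total"]):
        values = df[col]
        as_float = pd.to_numeric(values, errors="raise")
        if not (as_float == as_float.round()).all():
            raise ValueError(f"non-integer counts in column {col!r}")
        df[col] = as_float.astype(int)

    if isinstance(treatments, (str, Path)):
        declared = read_treatment_table(treatments)
    elif treatments is not None:
        declared = [(str(lbl), kl) for lbl, kl in treatments]
    else:
        inline = {}
        if "class" in df.columns:
            for lbl, cl in zip(df[schema["treatment"]], df["class"]):
                inline.setdefault(str(lbl).strip(), _parse_class(cl))
        seen: list[str] = []
        for lbl in df[schema["treatment"]]:
            lbl = str(lbl).strip()
            if lbl not in seen:
                seen.append(lbl)
        declared = [(lbl, inline.get(lbl)) for lbl in seen]

    labels = [lbl for lbl, _ in declared]
    if reference is not None:
        if reference not in labels:
            raise ValueError(f"reference treatment {reference!r} not declared")
        declared = sorted(declared, key=lambda t: t[0] != reference)
    treatment_objs = [Treatment(i, lbl, kl) for i, (lbl, kl) in enumerate(declared)]
    index = {t.label: t.id for t in treatment_objs}

    seen_pairs: set[tuple[str, str]] = set()
    arms_by_study: dict[str, list[ArmRecord]] = {}
    for _, row in df.iterrows():
        study = str(row[schema["study"]]).strip()
        lbl = str(row[schema["treatment"]]).strip()
        if lbl not in index:
            raise ValueError(f"arm treatment {lbl!r} not in declared treatment table")
        if (study, lbl) in seen_pairs:
            raise ValueError(f"duplicate arm row for study {study!r}, treatment {lbl!r}")
        seen_pairs.add((study, lbl))
        arms_by_study.setdefault(study, []).append(
            ArmRecord(study, index[lbl], int(row[schema["events"]]), int(row[schema["total"]]))
        )
    studies = [Study(sid, tuple(arms)) for sid, arms in arms_by_study.items()]
    return NetworkDataset(treatment_objs, studies)


def write_network_table(
    ds: NetworkDataset, path: str | Path, treatment_path: str | Path | None = None
) -> None:
    """Write the arm table (and optionally the treatment table) as CSV."""
    rows = []
    label = {t.id: t.label for t in ds.treatments}
    for s in ds.studies:
        for a in s.arms:
            rows.append(
                {"study": a.study, "treatment": label[a.treatment], "events": a.events, "total": a.total}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    if treatment_path is not None:
        pd.DataFrame(
            {
                "treatment": [t.label for t in ds.treatments],
                "class": [t.klass.value if t.klass else "" for t in ds.treatments],
            }
        ).to_csv(treatment_path, index=False)


def validate_network(ds: NetworkDataset) -> ValidationReport:
    """Summarise the evidence network: direct-comparison counts, connectivity,
    and multi-arm studies.  A disconnected network is reported, not raised."""
    label = {t.id: t.label for t in ds.treatments}
    counts: Counter[tuple[str, str]] = Counter()
    for s in ds.studies:
        for a, b in itertools.combinations(sorted(s.treatments), 2):
            counts[(label[a], label[b])] += 1
    return ValidationReport(
        comparison_counts=dict(counts),
        connected=ds.is_connected(),
        multi_arm_studies=[s.id for s in ds.studies if len(s.arms) > 2],
        n_studies=len(ds.studies),
        n_treatments=ds.n_treatments,
    )


def classify_comparison(a: Treatment, b: Treatment) -> ComparisonType:
    """Classify a pair of treatments into one of the five comparison types.

    Symmetric in its arguments; comparing two control treatments is an error,
    as is classifying a treatment without a class label.
    """
    if a.id == b.id:
        raise ValueError("cannot classify a treatment against itself")
    if a.klass is None or b.klass is None:
        raise ValueError("both treatments need a class label to classify the comparison")
    kinds = Counter([a.klass, b.klass])
    c, ph, np_ = (
        kinds[TreatmentClass.CONTROL],
        kinds[TreatmentClass.PHARMACOLOGICAL],
        kinds[TreatmentClass.NONPHARMACOLOGICAL],
    )
    if c == 2:
        raise ValueError("cannot classify a control vs control comparison")
    if c == 1:
        return ComparisonType.PHARM_VS_CONTROL if ph else ComparisonType.NONPHARM_VS_CONTROL
    if ph == 2:
        return ComparisonType.PHARM_VS_PHARM
    if np_ == 2:
        return ComparisonType.NONPHARM_VS_NONPHARM
    return ComparisonType.PHARM_VS_NONPHARM
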