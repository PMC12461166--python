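"""Core longitudinal domain types: features, visits, patients, cohorts.

A cohort is a set of patients; each patient is a date-ordered sequence of
visits carrying a diagnosis label (Control < aMCI < AD, with OtherDementia
outside the studied spectrum) and a sparse feature vector.  Features belong
to one of two groups — per-visit cognitive scores ("cognition") or
health/history variables ("health") — and may be static (constant within a
patient, e.g. family history).  Missing values are represented as NaN.

Long-format CSV round-tripping (one row per visit) plus a YAML sidecar for
the feature dictionary lives here as well.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CONTROL",
    "AMCI",
    "AD",
    "OTHER_DEMENTIA",
    "LABELS",
    "SEVERITY",
    "FeatureSpec",
    "Visit",
    "PatientRecord",
    "Cohort",
    "span_years",
    "years_between",
]

CONTROL = "Control"
AMCI = "aMCI"
AD = "AD"
OTHER_DEMENTIA = "OtherDementia"

#: The three predicted classes, ordered by clinical severity.
LABELS = (CONTROL, AMCI, AD)
SEVERITY = {CONTROL: 0, AMCI: 1, AD: 2}

DAYS_PER_YEAR = 365.25


def years_between(earlier: dt.date, later: dt.date) -> float:
    """Fractional years between two dates (365.25-day year)."""
    return (later - earlier).days / DAYS_PER_YEAR


@dataclass(frozen=True)
class FeatureSpec:
    """One feature's metadata.

    Parameters
    ----------
    name : unique identifier (CSV column name).
    group : "cognition" or "health".
    static : True if the value never changes across a patient's visits;
        static features are excluded from the change (ratio) representation.
    positive_coding : True if non-missing raw values are strictly positive,
        which is what makes a negative sentinel linearly separable.
    """

    name: str
    group: str
    static: bool = False
    positive_coding: bool = True

    def __post_init__(self):
        if self.group not in ("cognition", "health"):
            raise ValueError(f"unknown feature group {self.group!r}")


def validate_specs(specs: Iterable[FeatureSpec]) -> list[FeatureSpec]:
    specs = list(specs)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    return specs


@dataclass
class Visit:
    date: dt.date
    values: dict[str, float]  # missing entries are NaN or absent
    label: str

    def value(self, name: str) -> float:
        v = self.values.get(name, np.nan)
        return float(v) if v is not None else np.nan


@dataclass
class PatientRecord:
    patient_id: str
    visits: list[Visit] = field(default_factory=list)

    def __post_init__(self):
        dates = [v.date for v in self.visits]
        if any(d is None for d in dates):
            raise ValueError(f"patient {self.patient_id}: undated visit")
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(
                f"patient {self.patient_id}: visits must be strictly increasing in date")

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def final_label(self) -> str:
        return self.visits[-1].label

    @property
    def span_years(self) -> float:
        return years_between(self.visits[0].date, self.visits[-1].date)


def span_years(patient: PatientRecord) -> float:
    return patient.span_years


@dataclass
class Cohort:
    patients: list[PatientRecord]
    feature_specs: list[FeatureSpec]

    def __post_init__(self):
        self.feature_specs = validate_specs(self.feature_specs)

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.feature_specs]

    def spec_by_name(self) -> dict[str, FeatureSpec]:
        return {s.name: s for s in self.feature_specs}

    def copy(self) -> "Cohort":
        patients = [
            PatientRecord(p.patient_id,
                          [Visit(v.date, dict(v.values), v.label) for v in p.visits])
            for p in self.patients
        ]
        return Cohort(patients, list(self.feature_specs))

    # -- long-format round-trip -------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            for v in p.visits:
                row = {"patient_id": p.patient_id,
                       "visit_date": v.date.isoformat(),
                       "label": v.label}
                for name in self.feature_names:
                    row[name] = v.value(name)
                rows.append(row)
        return pd.DataFrame(rows, columns=["patient_id", "visit_date", "label",
                                           *self.feature_names])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, specs: list[FeatureSpec]) -> "Cohort":
        specs = validate_specs(specs)
        names = [s.name for s in specs]
        patients = []
        for pid, grp in frame.groupby("patient_id", sort=True):
            grp = grp.sort_values("visit_date")
            visits = []
            for _, row in grp.iterrows():
                date = pd.Timestamp(row["visit_date"]).date()
                values = {n: float(row[n]) if pd.notna(row[n]) else np.nan
                          for n in names}
                visits.append(Visit(date, values, str(row["label"])))
            patients.append(PatientRecord(str(pid), visits))
        return cls(patients, specs)

    def write_csv(self, path: str | Path, spec_path: str | Path | None = None) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if spec_path is None:
            spec_path = path.with_suffix(".spec.yaml")
        write_feature_specs(self.feature_specs, spec_path)

    @classmethod
    def read_csv(cls, path: str | Path, spec_path: str | Path | None = None) -> "Cohort":
        path = Path(path)
        if spec_path is None:
            spec_path = path.with_suffix(".spec.yaml")
        specs = read_feature_specs(spec_path)
        frame = pd.read_csv(path, float_precision="round_trip")
        unknown = set(frame["label"].unique()) - {CONTROL, AMCI, AD, OTHER_DEMENTIA}
        if unknown:
            raise ValueError(f"unknown label(s) in cohort file: {sorted(unknown)}")
        return cls.from_frame(frame, specs)


def write_feature_specs(specs: Iterable[FeatureSpec], path: str | Path) -> None:
    payload = {"features": [dataclasses.asdict(s) for s in specs]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_feature_specs(path: str | Path) -> list[FeatureSpec]:
    payload = yaml.safe_load(Path(path).read_text())
    return [FeatureSpec(**entry) for entry in payload["features"]]
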