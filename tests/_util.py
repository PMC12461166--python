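"""Hand-built fixtures shared across test modules."""

from __future__ import annotations

import datetime as dt

import numpy as np

from longicog.cohort import FeatureSpec, PatientRecord, Visit

BASE_DATE = dt.date(2000, 1, 1)


def date_at(years: float) -> dt.date:
    return BASE_DATE + dt.timedelta(days=round(years * 365.25))


def make_patient(pid: str, years: list[float], labels: list[str],
                 values: list[dict] | None = None) -> PatientRecord:
    values = values or [{} for _ in years]
    visits = [Visit(date_at(y), dict(v), lab)
              for y, lab, v in zip(years, labels, values)]
    return PatientRecord(pid, visits)


def simple_specs() -> list[FeatureSpec]:
    return [
        FeatureSpec("memory", "cognition"),
        FeatureSpec("attention", "cognition"),
        FeatureSpec("bmi", "health"),
        FeatureSpec("family_history", "health", static=True),
    ]


def random_engineered(rng: np.random.Generator, K: int = 6, T: int = 3):
    from longicog.features import EngineeredSample

    bm = (rng.random(K) > 0.3).astype(float)
    baseline = np.where(bm > 0, rng.normal(size=K), np.nan)
    cm = (rng.random((K, T)) > 0.3).astype(float)
    change = np.where(cm > 0, rng.lognormal(0, 0.2, size=(K, T)), np.nan)
    label = ["Control", "aMCI", "AD"][int(rng.integers(3))]
    return EngineeredSample("px", baseline, bm, change, cm, label)
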