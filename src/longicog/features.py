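"""Dual feature engineering: "baseline" and "change" representations.

Two complementary views of each visit prefix are produced:

* **baseline** — the most recent prefix visit's raw values standardised as
  z-scores against the cognitively normal population *of the training
  split* (validation data is scored with the same training statistics, so
  no information flows backwards).  This captures how far a patient sits
  from the healthy norm.
* **change** — each prefix visit's raw values expressed as the ratio to the
  same patient's first visit, ``x_j(t) / x_j(1)``, a ``features x
  timesteps`` matrix capturing intrapersonal drift.  Features that are
  static within a patient (family history and the like) would contribute a
  constant ratio of 1, so they are masked out of the change view entirely
  and live only in the baseline view.

Missingness is carried as explicit binary masks (1 = observed).  Ratios are
taken on raw, pre-standardisation values: a ratio of z-scores is ill-defined
near zero.  A zero or missing first-visit denominator masks the whole
feature row rather than producing infinities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CONTROL, FeatureSpec, Visit
from .pipeline import TrainingPair

__all__ = [
    "ControlStats",
    "EngineeredSample",
    "fit_control_stats",
    "zscore_baseline",
    "change_ratios",
    "mask_static_in_change",
    "engineer_sample",
    "BaselineChangeFeaturizer",
]

LABEL_INDEX = {"Control": 0, "aMCI": 1, "AD": 2}


@dataclass
class ControlStats:
    """Per-feature mean/sd of the training-split control population.

    ``flagged`` marks features with fewer than two observed control values
    or zero variance; these cannot be z-scored and pass through as missing.
    """

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_obs: np.ndarray
    flagged: np.ndarray  # boolean, True = unusable for z-scoring
    n_control: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "n_obs": self.n_obs.tolist(),
            "flagged": self.flagged.tolist(),
            "n_control": self.n_control,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ControlStats":
        d = json.loads(Path(path).read_text())
        return cls(d["feature_names"], np.array(d["mean"]), np.array(d["sd"]),
                   np.array(d["n_obs"]), np.array(d["flagged"], dtype=bool),
                   d["n_control"])


@dataclass
class EngineeredSample:
    """Model-ready sample: baseline vector, change matrix, masks, target."""

    patient_id: str
    baseline: np.ndarray        # (K,), NaN where missing
    baseline_mask: np.ndarray   # (K,), 1 = observed
    change: np.ndarray          # (K, T), NaN where missing; T may be 0
    change_mask: np.ndarray     # (K, T)
    target_label: str
    horizon_years: float = float("nan")

    @property
    def y(self) -> int:
        return LABEL_INDEX[self.target_label]

    @property
    def n_timesteps(self) -> int:
        return self.change.shape[1]


def control_visits_from_pairs(pairs: list[TrainingPair]) -> list[Visit]:
    """Unique control-labelled prefix visits across training pairs.  The
    same visit appears in many augmented prefixes; deduplicate by
    (patient, date) so early visits are not over-weighted."""
    seen: set[tuple[str, object]] = set()
    visits = []
    for pair in pairs:
        for v in pair.prefix:
            key = (pair.patient_id, v.date)
            if v.label == CONTROL and key not in seen:
                seen.add(key)
                visits.append(v)
    return visits


def fit_control_stats(train_pairs: list[TrainingPair],
                      feature_names: list[str]) -> ControlStats:
    """Mean and sample sd (n-1) of each feature over observed values of the
    training split's control visits."""
    visits = control_visits_from_pairs(train_pairs)
    K = len(feature_names)
    mean = np.full(K, np.nan)
    sd = np.full(K, np.nan)
    n_obs = np.zeros(K, dtype=int)
    flagged = np.zeros(K, dtype=bool)
    for j, name in enumerate(feature_names):
        vals = np.array([v.value(name) for v in visits], dtype=float)
        vals = vals[np.isfinite(vals)]
        n_obs[j] = vals.size
        if vals.size < 2:
            flagged[j] = True
            continue
        mean[j] = vals.mean()
        sd[j] = vals.std(ddof=1)
        if sd[j] == 0:
            flagged[j] = True
    return ControlStats(list(feature_names), mean, sd, n_obs, flagged,
                        n_control=len(visits))


def _values_vector(visit: Visit, feature_names: list[str]) -> np.ndarray:
    return np.array([visit.value(n) for n in feature_names], dtype=float)


def zscore_baseline(visit: Visit | np.ndarray, stats: ControlStats
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(x - mean)/sd per observed value; missing or flagged features stay
    missing with mask 0."""
    raw = visit if isinstance(visit, np.ndarray) else \
        _values_vector(visit, stats.feature_names)
    observed = np.isfinite(raw) & ~stats.flagged
    out = np.full(raw.shape, np.nan)
    with np.errstate(invalid="ignore"):
        z = (raw - stats.mean) / stats.sd
    out[observed] = z[observed]
    return out, observed.astype(float)


def change_ratios(prefix: list[Visit] | tuple[Visit, ...],
                  feature_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(K, T) matrix of ratios against the first visit on raw values.

    Entry (j, t) = x_j(t) / x_j(1) where both are observed and the
    denominator is nonzero; the first column is exactly 1 where the first
    visit is observed; everything else is masked.
    """
    if len(prefix) == 0:
        raise ValueError("change_ratios requires at least one visit")
    K, T = len(feature_names), len(prefix)
    raw = np.stack([_values_vector(v, feature_names) for v in prefix], axis=1)
    denom = raw[:, :1]  # first-visit values
    valid_denom = np.isfinite(denom) & (denom != 0)
    observed = np.isfinite(raw) & valid_denom
    change = np.full((K, T), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = raw / denom
    change[observed] = ratio[observed]
    return change, observed.astype(float)


def mask_static_in_change(change_mask: np.ndarray,
                          specs: list[FeatureSpec]) -> np.ndarray:
    """Zero the change mask on static features (their ratio is identically
    1 and carries no information); the baseline view keeps them."""
    out = change_mask.copy()
    static = np.array([s.static for s in specs])
    out[static, :] = 0.0
    return out


def engineer_sample(pair: TrainingPair, stats: ControlStats,
                    specs: list[FeatureSpec]) -> EngineeredSample:
    """Build the model-ready representation of one pair.

    The baseline vector comes from the most recent prefix visit.  The change
    matrix covers every prefix visit; a single-visit prefix produces an
    *empty* change sequence (its only column would be the constant 1), so
    the temporal encoder's state stays at zero and the classifier reduces to
    the pure-baseline path.
    """
    names = stats.feature_names
    baseline, baseline_mask = zscore_baseline(pair.prefix[-1], stats)
    K = len(names)
    if len(pair.prefix) < 2:
        change = np.zeros((K, 0))
        change_mask = np.zeros((K, 0))
    else:
        change, change_mask = change_ratios(pair.prefix, names)
        change_mask = mask_static_in_change(change_mask, specs)
        change = np.where(change_mask > 0, change, np.nan)
    return EngineeredSample(
        patient_id=pair.patient_id,
        baseline=baseline,
        baseline_mask=baseline_mask,
        change=change,
        change_mask=change_mask,
        target_label=pair.target_label,
        horizon_years=pair.horizon_years,
    )


class BaselineChangeFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer from training pairs to engineered samples.

    ``fit`` learns the control-population statistics from the training
    pairs; ``transform`` applies them to any pairs (training or held-out),
    never refitting — the held-out split is standardised against the
    *training* control population.

    Attributes
    ----------
    stats_ : ControlStats
    feature_names_ : list of str
    n_features_in_ : int
    """

    def __init__(self, specs: list[FeatureSpec] | None = None):
        self.specs = specs

    def fit(self, X: list[TrainingPair], y=None) -> "BaselineChangeFeaturizer":
        if self.specs is None:
            raise ValueError("feature specs are required")
        if len(X) == 0:
            raise ValueError("cannot fit on an empty pair list")
        self.feature_names_ = [s.name for s in self.specs]
        self.stats_ = fit_control_stats(X, self.feature_names_)
        self.n_features_in_ = len(self.feature_names_)
        return self

    def transform(self, X: list[TrainingPair]) -> list[EngineeredSample]:
        if not hasattr(self, "stats_"):
            raise RuntimeError("featurizer is not fitted")
        return [engineer_sample(p, self.stats_, self.specs) for p in X]
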