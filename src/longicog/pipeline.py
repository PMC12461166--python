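"""Cohort preparation: eligibility, exclusions, balancing, prefix
augmentation, evaluation-pair construction, and patient-level folds.

The study design asks whether a patient's cognitive status 3-10 years past
their last observed visit can be predicted.  Training exploits every
(visit-prefix, next-visit-label) transition a record contains — a t-visit
record yields t-1 training pairs — while evaluation uses exactly one pair
per patient, whose prefix contains only visits 3-10 years before the final
visit and whose prefixes are therefore a subset of what training saw.
Cross-validation folds partition *patients*, never pairs, so no augmented
view of an evaluation patient can leak into training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    AD,
    AMCI,
    CONTROL,
    OTHER_DEMENTIA,
    SEVERITY,
    Cohort,
    PatientRecord,
    Visit,
    years_between,
)

__all__ = [
    "TrainingPair",
    "FoldAssignment",
    "filter_eligibility",
    "drop_non_ad_and_reversions",
    "drop_reversion_pairs",
    "balance_classes",
    "augment_prefixes",
    "build_eval_pairs",
    "split_folds",
    "prepare_pairs",
    "pairs_manifest",
]


@dataclass(frozen=True)
class TrainingPair:
    """A (visit-prefix, target) supervision pair.

    ``horizon_years`` is the gap from the *last prefix visit* to the target
    visit; augmented training pairs span roughly 1-10 years while evaluation
    pairs are constrained to the 3-10 year band.
    """

    patient_id: str
    prefix: tuple[Visit, ...]
    target_label: str
    horizon_years: float
    target_date: object = None  # datetime.date of the target visit

    def __post_init__(self):
        if len(self.prefix) == 0:
            raise ValueError("prefix must be non-empty")


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    assignment: dict[str, int]  # patient_id -> fold index

    def patients_in_fold(self, fold: int) -> list[str]:
        return sorted(pid for pid, f in self.assignment.items() if f == fold)

    def fold_of(self, patient_id: str) -> int:
        return self.assignment[patient_id]


# -- filtering -------------------------------------------------------------

def filter_eligibility(cohort: Cohort, min_span: float = 3.0,
                       max_span: float = 10.0, min_visits: int = 2) -> Cohort:
    """Keep patients with >= min_visits visits whose first-to-last span lies
    in [min_span, max_span] fractional years (365.25-day year)."""
    kept = [p for p in cohort.patients
            if p.n_visits >= min_visits and min_span <= p.span_years <= max_span]
    return Cohort(kept, list(cohort.feature_specs))


def drop_non_ad_and_reversions(cohort: Cohort) -> Cohort:
    """Remove patients who ever carry a non-AD dementia label.  Reversion
    handling is pair-level (see :func:`drop_reversion_pairs`): a patient with
    a reverting label sequence keeps their non-reverting transitions."""
    known = {CONTROL, AMCI, AD, OTHER_DEMENTIA}
    for p in cohort.patients:
        for v in p.visits:
            if v.label not in known:
                raise ValueError(
                    f"patient {p.patient_id}: unknown label {v.label!r}")
    kept = [p for p in cohort.patients
            if all(v.label != OTHER_DEMENTIA for v in p.visits)]
    return Cohort(kept, list(cohort.feature_specs))


def _is_reversion(pair: TrainingPair) -> bool:
    return SEVERITY[pair.target_label] < SEVERITY[pair.prefix[-1].label]


def drop_reversion_pairs(pairs: list[TrainingPair]) -> list[TrainingPair]:
    """Drop pairs whose target label is less severe than the last prefix
    label (Control < aMCI < AD)."""
    return [p for p in pairs if not _is_reversion(p)]


def balance_classes(items: list, labels: list[str], seed: int = 0):
    """Uniform draw without replacement down to the smallest class size.

    Returns the retained items in their original relative order.  Raises if
    any of the three classes is empty (balancing would erase it).
    """
    if len(items) != len(labels):
        raise ValueError("items and labels must align")
    by_class: dict[str, list[int]] = {c: [] for c in (CONTROL, AMCI, AD)}
    for i, lab in enumerate(labels):
        if lab not in by_class:
            raise ValueError(f"unknown class label {lab!r}")
        by_class[lab].append(i)
    counts = {c: len(ix) for c, ix in by_class.items()}
    if min(counts.values()) == 0:
        empty = [c for c, n in counts.items() if n == 0]
        raise ValueError(f"cannot balance: empty class(es) {empty}")
    m = min(counts.values())
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for c in (CONTROL, AMCI, AD):
        ix = by_class[c]
        chosen = rng.choice(len(ix), size=m, replace=False)
        keep.update(ix[j] for j in chosen)
    return [items[i] for i in sorted(keep)]


# -- pair construction -----------------------------------------------------

def augment_prefixes(patient: PatientRecord) -> list[TrainingPair]:
    """Expand a t-visit record into the t-1 pairs
    (visits[0:j], label of visit j) for j = 1..t-1.  Single-visit records
    yield no pairs.  Reversion pairs are *not* removed here."""
    pairs = []
    for j in range(1, patient.n_visits):
        prefix = tuple(patient.visits[:j])
        target = patient.visits[j]
        pairs.append(TrainingPair(
            patient_id=patient.patient_id,
            prefix=prefix,
            target_label=target.label,
            horizon_years=years_between(prefix[-1].date, target.date),
            target_date=target.date,
        ))
    return pairs


def build_eval_pairs(patient: PatientRecord, min_h: float = 3.0,
                     max_h: float = 10.0) -> list[TrainingPair]:
    """Zero or one evaluation pair per patient: target = last visit, prefix =
    every earlier visit dated min_h..max_h years before it.  No prefix
    augmentation is applied at evaluation time."""
    if patient.n_visits < 2:
        return []
    target = patient.visits[-1]
    prefix = tuple(
        v for v in patient.visits[:-1]
        if min_h <= years_between(v.date, target.date) <= max_h)
    if not prefix:
        return []
    pair = TrainingPair(
        patient_id=patient.patient_id,
        prefix=prefix,
        target_label=target.label,
        horizon_years=years_between(prefix[-1].date, target.date),
        target_date=target.date,
    )
    return drop_reversion_pairs([pair])


def split_folds(patient_ids: list[str], k: int = 10, seed: int = 0) -> FoldAssignment:
    """Patient-level k-fold assignment: stable sort, seeded shuffle, round
    robin.  Fold sizes differ by at most one patient."""
    ids = sorted(set(patient_ids))
    if len(ids) != len(patient_ids):
        raise ValueError("duplicate patient ids")
    if k < 2 or k > len(ids):
        raise ValueError(f"k={k} must be in [2, n_patients={len(ids)}]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = {ids[p]: i % k for i, p in enumerate(perm)}
    return FoldAssignment(k=k, assignment=assignment)


# -- end-to-end preparation ------------------------------------------------

@dataclass
class PreparedPairs:
    """Everything downstream training needs: per-patient augmented training
    pairs (reversions removed), per-patient evaluation pairs, and the fold
    assignment."""

    train_pairs: dict[str, list[TrainingPair]]
    eval_pairs: dict[str, list[TrainingPair]]
    folds: FoldAssignment
    cohort: Cohort

    def train_pairs_for_fold(self, fold: int, held_out: bool = False):
        sel = (lambda f: f == fold) if held_out else (lambda f: f != fold)
        out = []
        for pid, pairs in sorted(self.train_pairs.items()):
            if sel(self.folds.fold_of(pid)):
                out.extend(pairs)
        return out

    def eval_pairs_for_fold(self, fold: int):
        out = []
        for pid, pairs in sorted(self.eval_pairs.items()):
            if self.folds.fold_of(pid) == fold:
                out.extend(pairs)
        return out


def prepare_pairs(cohort: Cohort, k: int = 10, seed: int = 0,
                  min_span: float = 3.0, max_span: float = 10.0,
                  balance: bool = True) -> PreparedPairs:
    """Full preparation pipeline: eligibility filter, non-AD-dementia
    exclusion, patient-level class balancing on final status, prefix
    augmentation (+ reversion-pair removal), evaluation pairs, fold split."""
    cohort = drop_non_ad_and_reversions(filter_eligibility(
        cohort, min_span=min_span, max_span=max_span))
    patients = cohort.patients
    if balance:
        patients = balance_classes(
            patients, [p.final_label for p in patients], seed=seed)
    cohort = Cohort(patients, list(cohort.feature_specs))
    train_pairs = {p.patient_id: drop_reversion_pairs(augment_prefixes(p))
                   for p in patients}
    eval_pairs = {p.patient_id: build_eval_pairs(p, min_h=min_span, max_h=max_span)
                  for p in patients}
    folds = split_folds([p.patient_id for p in patients], k=k, seed=seed)
    return PreparedPairs(train_pairs, eval_pairs, folds, cohort)


def pairs_manifest(prepared: PreparedPairs) -> pd.DataFrame:
    """Flat manifest of every pair, for inspection and the CLI."""
    rows = []
    for split, mapping in (("train", prepared.train_pairs),
                           ("eval", prepared.eval_pairs)):
        for pid, pairs in sorted(mapping.items()):
            for i, pair in enumerate(pairs):
                rows.append({
                    "patient_id": pid,
                    "pair_index": i,
                    "prefix_visit_dates": ";".join(v.date.isoformat()
                                                   for v in pair.prefix),
                    "target_date": pair.target_date.isoformat(),
                    "target_label": pair.target_label,
                    "horizon_years": round(pair.horizon_years, 4),
                    "split": split,
                    "fold": prepared.folds.fold_of(pid),
                })
    return pd.DataFrame(rows)
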