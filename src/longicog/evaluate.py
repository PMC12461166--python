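"""Patient-level cross-validated evaluation and the one-vs-rest metric suite.

Metrics follow the one-vs-rest (OvR) reading of a 3x3 confusion matrix
(rows = true label, columns = predicted): for the class under test,
predicting that class is "positive" and anything else "negative", giving
per-class precision, recall and OvR accuracy, plus rank-based (Mann-Whitney,
midrank ties) OvR AUC.  Cross-fold aggregates are reported as
``mean +/- half-width`` where the half-width is the two-tailed 95%
t-confidence band t_{0.975, k-1} * sd / sqrt(k) over the k fold values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .features import BaselineChangeFeaturizer
from .model import FusionClassifier
from .pipeline import PreparedPairs

__all__ = [
    "confusion_matrix",
    "ovr_extract",
    "ovr_auc",
    "fold_band",
    "FoldReport",
    "evaluate_fold",
    "crossval",
]

CLASS_NAMES = ("Control", "aMCI", "AD")


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int = 3) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def ovr_extract(confusion: np.ndarray, c: int) -> tuple[float, float, float]:
    """(precision, recall, OvR accuracy) for class c.

    Division by zero yields NaN (flagged undefined) rather than raising.
    """
    confusion = np.asarray(confusion)
    total = confusion.sum()
    tp = confusion[c, c]
    fp = confusion[:, c].sum() - tp
    fn = confusion[c, :].sum() - tp
    tn = total - tp - fp - fn
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    ovr_acc = (tp + tn) / total if total > 0 else float("nan")
    return float(precision), float(recall), float(ovr_acc)


def ovr_auc(probs: np.ndarray, labels: np.ndarray,
            n_classes: int = 3) -> tuple[list[float], float]:
    """Per-class rank AUC of P(class c) against (label == c), plus the
    unweighted macro average over classes with both positives and
    negatives; degenerate classes are NaN and excluded with a warning."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    per_class: list[float] = []
    for c in range(n_classes):
        pos = labels == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"class {c}: no positives or no negatives; "
                          "AUC undefined", stacklevel=2)
            per_class.append(float("nan"))
            continue
        ranks = sps.rankdata(probs[:, c])  # midranks for ties
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        per_class.append(float(auc))
    defined = [a for a in per_class if np.isfinite(a)]
    macro = float(np.mean(defined)) if defined else float("nan")
    return per_class, macro


def fold_band(values: list[float] | np.ndarray) -> tuple[float, float]:
    """mean and two-tailed 95% t-band half-width over k >= 2 fold values."""
    values = np.asarray(values, dtype=float)
    k = values.size
    if k < 2:
        raise ValueError("confidence band needs at least two fold values")
    half = sps.t.ppf(0.975, k - 1) * values.std(ddof=1) / np.sqrt(k)
    return float(values.mean()), float(half)


@dataclass
class FoldReport:
    """Per-fold metrics plus cross-fold mean +/- p95 bands."""

    per_fold: list[dict] = field(default_factory=list)
    confusions: list[np.ndarray] = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)

    def aggregate_bands(self) -> None:
        if len(self.per_fold) < 2:
            self.aggregate = {}
            return
        keys = [k for k in self.per_fold[0] if k != "fold"]
        agg = {}
        for key in keys:
            vals = [f[key] for f in self.per_fold]
            if all(np.isfinite(v) for v in vals):
                mean, half = fold_band(vals)
                agg[key] = {"mean": mean, "half_width": half,
                            "display": f"{mean:.4f} ± {half:.4f}"}
        self.aggregate = agg

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_fold": self.per_fold,
            "confusion_matrices": [cm.tolist() for cm in self.confusions],
            "aggregate": self.aggregate,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _fold_metrics(cm: np.ndarray, probs: np.ndarray,
                  labels: np.ndarray) -> dict:
    total = cm.sum()
    metrics = {"overall_accuracy": float(np.trace(cm) / total) if total else
               float("nan"), "n_eval": int(total)}
    auc_per_class, auc_macro = ovr_auc(probs, labels)
    metrics["ovr_auc_macro"] = auc_macro
    for c, name in enumerate(CLASS_NAMES):
        precision, recall, ovr_acc = ovr_extract(cm, c)
        metrics[f"{name}_precision"] = precision
        metrics[f"{name}_recall"] = recall
        metrics[f"{name}_ovr_accuracy"] = ovr_acc
        metrics[f"{name}_ovr_auc"] = auc_per_class[c]
    return metrics


def evaluate_fold(prepared: PreparedPairs, fold: int,
                  model_params: dict | None = None,
                  ) -> tuple[dict, np.ndarray, FusionClassifier]:
    """Train on all folds but `fold`, evaluate on `fold`'s eval pairs.

    The held-out fold doubles as the dev set for early stopping (no third
    split), matching the reported training protocol.
    """
    train_pairs = prepared.train_pairs_for_fold(fold)
    eval_pairs = prepared.eval_pairs_for_fold(fold)
    if not eval_pairs:
        warnings.warn(f"fold {fold}: no evaluation pairs; skipping",
                      stacklevel=2)
        return {}, np.zeros((3, 3), dtype=int), None
    featurizer = BaselineChangeFeaturizer(prepared.cohort.feature_specs)
    train_samples = featurizer.fit(train_pairs).transform(train_pairs)
    eval_samples = featurizer.transform(eval_pairs)
    clf = FusionClassifier(**(model_params or {}))
    clf.fit(train_samples, X_val=eval_samples)
    labels = np.array([s.y for s in eval_samples])
    preds = clf.predict(eval_samples)
    probs = clf.predict_proba(eval_samples)
    cm = confusion_matrix(labels, preds)
    metrics = _fold_metrics(cm, probs, labels)
    metrics["fold"] = fold
    return metrics, cm, clf


def crossval(prepared: PreparedPairs, model_params: dict | None = None,
             folds: list[int] | None = None) -> FoldReport:
    """K-fold cross-validation over the prepared patient-level folds."""
    report = FoldReport()
    fold_ids = folds if folds is not None else list(range(prepared.folds.k))
    for fold in fold_ids:
        params = dict(model_params or {})
        params.setdefault("random_state", 0)
        params["random_state"] = params["random_state"] + fold  # vary per fold
        metrics, cm, _ = evaluate_fold(prepared, fold, params)
        if metrics:
            report.per_fold.append(metrics)
            report.confusions.append(cm)
    report.aggregate_bands()
    return report
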