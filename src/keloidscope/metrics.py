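"""Confusion-matrix metrics and stratified cross-validation.

Both trained stages are validated with 5-fold cross-validation, and the
growth-state classifier is summarized per class (one-vs-rest sensitivity,
specificity, Youden index J = sensitivity + specificity − 1, accuracy)
plus the multiclass accuracy (trace / total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .errors import InvalidInputError, InvalidKError, UndefinedMetricError

__all__ = [
    "CLASS_ORDER",
    "ConfusionMatrix3",
    "ClassMetrics",
    "FoldSplit",
    "confusion",
    "class_metrics",
    "overall_accuracy",
    "stratified_kfold",
    "aggregate_folds",
    "metrics_report",
]

CLASS_ORDER = ("regressive", "stable", "progressive")


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3×3 counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: float
    specificity: float
    youden: float
    accuracy_ovr: float


@dataclass(frozen=True)
class FoldSplit:
    """Stratified fold assignment: ``assignments[i]`` is sample i's fold id."""

    k: int
    assignments: np.ndarray
    seed: int

    def train_val(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        val = np.nonzero(self.assignments == fold)[0]
        if self.k == 1:  # trivial split: train = validate = everything
            return val, val
        train = np.nonzero(self.assignments != fold)[0]
        return train, val


def _as_indices(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        idx = arr.astype(int)
    else:
        lookup = {name: i for i, name in enumerate(CLASS_ORDER)}
        try:
            idx = np.array([lookup[str(v)] for v in arr])
        except KeyError as exc:
            raise InvalidInputError(f"unknown class label {exc.args[0]!r}") from exc
    if idx.size and (idx.min() < 0 or idx.max() > 2):
        raise InvalidInputError("class indices must be in {0, 1, 2}")
    return idx


def confusion(true_labels, predicted_labels) -> ConfusionMatrix3:
    """Count (true, predicted) pairs; labels may be names or indices 0..2."""
    t = _as_indices(true_labels)
    p = _as_indices(predicted_labels)
    if t.size == 0:
        raise InvalidInputError("cannot build a confusion matrix from empty inputs")
    if t.shape != p.shape:
        raise InvalidInputError("true and predicted label lists differ in length")
    counts = _sk_confusion(t, p, labels=[0, 1, 2])
    return ConfusionMatrix3(counts=counts.astype(np.int64))


def class_metrics(cm: ConfusionMatrix3, c: int | str) -> ClassMetrics:
    """One-vs-rest metrics for class ``c`` (index or name)."""
    if isinstance(c, str):
        c = CLASS_ORDER.index(c)
    m = cm.counts
    total = cm.total
    if total == 0:
        raise InvalidInputError("empty confusion matrix")
    tp = int(m[c, c])
    fn = int(m[c].sum() - tp)
    fp = int(m[:, c].sum() - tp)
    tn = total - tp - fn - fp
    if tp + fn == 0:
        raise UndefinedMetricError(f"sensitivity undefined: no true samples of class {CLASS_ORDER[c]}")
    if tn + fp == 0:
        raise UndefinedMetricError(f"specificity undefined: no negatives of class {CLASS_ORDER[c]}")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ClassMetrics(
        sensitivity=sens,
        specificity=spec,
        youden=sens + spec - 1.0,
        accuracy_ovr=(tp + tn) / total,
    )


def overall_accuracy(cm: ConfusionMatrix3) -> float:
    """Multiclass accuracy: trace / total."""
    if cm.total == 0:
        raise InvalidInputError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified fold assignment; per-fold class counts proportional ±1."""
    idx = _as_indices(labels)
    n = len(idx)
    if k < 1:
        raise InvalidKError("k must be >= 1")
    if k == 1:
        return FoldSplit(k=1, assignments=np.zeros(n, dtype=int), seed=seed)
    smallest = np.bincount(idx, minlength=3)
    smallest = smallest[smallest > 0].min()
    if k > smallest:
        raise InvalidKError(f"k={k} exceeds the smallest class count ({smallest})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32))
    assignments = np.empty(n, dtype=int)
    for fold, (_, val) in enumerate(skf.split(np.zeros(n), idx)):
        assignments[val] = fold
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def aggregate_folds(per_fold: list[float] | np.ndarray) -> dict:
    """Unweighted mean and SD of a per-fold metric vector."""
    arr = np.asarray(per_fold, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("need at least one fold")
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=0)), "per_fold": arr.tolist()}


def metrics_report(true_labels, predicted_labels) -> dict:
    """Full classification report: per-class metrics plus overall accuracy."""
    cm = confusion(true_labels, predicted_labels)
    report: dict = {"confusion": cm.counts.tolist(), "overall_accuracy": overall_accuracy(cm)}
    for i, name in enumerate(CLASS_ORDER):
        try:
            m = class_metrics(cm, i)
        except UndefinedMetricError:
            continue
        report[name] = {
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "youden": m.youden,
            "accuracy_ovr": m.accuracy_ovr,
        }
    return report
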