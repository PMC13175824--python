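"""Multi-class evaluation: confusion matrix, metrics, stratified folds.

Metrics follow the conventions standard in multi-class classification:
accuracy is trace(counts)/N; per-class precision and recall divide the
diagonal by column and row sums (defined as 0 when the denominator is
empty, with the class flagged); macro precision/recall/F1 are unweighted
class means; Cohen's kappa is (p_o - p_e)/(1 - p_e) with the marginal
chance agreement p_e = sum_c (row_c/N)(col_c/N).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "compute_metrics",
    "stratified_kfold",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C matrix of counts indexed (true class, predicted class)."""

    counts: np.ndarray
    class_names: tuple = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.counts, dtype=np.int64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("confusion matrix counts must be non-negative")
        object.__setattr__(self, "counts", m)
        names = tuple(self.class_names) or tuple(
            f"class_{i}" for i in range(m.shape[0])
        )
        if len(names) != m.shape[0]:
            raise ValueError("class_names length does not match matrix size")
        object.__setattr__(self, "class_names", names)

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def to_table(self, sep: str = ",") -> str:
        """Delimited text with class-name headers (rows: true class)."""
        lines = ["true\\pred" + sep + sep.join(self.class_names)]
        for name, row in zip(self.class_names, self.counts):
            lines.append(name + sep + sep.join(str(int(x)) for x in row))
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "counts": self.counts.tolist(),
        }


@dataclass(frozen=True)
class MetricsReport:
    """Aggregate and per-class classification metrics."""

    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    kappa: float
    per_class_precision: tuple
    per_class_recall: tuple
    per_class_f1: tuple
    class_names: tuple
    undefined_precision_classes: tuple = field(default=())
    undefined_recall_classes: tuple = field(default=())

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "kappa": self.kappa,
            "per_class": {
                name: {
                    "precision": p,
                    "recall": r,
                    "f1": f,
                }
                for name, p, r, f in zip(
                    self.class_names,
                    self.per_class_precision,
                    self.per_class_recall,
                    self.per_class_f1,
                )
            },
            "undefined_precision_classes": list(self.undefined_precision_classes),
            "undefined_recall_classes": list(self.undefined_recall_classes),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def confusion_matrix(y_true, y_pred, n_classes: int, class_names=()) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a C x C matrix."""
    t = np.asarray(y_true).astype(np.int64)
    p = np.asarray(y_pred).astype(np.int64)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(
            f"label vectors must be equal-length 1-d; got {t.shape} and {p.shape}"
        )
    if t.size and (t.min() < 0 or t.max() >= n_classes):
        raise ValueError(f"true labels outside [0, {n_classes - 1}]")
    if p.size and (p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"predicted labels outside [0, {n_classes - 1}]")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts, class_names=class_names)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Derive accuracy, macro precision/recall/F1 and Cohen's kappa.

    Degenerate conventions: precision (recall) for a class with an empty
    column (row) is 0 and the class is listed in the report's undefined
    set; F1 is 0 when precision and recall are both 0; kappa is 1 when
    p_e = 1 and p_o = 1, else 0 when p_e = 1.
    """
    m = cm.counts
    n = m.sum()
    if n == 0:
        raise ValueError("empty confusion matrix (N = 0)")
    diag = np.diag(m).astype(float)
    row = m.sum(axis=1).astype(float)
    col = m.sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)

    accuracy = float(diag.sum() / n)
    p_o = accuracy
    p_e = float(np.sum((row / n) * (col / n)))
    if p_e >= 1.0 - 1e-15:
        kappa = 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)

    return MetricsReport(
        accuracy=accuracy,
        precision_macro=float(precision.mean()),
        recall_macro=float(recall.mean()),
        f1_macro=float(f1.mean()),
        kappa=float(kappa),
        per_class_precision=tuple(precision.tolist()),
        per_class_recall=tuple(recall.tolist()),
        per_class_f1=tuple(f1.tolist()),
        class_names=cm.class_names,
        undefined_precision_classes=tuple(
            cm.class_names[i] for i in np.flatnonzero(col == 0)
        ),
        undefined_recall_classes=tuple(
            cm.class_names[i] for i in np.flatnonzero(row == 0)
        ),
    )


def stratified_kfold(labels, k: int, seed: int) -> np.ndarray:
    """Assign each sample a fold id in [0, k-1], stratified by class.

    Within each class the (seeded) shuffled indices are dealt round-robin
    over folds, so per-class fold sizes differ by at most one and the
    folds partition all indices.  Deterministic given the seed.
    """
    y = np.asarray(labels).astype(np.int64)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("labels must be a non-empty 1-d vector")
    if k < 2:
        raise ValueError(f"fold count must be >= 2, got {k}")
    classes, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        warnings.warn(
            f"k={k} exceeds the smallest class count ({counts.min()}); "
            "some folds will miss that class",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=np.int64)
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds
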