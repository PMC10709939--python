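"""Confusion matrices, the diagnostic metric set, and ROC/AUC.

Leiomyosarcoma is always the positive class.  AUC is defined as the
Mann-Whitney pair statistic — the fraction of (positive, negative) sample
pairs where the positive sample scores higher, ties counting one half — and
the ROC curve is thresholded at every distinct score, so the trapezoidal
integral of the curve equals the pair statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "EvaluationReport",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auc: float | None = None

    def rounded(self, ndigits: int = 3) -> dict:
        """Display form at the customary 3-decimal precision."""
        out = {
            "accuracy": round(self.accuracy, ndigits),
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "balanced_accuracy": round(self.balanced_accuracy, ndigits),
        }
        if self.auc is not None:
            out["auc"] = round(self.auc, ndigits)
        return out


def confusion(pred: np.ndarray, actual: np.ndarray) -> ConfusionMatrix:
    """Count the four cells; inputs are 0/1 vectors, 1 = leiomyosarcoma."""
    pred = np.asarray(pred).astype(int).ravel()
    actual = np.asarray(actual).astype(int).ravel()
    if pred.size != actual.size:
        raise ValueError(f"length mismatch: {pred.size} predictions vs {actual.size} labels")
    if pred.size == 0:
        raise ValueError("cannot build a confusion matrix from no samples")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (actual == 1))),
        fp=int(np.sum((pred == 1) & (actual == 0))),
        tn=int(np.sum((pred == 0) & (actual == 0))),
        fn=int(np.sum((pred == 0) & (actual == 1))),
    )


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, sensitivity, specificity, and balanced accuracy."""
    if cm.tp + cm.fn < 1:
        raise ValueError("sensitivity undefined: no actual positives")
    if cm.tn + cm.fp < 1:
        raise ValueError("specificity undefined: no actual negatives")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    return MetricSet(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2,
    )


def roc_auc(scores: np.ndarray, actual: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and AUC with leiomyosarcoma positive.

    Returns ``(points, auc)`` where ``points`` is an array of (fpr, tpr) rows
    obtained by thresholding at every distinct score (plus the degenerate
    endpoints), and ``auc`` is the tie-aware Mann-Whitney pair statistic.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    actual = np.asarray(actual).astype(int).ravel()
    if scores.size != actual.size:
        raise ValueError("scores and labels differ in length")
    n_pos = int(np.sum(actual == 1))
    n_neg = int(np.sum(actual == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    # pair statistic via midranks
    ranks = rankdata(scores)
    auc = (ranks[actual == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    points = []
    for t in thresholds:
        called = scores >= t
        tpr = np.sum(called & (actual == 1)) / n_pos
        fpr = np.sum(called & (actual == 0)) / n_neg
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return np.array(points), float(auc)


@dataclass
class EvaluationReport:
    confusion_matrix: ConfusionMatrix
    metrics: MetricSet
    roc_points: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        cm = self.confusion_matrix
        rows = [
            ("tp", cm.tp), ("fp", cm.fp), ("tn", cm.tn), ("fn", cm.fn),
            ("accuracy", self.metrics.accuracy),
            ("sensitivity", self.metrics.sensitivity),
            ("specificity", self.metrics.specificity),
            ("balanced_accuracy", self.metrics.balanced_accuracy),
            ("auc", self.metrics.auc),
        ]
        pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
            Path(path), sep="\t", index=False
        )

    def roc_to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.roc_points, columns=["fpr", "tpr"]).to_csv(
            Path(path), sep="\t", index=False
        )


def evaluate_predictions(
    probabilities: np.ndarray, actual: np.ndarray, threshold: float = 0.5
) -> EvaluationReport:
    """Full report from probabilities: threshold, count, score."""
    probabilities = np.asarray(probabilities, dtype=float).ravel()
    pred = (probabilities >= threshold).astype(int)
    cm = confusion(pred, actual)
    base = metrics_from_confusion(cm)
    points, auc = roc_auc(probabilities, actual)
    metrics = MetricSet(
        accuracy=base.accuracy,
        sensitivity=base.sensitivity,
        specificity=base.specificity,
        balanced_accuracy=base.balanced_accuracy,
        auc=auc,
    )
    return EvaluationReport(cm, metrics, points)
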