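"""Confusion-count metrics, class-ratio delta, CV folds, ROC/AUC, z-test.

The seven measures derived from a confusion matrix are accuracy, sensitivity,
specificity, precision, F1, Matthews correlation coefficient, and the
imbalance-aware ``Hybrid = sensitivity + delta * specificity`` where ``delta``
is a training group's cancer:neutral count ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    hybrid: float
    delta: float

    def get(self, name: str) -> float:
        return getattr(self, name.lower())


#: canonical fitness-function names -> MetricSet attributes
FITNESS_ATTR = {"Acc": "accuracy", "MCC": "mcc", "F1": "f1", "Hybrid": "hybrid"}


def compute_metrics(counts: ConfusionCounts, delta: float = 1.0) -> MetricSet:
    """All seven measures from TP/TN/FP/FN.

    Zero-denominator conventions: precision is 0 when no positive calls were
    made, MCC is 0 when any marginal is empty, F1 is 0 when precision and
    sensitivity are both 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("cannot evaluate metrics on all-zero counts")
    accuracy = (tp + tn) / counts.total
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    hybrid = sensitivity + delta * specificity
    return MetricSet(accuracy, sensitivity, specificity, precision, f1, mcc, hybrid, delta)


def counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts with 1 = cancer-related (positive class)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def class_ratio(n_cancer: int, n_neutral: int) -> float:
    """delta = cancer-related count / neutral count of a training group."""
    if n_neutral <= 0:
        raise ValueError("neutral count must be positive to form delta")
    return n_cancer / n_neutral


def stratified_folds(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1) per sample."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank statistic (midrank ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class ZTestResult:
    z: float
    significant: bool


def two_sample_z(group1, group2, threshold: float = 1.96) -> ZTestResult:
    """Welch-type two-sample z statistic with a null difference of zero.

    ``z = (mean1 - mean2) / sqrt(s1^2/n1 + s2^2/n2)`` with unbiased sample
    variances; significance at ``|z| > threshold`` (default 1.96, p < 0.05).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need at least 2 values")
    se2 = g1.var(ddof=1) / len(g1) + g2.var(ddof=1) / len(g2)
    if se2 <= 0:
        raise ValueError("zero variance in both groups; z undefined")
    z = float((g1.mean() - g2.mean()) / math.sqrt(se2))
    return ZTestResult(z=z, significant=abs(z) > threshold)
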