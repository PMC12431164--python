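"""Evaluation metrics: ROC AUC and F1 at the ROC-optimal threshold.

The AUC is the Mann-Whitney probability (ties counted 1/2), identical to the
trapezoidal area under the empirical ROC curve.  The operating threshold is
chosen to maximise sensitivity^2 + specificity^2 over the ROC's candidate
thresholds (the distinct scores plus one value above the maximum); ties are
broken toward the largest threshold, i.e. the fewest predicted positives.
The F1-score is reported for the positive (readmitted) class at that
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("labels contain a single class")
    return y


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney probability, ties 1/2)."""
    y = _check_two_classes(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def f1_at_threshold(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """F1 for the positive class with prediction rule score >= threshold."""
    y = _check_two_classes(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    if tp == 0 and fp == 0 and fn == 0:  # no actual and no predicted positives
        raise ValueError("F1 undefined: no actual or predicted positives")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def optimal_threshold_f1(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(threshold, F1) at the ROC point maximising sens^2 + spec^2.

    Candidate thresholds are every distinct score plus one value above the
    maximum (no predicted positives); among ties the largest threshold wins.
    """
    y = _check_two_classes(labels)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    objective = tpr**2 + (1.0 - fpr) ** 2
    best = int(np.argmax(objective))  # thresholds descend -> first max = largest
    thr = float(thresholds[best])
    return thr, f1_at_threshold(s, y, thr)


@dataclass
class MetricResult:
    """Per-replication AUC / F1 / threshold vectors with their averages."""

    aucs: np.ndarray
    f1s: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.aucs = np.asarray(self.aucs, dtype=float)
        self.f1s = np.asarray(self.f1s, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)

    @property
    def n_reps(self) -> int:
        return len(self.aucs)

    @property
    def auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def f1(self) -> float:
        return float(np.mean(self.f1s))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if self.n_reps > 1 else 0.0

    @property
    def f1_sd(self) -> float:
        return float(np.std(self.f1s, ddof=1)) if self.n_reps > 1 else 0.0
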