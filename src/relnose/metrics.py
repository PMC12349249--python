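"""Evaluation statistics: confusion matrix, accuracy, macro F1, and
t-distribution confidence half-widths.

A run of repeated tests yields accuracies a_1..a_n and F1 scores f_1..f_n;
besides their means, the dispersion is summarized by ``h``, the half-width
of the 95% confidence interval under a t distribution with n - 1 degrees
of freedom: h = (sigma / sqrt(n)) * t_{0.975, n-1}, with sigma the sample
(n - 1) standard deviation.  Small h means the model's performance is
stable across repeated tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RunStatistics:
    """Aggregate of repeated tests: means and 95% CI half-widths."""

    mean_accuracy: float
    h_accuracy: float
    mean_f1: float
    h_f1: float


def confusion(y_true: Sequence, y_pred: Sequence, classes: Sequence) -> np.ndarray:
    """Confusion matrix with rows = predicted class, columns = reference."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        cm[index[p], index[t]] += 1
    return cm


def accuracy(cm: np.ndarray) -> float:
    """Fraction of correct predictions: trace / total.  In the binary case
    this is (TP + TN) / (TP + TN + FP + FN)."""
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def _per_class_prf(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=1) - tp          # predicted c, reference other
    fn = cm.sum(axis=0) - tp          # reference c, predicted other
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    return precision, recall, f1


def macro_f1(cm: np.ndarray, average: str = "macro") -> float:
    """One-vs-rest F1 averaged over classes.

    ``macro`` (default) weights every class equally — appropriate when the
    test classes are imbalanced; ``weighted`` weights by reference support;
    ``micro`` pools counts (equal to accuracy for single-label tasks).
    """
    if cm.size == 0 or cm.shape[0] < 2:
        raise ValueError("confusion matrix must cover at least two classes")
    precision, recall, f1 = _per_class_prf(cm)
    if average == "macro":
        return float(f1.mean())
    if average == "weighted":
        support = cm.sum(axis=0)
        total = support.sum()
        return float((f1 * support).sum() / total) if total else 0.0
    if average == "micro":
        return accuracy(cm)
    raise ValueError(f"unknown average {average!r}")


def mean_and_h(values: Sequence[float], confidence: float = 0.95) -> tuple[float, float]:
    """Mean and t-interval half-width of repeated measurements.

    With a single measurement the half-width is undefined; it is reported
    as 0 with a warning rather than raising.
    """
    # sorting makes the result exactly permutation-invariant
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if n == 0:
        raise ValueError("need at least one value")
    mean = float(values.mean())
    if n == 1:
        warnings.warn("half-width undefined for a single measurement; reporting 0",
                      stacklevel=2)
        return mean, 0.0
    if values[0] == values[-1]:      # constant measurements: no dispersion
        return mean, 0.0
    sem = float(values.std(ddof=1)) / np.sqrt(n)
    quantile = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    return mean, float(sem * quantile)


def run_statistics(accuracies: Sequence[float], f1_scores: Sequence[float],
                   confidence: float = 0.95) -> RunStatistics:
    mean_a, h_a = mean_and_h(accuracies, confidence)
    mean_f, h_f = mean_and_h(f1_scores, confidence)
    return RunStatistics(mean_a, h_a, mean_f, h_f)
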