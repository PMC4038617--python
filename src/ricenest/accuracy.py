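"""Thematic-map accuracy assessment.

Confusion matrix against reference plots, overall accuracy, Cohen's kappa,
per-class producer's/user's accuracy, and the McNemar paired test for
comparing two classifiers on the same reference sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import DEFAULT_SCHEME, ClassScheme

__all__ = [
    "ConfusionMatrix",
    "AccuracyMetrics",
    "McNemarResult",
    "confusion_matrix",
    "accuracy_metrics",
    "mcnemar_test",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = reference class, columns = predicted class."""

    counts: np.ndarray
    scheme: ClassScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        n = self.scheme.n_classes
        if c.shape != (n, n):
            raise ValueError(f"confusion matrix must be {n}x{n}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(
    reference: np.ndarray, predicted: np.ndarray, scheme: ClassScheme = DEFAULT_SCHEME
) -> ConfusionMatrix:
    """Tabulate counts[i, j] = number of plots with reference i predicted j."""
    ref = np.asarray(reference, dtype=int)
    pred = np.asarray(predicted, dtype=int)
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted labels must have equal length")
    n = scheme.n_classes
    if ref.size == 0:
        warnings.warn("empty label vectors: all-zero confusion matrix", stacklevel=2)
        return ConfusionMatrix(np.zeros((n, n), dtype=int), scheme)
    if ref.min() < 0 or ref.max() >= n or pred.min() < 0 or pred.max() >= n:
        raise ValueError("labels outside the class scheme")
    counts = np.zeros((n, n), dtype=int)
    np.add.at(counts, (ref, pred), 1)
    return ConfusionMatrix(counts, scheme)


@dataclass
class AccuracyMetrics:
    overall: float
    kappa: float
    producers: dict[str, float | None]  # None where the reference marginal is zero
    users: dict[str, float | None]  # None where the predicted marginal is zero


def accuracy_metrics(cm: ConfusionMatrix) -> AccuracyMetrics:
    """Overall accuracy, Cohen's kappa, producer's and user's accuracy.

    kappa = (p_o − p_e) / (1 − p_e) with p_e the chance agreement from the
    row and column marginals. Producer's accuracy for class j is the correct
    fraction of its reference plots (1 − omission); user's accuracy is the
    correct fraction of its predictions (1 − commission). Classes with a zero
    marginal have the corresponding metric undefined (reported as None).
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix: metrics undefined")
    p_o = np.trace(c) / total
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    p_e = float(np.sum(row * col)) / total**2
    kappa = 1.0 if p_e == 1.0 and p_o == 1.0 else (p_o - p_e) / (1.0 - p_e)
    diag = np.diag(c)
    producers = {
        name: (float(diag[j] / row[j]) if row[j] > 0 else None)
        for j, name in enumerate(cm.scheme.names)
    }
    users = {
        name: (float(diag[j] / col[j]) if col[j] > 0 else None)
        for j, name in enumerate(cm.scheme.names)
    }
    return AccuracyMetrics(float(p_o), float(kappa), producers, users)


@dataclass
class McNemarResult:
    statistic: float | None  # None when there are no discordant pairs
    p_value: float
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct


def mcnemar_test(
    correct_a: np.ndarray, correct_b: np.ndarray, continuity_correction: bool = False
) -> McNemarResult:
    """McNemar chi-square test on the discordant pairs of two classifiers.

    ``correct_a``/``correct_b`` mark, plot by plot on the same reference
    sample, whether each classifier was right. chi2 = (b − c)^2 / (b + c) on
    1 df (by default without continuity correction; pass
    ``continuity_correction=True`` for (|b − c| − 1)^2 / (b + c)). With no
    discordant pairs the statistic is undefined and p = 1.
    """
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError("correctness vectors must have equal length")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    if b + c == 0:
        return McNemarResult(None, 1.0, b, c)
    diff = abs(b - c) - 1 if continuity_correction else b - c
    diff = max(diff, 0) if continuity_correction else diff
    chi2 = float(diff * diff) / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(chi2, p, b, c)
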