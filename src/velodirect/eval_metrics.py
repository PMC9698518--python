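"""Confusion-matrix metrics: accuracy, macro precision/recall/F1, Cohen's kappa.

Macro-F1 here is the harmonic mean of the macro-averaged precision and the
macro-averaged recall, 2*P_macro*R_macro/(P_macro + R_macro).  Note this is
NOT the average of per-class F1 scores (the other common convention, e.g.
sklearn's ``f1_score(average="macro")``); the two differ whenever per-class
precision/recall are unbalanced.

Cohen's kappa is ``(p0 - pe)/(1 - pe)`` with observed agreement
``p0 = trace/n`` and chance agreement ``pe = sum_i a_i*b_i / n^2`` from the
row (true) and column (predicted) marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from velodirect.errors import ConfigError, ShapeError


@dataclass
class ConfusionMatrix:
    """C x C counts; rows index true class, columns predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ShapeError("confusion matrix must be square")
        if np.any(c < 0):
            raise ConfigError("confusion counts must be nonnegative")
        self.counts = c.astype(np.int64)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def true_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def pred_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    kappa: float
    per_class_precision: np.ndarray = field(repr=False, default=None)
    per_class_recall: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
        }


def confusion(true_labels, predicted_labels, n_classes: int | None = None) -> ConfusionMatrix:
    """Tally ``counts[i, j] = #{true == i and pred == j}``."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ShapeError("label vectors must be 1-D and equal length")
    if n_classes is None:
        n_classes = int(max(t.max(initial=-1), p.max(initial=-1))) + 1
    if t.size and (t.min() < 0 or p.min() < 0 or t.max() >= n_classes or p.max() >= n_classes):
        raise ConfigError(f"labels out of range [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace / n."""
    if cm.n == 0:
        raise ConfigError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.n


def _macro_pr(cm: ConfusionMatrix) -> tuple[float, float, np.ndarray, np.ndarray]:
    tp = np.diag(cm.counts).astype(float)
    pred = cm.pred_marginals.astype(float)   # TP + FP per class
    true = cm.true_marginals.astype(float)   # TP + FN per class
    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = np.where(pred > 0, tp / pred, 0.0)
        r_i = np.where(true > 0, tp / true, 0.0)
    if np.any(pred == 0):
        warnings.warn("class(es) never predicted: precision treated as 0")
    if np.any(true == 0):
        warnings.warn("class(es) absent from truth: recall treated as 0")
    return float(p_i.mean()), float(r_i.mean()), p_i, r_i


def macro_f1(cm: ConfusionMatrix) -> float:
    """Harmonic mean of macro-averaged precision and macro-averaged recall."""
    p_macro, r_macro, _, _ = _macro_pr(cm)
    if p_macro + r_macro == 0:
        return 0.0
    return 2 * p_macro * r_macro / (p_macro + r_macro)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa, chance-corrected agreement from the marginals."""
    n = cm.n
    if n == 0:
        raise ConfigError("empty confusion matrix")
    p0 = float(np.trace(cm.counts)) / n
    pe = float(cm.true_marginals @ cm.pred_marginals) / (n * n)
    if pe >= 1.0:
        warnings.warn("degenerate single-class agreement (pe = 1); kappa defined as 0")
        return 0.0
    return (p0 - pe) / (1.0 - pe)


def compute_report(true_labels, predicted_labels, n_classes: int | None = None) -> MetricsReport:
    """All printed metrics from raw label vectors."""
    cm = confusion(true_labels, predicted_labels, n_classes)
    p_macro, r_macro, p_i, r_i = _macro_pr(cm)
    f1 = 0.0 if p_macro + r_macro == 0 else 2 * p_macro * r_macro / (p_macro + r_macro)
    return MetricsReport(
        accuracy=accuracy(cm),
        macro_precision=p_macro,
        macro_recall=r_macro,
        macro_f1=f1,
        kappa=kappa(cm),
        per_class_precision=p_i,
        per_class_recall=r_i,
    )
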