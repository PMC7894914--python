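"""Classification metrics: confusion matrix, per-class statistics, R_K.

The confusion matrix convention is fixed throughout the package: rows are
the *actual* class, columns the *predicted* class, class order
(low, medium, high).  R_K is symmetric under transposition but precision
and recall are not, so the orientation matters.

R_K is Gorodkin's multiclass generalisation of the Pearson/Matthews
correlation, computed directly from a K x K confusion matrix C with total
N, diagonal sum c, row sums t (actual) and column sums p (predicted):

    R_K = (c * N - t . p) / sqrt((N^2 - p . p) * (N^2 - t . t))

Values lie in [-1, 1]; by common practice a correlation above 0.7 is
considered satisfactory.  When either denominator factor vanishes (only one
class observed on one side) the value is defined as 0, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import N_CLASSES, RISK_NAMES

__all__ = ["confusion", "class_metrics", "r_k", "accuracy", "MetricsReport"]


def confusion(actual, predicted, n_classes: int = N_CLASSES) -> np.ndarray:
    """Count matrix C with C[a][p] = number of trials of actual class a
    predicted as p."""
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if actual.shape != predicted.shape:
        raise ValueError("label sequences must have equal length")
    for name, arr in (("actual", actual), ("predicted", predicted)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside 0..{n_classes - 1}")
    c = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(c, (actual, predicted), 1)
    return c


def _validate_matrix(c) -> np.ndarray:
    c = np.asarray(c)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (c < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    if c.sum() == 0:
        raise ValueError("confusion matrix is empty")
    return c.astype(np.float64)


def accuracy(c) -> float:
    c = _validate_matrix(c)
    return float(np.trace(c) / c.sum())


def r_k(c) -> float:
    """Discretised Gorodkin R_K correlation of a confusion matrix."""
    c = _validate_matrix(c)
    n = c.sum()
    t = c.sum(axis=1)  # actual-class totals
    p = c.sum(axis=0)  # predicted-class totals
    cov_tp = np.trace(c) * n - t @ p
    var_p = n * n - p @ p
    var_t = n * n - t @ t
    if var_p <= 0 or var_t <= 0:
        warnings.warn(
            "degenerate confusion matrix (single observed class); R_K set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(cov_tp / np.sqrt(var_p * var_t))


@dataclass
class MetricsReport:
    """Per-class and overall statistics of one confusion matrix."""

    confusion_matrix: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f_measure: np.ndarray
    accuracy: float
    r_k: float
    class_names: tuple = field(default=RISK_NAMES)

    def to_dict(self, digits: int | None = None) -> dict:
        def r(x):
            return round(float(x), digits) if digits is not None else float(x)

        return {
            "confusion_matrix": np.asarray(self.confusion_matrix).tolist(),
            "per_class": {
                name: {
                    "tp": int(self.tp[k]),
                    "fp": int(self.fp[k]),
                    "fn": int(self.fn[k]),
                    "precision": r(self.precision[k]),
                    "recall": r(self.recall[k]),
                    "f_measure": r(self.f_measure[k]),
                }
                for k, name in enumerate(self.class_names)
            },
            "accuracy": r(self.accuracy),
            "r_k": r(self.r_k),
        }


def _safe_div(num, den, what):
    out = np.zeros_like(num, dtype=np.float64)
    bad = den == 0
    if bad.any():
        warnings.warn(
            f"{what}: division by zero for class(es) {np.flatnonzero(bad).tolist()}; "
            "value set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    np.divide(num, den, out=out, where=~bad)
    return out


def class_metrics(c, class_names: tuple = RISK_NAMES) -> MetricsReport:
    """Precision, recall and F-measure per class plus accuracy and R_K.

    Precision = TP / (TP + FP), Recall = TP / (TP + FN), F = harmonic mean
    of the two; accuracy = trace / total.  Zero denominators yield 0 with a
    warning.
    """
    cm = _validate_matrix(c)
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f = _safe_div(2.0 * precision * recall, precision + recall, "f_measure")
    return MetricsReport(
        confusion_matrix=np.asarray(c),
        tp=tp.astype(np.int64),
        fp=fp.astype(np.int64),
        fn=fn.astype(np.int64),
        precision=precision,
        recall=recall,
        f_measure=f,
        accuracy=accuracy(c),
        r_k=r_k(c),
        class_names=tuple(class_names),
    )
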