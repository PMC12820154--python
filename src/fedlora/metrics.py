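"""Classification metrics, ROC/PR analysis with Youden's J operating point,
and communication-cost accounting.

Accuracy, precision, recall and F1 are computed from the confusion matrix:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the positive class being pneumonia, and the same formulas with roles
swapped for the normal class.  Zero denominators yield 0 with a degeneracy
flag.  Percentages are formatted to two decimals, round-half-up.

Communication cost converts a transmitted parameter count to megabytes under
two conventions: ``decimal_eq12`` (bytes / 1e6) and ``binary_mib``
(bytes / 2^20).  The published per-round payloads (21.64 / 0.56 MB) are the
binary-convention values; the decimal convention gives 0.59 MB for the
adapter state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata

from .errors import ShapeError, UndefinedMetricError

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "classification_metrics",
    "roc_auc",
    "pr_average_precision",
    "youden_threshold",
    "communication_cost",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round-half-up to the given decimals (matches printed percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = pneumonia (label 1)."""

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


@dataclass
class MetricReport:
    accuracy: float
    per_class: dict[str, dict[str, float]]
    degenerate: list[str] = field(default_factory=list)
    auc_roc: float | None = None
    average_precision: float | None = None
    optimal_threshold: float | None = None

    def percent(self, cls: str, metric: str) -> float:
        """A per-class rate as a percentage to 2 decimals (round-half-up)."""
        value = self.accuracy if metric == "accuracy" else self.per_class[cls][metric]
        return round_half_up(100.0 * value)


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ShapeError("labels/predictions must be binary 0/1")
    return y.astype(int)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    y_true, y_pred = _check_binary(y_true), _check_binary(y_pred)
    if y_true.shape != y_pred.shape:
        raise ShapeError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy plus precision/recall/F1 for both classes.

    For the normal class the confusion roles swap: TN acts as the "true
    positive" count, so normal precision is TN / (TN + FN) and normal recall
    (specificity) is TN / (TN + FP).
    """
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    flags: list[str] = []
    acc = (cm.tp + cm.tn) / cm.total
    per_class = {}
    for cls, tp_, fp_, fn_ in (
        ("pneumonia", cm.tp, cm.fp, cm.fn),
        ("normal", cm.tn, cm.fn, cm.fp),
    ):
        prec = _safe_div(tp_, tp_ + fp_, flags, f"{cls}.precision")
        rec = _safe_div(tp_, tp_ + fn_, flags, f"{cls}.recall")
        f1 = _safe_div(2 * prec * rec, prec + rec, flags, f"{cls}.f1")
        per_class[cls] = {"precision": prec, "recall": rec, "f1": f1}
    return MetricReport(accuracy=acc, per_class=per_class, degenerate=flags)


def _check_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ShapeError("scores and labels must have equal length")
    if labels.min() == labels.max():
        raise UndefinedMetricError("both classes must be present")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) method; ties contribute one half."""
    scores, labels = _check_scores(scores, labels)
    ranks = rankdata(scores)  # average ranks handle ties
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pr_average_precision(scores, labels) -> float:
    """AP = sum over descending thresholds of (recall step) * precision."""
    scores, labels = _check_scores(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = y.sum()
    tp = fp = 0
    ap = 0.0
    prev_recall = 0.0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # process tied scores together
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(ap)


def youden_threshold(scores, labels) -> tuple[float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Predictions are positive at score >= threshold; candidate thresholds are
    the observed scores and ties in J break toward the higher threshold.
    """
    scores, labels = _check_scores(scores, labels)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):  # ascending: later candidates win J ties
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1
        if j >= best_j:
            best_t, best_j = float(t), float(j)
    return best_t, best_j


def communication_cost(
    param_count: int, bit_precision: int = 32, convention: str = "binary_mib"
) -> float:
    """Megabytes for one transmission of ``param_count`` parameters.

    ``decimal_eq12``: parameters x bits / (8 x 10^6).
    ``binary_mib``:   parameters x bits / (8 x 2^20) — the convention the
    published payload table uses.  Returns the raw value; use
    :func:`round_half_up` for 2-decimal display.
    """
    if param_count < 0:
        raise ValueError("param_count must be >= 0")
    if bit_precision not in (16, 32, 64):
        raise ValueError("bit_precision must be 16, 32 or 64")
    byte_count = param_count * bit_precision / 8
    if convention == "decimal_eq12":
        return byte_count / 1e6
    if convention == "binary_mib":
        return byte_count / 2**20
    raise ValueError(f"unknown convention {convention!r}")
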