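"""Evaluation statistics: confusion counts, accuracy, P/R/F1, ARI, ROC, PRC.

Per-class metrics are one-vs-rest; an ``"unknown"`` prediction counts as a
negative for every real class.  The F1 default aggregation is the macro
(unweighted) mean, the usual choice when rare cell types matter as much as
abundant ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .errors import ValidationError


@dataclass
class ClassCounts:
    tp: int
    fp: int
    fn: int
    tn: int


def confusion_counts(
    y_true: Sequence[str], y_pred: Sequence[str], class_names: Sequence[str]
) -> dict[str, ClassCounts]:
    """One-vs-rest TP/FP/FN/TN per class."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred differ in length")
    out: dict[str, ClassCounts] = {}
    for c in class_names:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        tn = len(y_true) - tp - fp - fn
        out[c] = ClassCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    return out


def accuracy(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    """Fraction of cells whose predicted label equals the true label."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true:
        raise ValidationError("cannot compute accuracy of an empty label set")
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred differ in length")
    return sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (0/0); returning 0", stacklevel=3)
        return 0.0
    return num / den


def precision_recall_f1(
    counts: dict[str, ClassCounts], averaging: str = "macro"
) -> dict:
    """Precision, recall, and F1 from one-vs-rest counts.

    ``averaging="per_class"`` returns a per-class mapping;
    ``averaging="macro"`` additionally reports unweighted means.
    """
    per_class = {}
    for c, k in counts.items():
        p = _safe_div(k.tp, k.tp + k.fp, f"precision[{c}]")
        r = _safe_div(k.tp, k.tp + k.fn, f"recall[{c}]")
        f1 = _safe_div(2 * p * r, p + r, f"F1[{c}]")
        per_class[c] = {"precision": p, "recall": r, "f1": f1}
    if averaging == "per_class":
        return per_class
    if averaging != "macro":
        raise ValidationError(f"unknown averaging {averaging!r}")
    n = len(per_class)
    return {
        "per_class": per_class,
        "macro_precision": sum(v["precision"] for v in per_class.values()) / n,
        "macro_recall": sum(v["recall"] for v in per_class.values()) / n,
        "macro_f1": sum(v["f1"] for v in per_class.values()) / n,
    }


def contingency_table(
    labels_a: Sequence, labels_b: Sequence
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts n_jj' of cells in cluster j of partition a and j' of partition b,
    with row margins a_j and column margins b_j'."""
    cats_a = sorted(set(labels_a), key=str)
    cats_b = sorted(set(labels_b), key=str)
    ia = {c: i for i, c in enumerate(cats_a)}
    ib = {c: i for i, c in enumerate(cats_b)}
    table = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        table[ia[a], ib[b]] += 1
    return table, table.sum(axis=1), table.sum(axis=0)


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two partitions of the same cells.

    Symmetric and invariant to relabeling; 1 for identical partitions,
    around 0 for independent ones.
    """
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValidationError("partitions differ in length")
    if len(labels_a) < 2:
        raise ValidationError("ARI needs at least two cells")
    return float(adjusted_rand_score([str(x) for x in labels_a], [str(x) for x in labels_b]))


def roc_curve_and_auc(
    scores: Sequence[float], truth: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC curve and trapezoid AUC.

    Thresholds sweep the unique scores from high to low; the curve starts at
    (0, 0) and ends at (1, 1).  AUC is the trapezoid sum
    (1/2) * sum (x_{i+1} - x_i)(y_i + y_{i+1}).
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.int64)
    n_pos = int(truth.sum())
    n_neg = int(len(truth) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = truth[order]
    tp = np.cumsum(t_sorted)
    fp = np.cumsum(1 - t_sorted)
    # keep one point per unique score (the last index of each score block)
    last = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    auc = float(0.5 * np.sum((fpr[1:] - fpr[:-1]) * (tpr[1:] + tpr[:-1])))
    return fpr, tpr, auc


def macro_auc(probabilities: np.ndarray, y_true: Sequence[str], class_names: Sequence[str]) -> float:
    """Unweighted mean one-vs-rest AUC over classes present in the truth."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    aucs = []
    for j, c in enumerate(class_names):
        truth = np.asarray([1 if t == c else 0 for t in y_true])
        if truth.sum() == 0 or truth.sum() == len(truth):
            continue
        aucs.append(roc_curve_and_auc(probabilities[:, j], truth)[2])
    if not aucs:
        raise ValidationError("no class has both positives and negatives")
    return float(np.mean(aucs))


def precision_recall_curve(
    scores: Sequence[float], truth: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision and recall at each unique score threshold, high to low.

    Returns (precision, recall, thresholds); a prediction is positive when
    its score is >= the threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.int64)
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ValidationError("precision-recall curve needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = truth[order]
    tp = np.cumsum(t_sorted)
    pred_pos = np.arange(1, len(scores) + 1)
    last = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    precision = tp[last] / pred_pos[last]
    recall = tp[last] / n_pos
    return precision, recall, s_sorted[last]
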