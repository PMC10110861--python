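"""Probability prediction, open-set rejection, and threshold sweeps.

A trained model only knows the cell types it saw during training.  Cells of
an unseen ("pseudo") type tend to receive a flat probability vector, so any
cell whose maximum softmax probability falls below a threshold (0.97 by
default) is labeled ``"unknown"`` instead of being forced into a known type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .errors import ValidationError
from .model import TrainedModel

UNKNOWN_LABEL = "unknown"
DEFAULT_THRESHOLD = 0.97


@dataclass
class PredictionResult:
    """Per-cell probabilities, arg-max labels, and the rejection threshold used."""

    cell_ids: list[str]
    probabilities: np.ndarray
    predicted_labels: list[str]
    class_names: list[str]
    threshold: float


def predict_proba(model: TrainedModel, X: ExpressionMatrix) -> np.ndarray:
    """Class-probability matrix for a normalized, gene-aligned query.

    Dropout is disabled, so repeated calls are bit-identical.
    """
    if not X.normalized:
        raise ValidationError("query matrix must be normalized before prediction")
    if X.gene_ids != model.gene_ids:
        model_set = set(X.gene_ids)
        for g in model.gene_ids:
            if g not in model_set:
                raise ValidationError(
                    f"query is missing model gene {g!r}; run align_genes and "
                    "apply_gene_filter first"
                )
        raise ValidationError("query gene order differs from the model's gene list")
    return model.predict_proba_values(X.values)


def predict_with_rejection(
    probabilities: np.ndarray,
    class_names: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[str]:
    """Arg-max labels with sub-threshold rows rejected as ``"unknown"``.

    A cell is rejected iff its maximum probability is strictly below the
    threshold; arg-max ties resolve to the lowest class index.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold must lie in [0, 1], got {threshold}")
    probabilities = np.asarray(probabilities, dtype=np.float64)
    best = probabilities.argmax(axis=1)
    best_p = probabilities[np.arange(len(best)), best]
    return [
        class_names[j] if p >= threshold else UNKNOWN_LABEL
        for j, p in zip(best, best_p)
    ]


def predict(
    model: TrainedModel, X: ExpressionMatrix, threshold: float = DEFAULT_THRESHOLD
) -> PredictionResult:
    """Full prediction: probabilities plus rejection-aware labels."""
    probs = predict_proba(model, X)
    labels = predict_with_rejection(probs, model.class_names, threshold)
    return PredictionResult(
        cell_ids=list(X.cell_ids),
        probabilities=probs,
        predicted_labels=labels,
        class_names=list(model.class_names),
        threshold=threshold,
    )


def default_threshold_grid() -> np.ndarray:
    """The default rejection sweep: 0.89 to 0.998 in steps of 0.002 (55 values)."""
    return np.round(np.arange(445, 500) * 0.002, 3)


def open_set_accuracy(
    y_true: Sequence[str],
    predicted: Sequence[str],
    known_classes: Sequence[str],
) -> float:
    """Accuracy where a cell of a type absent from training counts as correct
    iff it was rejected as ``"unknown"``; rejecting a known-type cell counts
    as incorrect."""
    known = set(known_classes)
    correct = 0
    for t, p in zip(y_true, predicted):
        if t in known:
            correct += t == p
        else:
            correct += p == UNKNOWN_LABEL
    return correct / len(list(y_true))


def sweep_threshold(
    probabilities: np.ndarray,
    y_true: Sequence[str],
    class_names: Sequence[str],
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Open-set accuracy and rejection count for each threshold.

    ``y_true`` may contain types absent from ``class_names``; those cells are
    scored correct only when rejected.  Returns a DataFrame with columns
    ``threshold``, ``accuracy``, ``n_unknown``.
    """
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = list(thresholds)
    if not thresholds:
        raise ValidationError("threshold list is empty")
    rows = []
    for t in thresholds:
        labels = predict_with_rejection(probabilities, class_names, t)
        rows.append(
            {
                "threshold": float(t),
                "accuracy": open_set_accuracy(y_true, labels, class_names),
                "n_unknown": labels.count(UNKNOWN_LABEL),
            }
        )
    return pd.DataFrame(rows)
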