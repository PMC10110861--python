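"""End-to-end training pipeline shared by the CLI, tests, and scripts.

Order of operations: split cell indices (stratified by type), fit the gene
filter on the training cells only, then filter + CPM/log-normalize every
partition with the training-derived filter, fit the model on train with
validation-based checkpoint selection, and score the held-back test cells.
Fitting the filter after the split keeps test information out of the gene
list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metrics as M
from .data_io import ExpressionMatrix, LabelVector
from .model import ModelConfig, TrainedModel, TrainingHistory, build_model, train
from .preprocess import (
    SplitSpec,
    apply_gene_filter,
    fit_gene_filter,
    normalize_cpm_log,
    split_dataset,
)


@dataclass
class TrainResult:
    model: TrainedModel
    history: TrainingHistory
    test_metrics: dict
    splits: tuple[np.ndarray, np.ndarray, np.ndarray]
    normalized: ExpressionMatrix
    labels: LabelVector


def evaluate_predictions(
    y_true: list[str],
    y_pred: list[str],
    class_names: list[str],
    probabilities: np.ndarray | None = None,
) -> dict:
    """Standard evaluation bundle: ACC, macro P/R/F1, ARI, macro AUC."""
    counts = M.confusion_counts(y_true, y_pred, class_names)
    prf = M.precision_recall_f1(counts, averaging="macro")
    out = {
        "accuracy": M.accuracy(y_true, y_pred),
        "macro_precision": prf["macro_precision"],
        "macro_recall": prf["macro_recall"],
        "macro_f1": prf["macro_f1"],
        "ari": M.adjusted_rand_index(y_true, y_pred),
        "per_class": prf["per_class"],
        "n_cells": len(y_true),
    }
    if probabilities is not None:
        out["macro_auc"] = M.macro_auc(probabilities, y_true, class_names)
    return out


def train_pipeline(
    raw: ExpressionMatrix,
    labels: LabelVector,
    model_config: ModelConfig,
    split_spec: SplitSpec | None = None,
    min_nonzero_cells: int | None = None,
    epochs: int | None = None,
) -> TrainResult:
    """Filter, normalize, split, train, and evaluate in one call.

    ``min_nonzero_cells`` defaults to the standard 200-cell gene filter,
    scaled down implicitly by passing a smaller value for small matrices.
    """
    labels = labels.aligned_to(raw)
    spec = split_spec or SplitSpec(seed=model_config.seed)
    train_idx, val_idx, test_idx = split_dataset(raw, labels, spec)

    threshold = 200 if min_nonzero_cells is None else min_nonzero_cells
    train_raw = ExpressionMatrix(
        values=raw.values[train_idx],
        gene_ids=list(raw.gene_ids),
        cell_ids=[raw.cell_ids[i] for i in train_idx],
        normalized=False,
    )
    gene_filter = fit_gene_filter(train_raw, min_nonzero_cells=threshold)
    norm = normalize_cpm_log(apply_gene_filter(gene_filter, raw))

    y = np.asarray(labels.labels)
    class_names = sorted(set(y[train_idx]))
    model = build_model(
        model_config,
        gene_ids=norm.gene_ids,
        class_names=class_names,
    )
    fitted, history = train(
        model,
        (norm.values[train_idx], list(y[train_idx])),
        (norm.values[val_idx], list(y[val_idx])),
        epochs=epochs,
    )

    probs = fitted.predict_proba_values(norm.values[test_idx])
    pred = [fitted.class_names[j] for j in probs.argmax(axis=1)]
    test_metrics = evaluate_predictions(
        list(y[test_idx]), pred, fitted.class_names, probabilities=probs
    )
    return TrainResult(
        model=fitted,
        history=history,
        test_metrics=test_metrics,
        splits=(train_idx, val_idx, test_idx),
        normalized=norm,
        labels=labels,
    )
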