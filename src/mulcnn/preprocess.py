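"""Gene filtering, CPM/log normalization, dataset splitting, and the 2D gene embedding.

The preprocessing chain for a labeled reference is::

    filter = fit_gene_filter(raw, min_nonzero_cells=200)   # on training data
    X = normalize_cpm_log(apply_gene_filter(filter, raw))  # CPM x 10,000, ln(1+x)
    train, val, test = split_dataset(X, y, SplitSpec(seed=...))
    images = embed_matrix(X.values)                        # one square image per cell

The filter is fit once on reference/training data and then applied to every
partition and query so that no information leaks across the split and every
cell maps onto the same image layout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, LabelVector
from .errors import ValidationError

DEFAULT_MIN_NONZERO_CELLS = 200
DEFAULT_CPM_SCALE = 10_000.0


@dataclass
class GeneFilter:
    """Genes retained after the minimum-nonzero-cells filter, in fit order."""

    min_nonzero_cells: int
    kept_gene_ids: list[str]


@dataclass
class GeneImage:
    """One cell's expression vector laid out row-major on a square grid.

    The side is ``ceil(sqrt(F))`` for ``F`` source genes; positions past the
    first ``F`` (row-major) are zero padding.
    """

    matrix: np.ndarray
    source_gene_count: int

    @property
    def side(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SplitSpec:
    """Train/validation/test fractions, seed, and stratification flag."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if len(self.fractions) != 3:
            raise ValidationError("exactly three split fractions are required")
        if any(not (0.0 < f < 1.0) for f in self.fractions):
            raise ValidationError("each split fraction must lie strictly in (0, 1)")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")


def fit_gene_filter(
    X: ExpressionMatrix, min_nonzero_cells: int = DEFAULT_MIN_NONZERO_CELLS
) -> GeneFilter:
    """Keep genes expressed (value > 0) in at least ``min_nonzero_cells`` cells.

    The cutoff is strict on the low side: a gene seen in exactly
    ``min_nonzero_cells - 1`` cells is discarded.
    """
    if X.normalized:
        raise ValidationError("gene filter must be fit on raw counts")
    nonzero_cells = np.count_nonzero(X.values > 0, axis=0)
    keep = nonzero_cells >= min_nonzero_cells
    if not keep.any():
        raise ValidationError(
            f"no gene is expressed in >= {min_nonzero_cells} cells; "
            "lower min_nonzero_cells"
        )
    kept = [g for g, k in zip(X.gene_ids, keep) if k]
    return GeneFilter(min_nonzero_cells=min_nonzero_cells, kept_gene_ids=kept)


def apply_gene_filter(filter: GeneFilter, X: ExpressionMatrix) -> ExpressionMatrix:
    """Restrict ``X`` to the filter's kept genes, in stored order."""
    return X.subset_genes(filter.kept_gene_ids)


def normalize_cpm_log(X: ExpressionMatrix, scale: float = DEFAULT_CPM_SCALE) -> ExpressionMatrix:
    """Per-cell depth normalization followed by a natural-log transform.

    Each count is divided by its cell's total, multiplied by ``scale``
    (default 10,000), then mapped through ``ln(1 + x)``.  Before the log step
    every cell's values sum to exactly ``scale``.  Zero counts stay zero.
    """
    if X.normalized:
        raise ValidationError("matrix is already normalized")
    totals = X.values.sum(axis=1)
    zero_cells = [c for c, t in zip(X.cell_ids, totals) if t == 0]
    if zero_cells:
        raise ValidationError(
            "cells with zero total count cannot be normalized: "
            + ", ".join(zero_cells[:10])
        )
    cpm = X.values / totals[:, None] * scale
    return ExpressionMatrix(
        values=np.log1p(cpm),
        gene_ids=list(X.gene_ids),
        cell_ids=list(X.cell_ids),
        normalized=True,
    )


def split_dataset(
    X: ExpressionMatrix, y: LabelVector, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition cell indices into train/val/test index arrays.

    Validation and test receive ``round(n * fraction)`` cells each and the
    remainder goes to train.  With ``stratified=True`` (the default) the
    allocation is done per cell type so rare types appear in every partition;
    a type with fewer cells than partitions falls back entirely into train
    with a warning.
    """
    if X.n_cells != len(y):
        raise ValidationError("matrix rows and label vector differ in length")
    rng = np.random.default_rng(spec.seed)
    labels = np.asarray(y.labels)
    train: list[np.ndarray] = []
    val: list[np.ndarray] = []
    test: list[np.ndarray] = []

    if spec.stratified:
        groups = [np.flatnonzero(labels == t) for t in sorted(set(labels))]
    else:
        groups = [np.arange(X.n_cells)]

    for idx in groups:
        if spec.stratified and len(idx) < 3:
            warnings.warn(
                f"cell type {labels[idx[0]]!r} has only {len(idx)} cells; "
                "placing all of them in the training set",
                stacklevel=2,
            )
            train.append(idx)
            continue
        perm = rng.permutation(idx)
        n = len(perm)
        n_val = int(round(n * spec.fractions[1]))
        n_test = int(round(n * spec.fractions[2]))
        test.append(perm[:n_test])
        val.append(perm[n_test : n_test + n_val])
        train.append(perm[n_test + n_val :])

    def _gather(parts: list[np.ndarray]) -> np.ndarray:
        if not parts:
            return np.array([], dtype=np.intp)
        return np.sort(np.concatenate(parts)).astype(np.intp)

    return _gather(train), _gather(val), _gather(test)


def image_side(n_genes: int) -> int:
    """Side length of the square gene image for ``n_genes`` genes."""
    if n_genes < 1:
        raise ValidationError("at least one gene is required")
    return math.ceil(math.sqrt(n_genes))


def embed_to_gene_image(row: np.ndarray, expected_genes: int | None = None) -> GeneImage:
    """Lay one normalized expression vector onto a square grid, row-major.

    Trailing grid positions beyond the vector length are zero.  A fixed gene
    order therefore maps each gene to a fixed pixel.
    """
    row = np.asarray(row, dtype=np.float64).ravel()
    F = row.size
    if expected_genes is not None and F != expected_genes:
        raise ValidationError(
            f"expression vector has {F} genes but the model stores {expected_genes}"
        )
    s = image_side(F)
    flat = np.zeros(s * s, dtype=np.float64)
    flat[:F] = row
    return GeneImage(matrix=flat.reshape(s, s), source_gene_count=F)


def embed_matrix(values: np.ndarray) -> np.ndarray:
    """Vectorized :func:`embed_to_gene_image` for a cells x genes matrix.

    Returns an ``(n_cells, s, s)`` array.
    """
    values = np.asarray(values, dtype=np.float64)
    n, F = values.shape
    s = image_side(F)
    flat = np.zeros((n, s * s), dtype=np.float64)
    flat[:, :F] = values
    return flat.reshape(n, s, s)
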