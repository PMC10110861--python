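"""Synthetic scRNA-seq count matrices with known cell-type structure.

The generator emulates the aspects of UMI data the classifier depends on:
each cell type gets a disjoint block of marker genes whose negative-binomial
mean is a fold-change above the shared baseline, counts are overdispersed,
and excess zeros are injected i.i.d. to mimic dropout.  An optional
multiplicative per-gene log-normal factor emulates an additive (in log
space) batch effect between two sequencing platforms.

The default configuration — 5 cell types of 300 cells each, 1,024 genes
(a 32x32 gene image with no padding), 20 markers per type at fold 5,
dispersion 2, dropout 0.3 — is the package's desk-scale benchmark: strong
enough class separation for a classifier to resolve, sparse and noisy
enough to be non-trivial, and small enough to train in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, LabelVector
from .errors import ValidationError


def default_cell_type_sizes() -> dict[str, int]:
    return {f"type_{i}": 300 for i in range(5)}


@dataclass
class SimConfig:
    """Parameters of the synthetic count generator."""

    n_genes: int = 1024
    cell_type_sizes: dict[str, int] = field(default_factory=default_cell_type_sizes)
    markers_per_type: int = 20
    baseline_mean: float = 1.0
    marker_fold: float = 5.0
    dispersion: float = 2.0
    dropout_rate: float = 0.3
    batch_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("baseline_mean and dispersion must be positive")
        if self.marker_fold < 1:
            raise ValidationError("marker_fold must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.markers_per_type * len(self.cell_type_sizes) > self.n_genes:
            raise ValidationError(
                "marker allocation infeasible: "
                f"{len(self.cell_type_sizes)} types x {self.markers_per_type} "
                f"markers > {self.n_genes} genes"
            )


def _marker_map(cfg: SimConfig) -> dict[str, list[str]]:
    """Disjoint marker blocks, assigned in type order from the gene list head."""
    markers: dict[str, list[str]] = {}
    g = 0
    for t in cfg.cell_type_sizes:
        markers[t] = [f"g{g + i}" for i in range(cfg.markers_per_type)]
        g += cfg.markers_per_type
    return markers


def _sample_counts(
    rng: np.random.Generator,
    mean: np.ndarray,
    dispersion: float,
    dropout_rate: float,
) -> np.ndarray:
    """Negative-binomial counts (mean mu, size theta) with i.i.d. dropout zeros."""
    # NumPy parametrizes NB by (n, p) with mean n(1-p)/p: p = theta/(theta+mu)
    p = dispersion / (dispersion + mean)
    counts = rng.negative_binomial(dispersion, p).astype(np.float64)
    if dropout_rate > 0:
        counts *= rng.random(counts.shape) >= dropout_rate
    return counts


def _mean_matrix(cfg: SimConfig, gene_factors: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Per-type NB mean vector over genes."""
    markers = _marker_map(cfg)
    gene_index = {f"g{i}": i for i in range(cfg.n_genes)}
    means: dict[str, np.ndarray] = {}
    for t in cfg.cell_type_sizes:
        mu = np.full(cfg.n_genes, cfg.baseline_mean, dtype=np.float64)
        mu[[gene_index[g] for g in markers[t]]] *= cfg.marker_fold
        if gene_factors is not None:
            mu = mu * gene_factors
        means[t] = mu
    return means


def generate_dataset(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    cell_prefix: str = "cell",
    exclude_types: tuple[str, ...] = (),
    gene_factors: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, LabelVector, dict[str, list[str]]]:
    """Draw a labeled raw-count matrix; fully reproducible from ``cfg.seed``.

    ``exclude_types`` drops whole cell types (used for held-out-type
    experiments); ``gene_factors`` multiplies every gene mean (used for
    batch effects).  Returns the matrix, the labels, and the marker map.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sizes = {
        t: n for t, n in cfg.cell_type_sizes.items() if t not in exclude_types
    }
    if not sizes:
        raise ValidationError("all cell types excluded")
    means = _mean_matrix(cfg, gene_factors)
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    for t, n in sizes.items():
        mu = np.broadcast_to(means[t], (n, cfg.n_genes))
        blocks.append(_sample_counts(rng, mu, cfg.dispersion, cfg.dropout_rate))
        labels.extend([t] * n)
    values = np.vstack(blocks)
    cell_ids = [f"{cell_prefix}_{i}" for i in range(values.shape[0])]
    matrix = ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(cfg.n_genes)],
        cell_ids=cell_ids,
        normalized=False,
    )
    return matrix, LabelVector(cell_ids=cell_ids, labels=labels), _marker_map(cfg)


def generate_batch_pair(
    cfg: SimConfig,
    batch_shift: float | None = None,
    exclude_from_first: tuple[str, ...] = (),
) -> tuple[
    tuple[ExpressionMatrix, LabelVector],
    tuple[ExpressionMatrix, LabelVector],
    dict[str, list[str]],
]:
    """Two datasets over the same cell types from simulated distinct platforms.

    The second batch multiplies every gene's mean by a per-gene log-normal
    factor with log-scale spread ``batch_shift`` (0 means distributionally
    identical batches).  ``exclude_from_first`` removes types from batch 1
    only, for held-out-type experiments where batch 2 keeps all types.
    """
    shift = cfg.batch_shift if batch_shift is None else batch_shift
    if shift < 0:
        raise ValidationError("batch_shift must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    X1, y1, markers = generate_dataset(
        cfg, rng=rng, cell_prefix="b1", exclude_types=exclude_from_first
    )
    factors = np.exp(rng.normal(0.0, shift, size=cfg.n_genes)) if shift > 0 else None
    X2, y2, _ = generate_dataset(cfg, rng=rng, cell_prefix="b2", gene_factors=factors)
    return (X1, y1), (X2, y2), markers
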