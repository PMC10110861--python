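"""Reading and writing expression matrices, labels, predictions, and checkpoints.

Conventions
-----------
Matrices are cells x genes throughout.  Dense input is delimited text with a
header row of gene identifiers and the first column holding cell identifiers.
Sparse input is Matrix Market coordinate format with ``genes.tsv`` and
``barcodes.tsv`` sidecar files; when the sidecar lengths imply the stored
matrix is genes x cells (the common 10x layout) it is transposed on read.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import CheckpointError, FormatError, ValidationError

CHECKPOINT_MAGIC = "mulcnn-checkpoint"
CHECKPOINT_VERSION = 1


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dups[:10]))}")


@dataclass
class ExpressionMatrix:
    """A cells x genes numeric matrix with row/column identifiers.

    ``values`` holds raw UMI counts when ``normalized`` is False (all entries
    must then be non-negative) or CPM/log-transformed values otherwise.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if not self.normalized and np.any(self.values < 0):
            raise ValidationError("raw count matrix contains negative values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict columns to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {', '.join(missing[:10])}")
        cols = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            values=self.values[:, cols],
            gene_ids=list(gene_ids),
            cell_ids=list(self.cell_ids),
            normalized=self.normalized,
        )


@dataclass
class LabelVector:
    """Per-cell cell-type labels, ordered like their companion matrix rows."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = [str(l).strip() for l in self.labels]
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("cell_ids and labels differ in length")
        if len(self.cell_ids) == 0:
            raise ValidationError("label file contains no cells")
        _check_unique(self.cell_ids, "cell ids")

    def __len__(self) -> int:
        return len(self.labels)

    def aligned_to(self, matrix: ExpressionMatrix) -> "LabelVector":
        """Reorder labels to match ``matrix.cell_ids``; every cell must be labeled."""
        lookup = dict(zip(self.cell_ids, self.labels))
        missing = [c for c in matrix.cell_ids if c not in lookup]
        if missing:
            raise ValidationError(
                f"cells without labels: {', '.join(missing[:10])}"
            )
        return LabelVector(
            cell_ids=list(matrix.cell_ids),
            labels=[lookup[c] for c in matrix.cell_ids],
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression_matrix(path: str | Path, format: str = "dense_delim") -> ExpressionMatrix:
    """Read a counts matrix from disk.

    ``format`` is ``"dense_delim"`` (TSV/CSV, header = gene ids, first column
    = cell ids) or ``"mtx_triplet"`` (Matrix Market file with ``genes.tsv``
    and ``barcodes.tsv`` sidecars in the same directory).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "dense_delim":
        return _read_dense(path)
    if format == "mtx_triplet":
        return _read_mtx(path)
    raise FormatError(f"unknown expression-matrix format: {format!r}")


def _read_dense(path: Path) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path} has no gene columns")
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path} contains non-numeric entries: {exc}") from exc
    return ExpressionMatrix(
        values=values,
        gene_ids=[str(g) for g in df.columns],
        cell_ids=[str(c) for c in df.index],
        normalized=False,
    )


def _read_sidecar(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing sidecar file: {path}")
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                # genes.tsv may carry extra columns (ensembl id, symbol); take the first
                out.append(line.split("\t")[0])
    return out


def _read_mtx(path: Path) -> ExpressionMatrix:
    genes = _read_sidecar(path.parent / "genes.tsv")
    cells = _read_sidecar(path.parent / "barcodes.tsv")
    try:
        mat = spio.mmread(path)
    except Exception as exc:
        raise FormatError(f"could not parse Matrix Market file {path}: {exc}") from exc
    dense = np.asarray(sparse.coo_matrix(mat).todense(), dtype=np.float64)
    n_rows, n_cols = dense.shape
    if n_rows == len(genes) and n_cols == len(cells):
        # genes x cells on disk (the 10x convention, also taken when square)
        dense = dense.T
    elif n_rows == len(cells) and n_cols == len(genes):
        pass
    else:
        raise FormatError(
            f"matrix shape {dense.shape} matches neither sidecar orientation "
            f"({len(genes)} genes, {len(cells)} barcodes)"
        )
    return ExpressionMatrix(values=dense, gene_ids=genes, cell_ids=cells, normalized=False)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix as delimited text readable by :func:`read_expression_matrix`."""
    df = pd.DataFrame(matrix.values, index=matrix.cell_ids, columns=matrix.gene_ids)
    df.to_csv(path, sep=sep)


def read_labels(path: str | Path) -> LabelVector:
    """Read a two-column (cell_id, label) delimited file, order preserved."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    cell_ids: list[str] = []
    labels: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                parts = line.rstrip("\n").split(",")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            if lineno == 1 and parts[1].strip().lower() in {"label", "cell_type", "celltype"}:
                continue  # optional header row
            cell_ids.append(parts[0].strip())
            labels.append(parts[1].strip())
    if not labels:
        raise ValidationError(f"{path} contains no labeled cells")
    return LabelVector(cell_ids=cell_ids, labels=labels)


def write_labels(labels: LabelVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, l in zip(labels.cell_ids, labels.labels):
            fh.write(f"{c}\t{l}\n")


def align_genes(
    ref: ExpressionMatrix, query: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, in the reference's order."""
    query_set = set(query.gene_ids)
    shared = [g for g in ref.gene_ids if g in query_set]
    if not shared:
        raise ValidationError(
            "reference and query share no genes; check that both files use the "
            "same gene identifier scheme"
        )
    return ref.subset_genes(shared), query.subset_genes(shared)


def write_predictions(
    path: str | Path,
    cell_ids: Sequence[str],
    predicted_labels: Sequence[str],
    probabilities: np.ndarray,
    class_names: Sequence[str],
) -> None:
    """Write per-cell predictions as TSV: id, label, max prob, per-class probs."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    df = pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "predicted_label": list(predicted_labels),
            "max_probability": probabilities.max(axis=1),
        }
    )
    for j, name in enumerate(class_names):
        df[f"prob_{name}"] = probabilities[:, j]
    df.to_csv(path, sep="\t", index=False)


def save_model(model, path: str | Path) -> None:
    """Serialize a trained model to a single zip archive.

    The archive holds a JSON header (magic, version, config, gene list, class
    names, array manifest) plus one ``.npy`` member per weight array, so a
    load reproduces predictions bit-identically.
    """
    header = {
        "magic": CHECKPOINT_MAGIC,
        "version": CHECKPOINT_VERSION,
        "config": model.config.to_dict(),
        "gene_ids": model.gene_ids,
        "class_names": model.class_names,
    }
    arrays = model.state_arrays()
    header["arrays"] = sorted(arrays.keys())
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))
        for name in header["arrays"]:
            buf = io.BytesIO()
            np.save(buf, np.ascontiguousarray(arrays[name]))
            zf.writestr(f"arrays/{name}.npy", buf.getvalue())


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`."""
    from .model import ModelConfig, TrainedModel  # local import avoids a cycle

    path = Path(path)
    if not path.exists():
        raise CheckpointError(f"no such checkpoint: {path}")
    try:
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            if header.get("magic") != CHECKPOINT_MAGIC:
                raise CheckpointError(f"{path} is not a model checkpoint")
            if header.get("version") != CHECKPOINT_VERSION:
                raise CheckpointError(
                    f"checkpoint version {header.get('version')} is incompatible "
                    f"with this build (expected {CHECKPOINT_VERSION})"
                )
            arrays = {
                name: np.load(io.BytesIO(zf.read(f"arrays/{name}.npy")))
                for name in header["arrays"]
            }
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"corrupt or truncated checkpoint {path}: {exc}") from exc
    config = ModelConfig.from_dict(header["config"])
    return TrainedModel.from_state(
        config=config,
        gene_ids=header["gene_ids"],
        class_names=header["class_names"],
        arrays=arrays,
    )
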