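"""The multi-scale convolutional cell-type classifier.

Architecture
------------
Each cell's normalized expression vector is laid out on a square "gene
image".  Two parallel convolutional branches read the image at different
scales (256 filters of 2x2 and 128 filters of 5x5 by default, each followed
by ReLU, dropout 0.25 and its own max-pooling stack), their feature maps are
flattened and concatenated with a PCA projection of the same expression
vector, and the joint feature vector feeds a multilayer perceptron with
hidden layers of 128, 128 and 64 ReLU units and a softmax output over the
cell types seen in training.  Training minimizes categorical cross-entropy
with plain SGD (no momentum), learning rate 1e-4, batch size 32; the
checkpoint with the best validation accuracy is returned.

Everything is NumPy with hand-written backpropagation; gradients are
verified against finite differences in the test suite.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from . import ops
from .errors import ConfigurationError, MulCNNError, ValidationError
from .preprocess import embed_matrix, image_side

HIDDEN_SIZES = (128, 128, 64)

# Network parameters and activations are single precision: the arithmetic is
# memory-bound on CPU and none of the quantities involved need more.  The
# gradient-check tests build float64 models instead.
DTYPE = np.float32


@dataclass
class ConvBranchConfig:
    """One convolutional branch: a conv layer and its pooling stack."""

    filters: int
    kernel: tuple[int, int]
    pools: list[tuple[int, int]]
    dropout: float = 0.25

    def __post_init__(self) -> None:
        self.kernel = tuple(int(k) for k in self.kernel)
        self.pools = [tuple(int(p) for p in w) for w in self.pools]
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.filters < 1:
            raise ConfigurationError("a branch needs at least one filter")


def default_conv_branches() -> list[ConvBranchConfig]:
    """The default two-scale wiring: 256@2x2 -> pool 2x2 -> pool 2x2,
    and 128@5x5 -> pool 3x3."""
    return [
        ConvBranchConfig(filters=256, kernel=(2, 2), pools=[(2, 2), (2, 2)], dropout=0.25),
        ConvBranchConfig(filters=128, kernel=(5, 5), pools=[(3, 3)], dropout=0.25),
    ]


@dataclass
class ModelConfig:
    """All trainable-model hyperparameters."""

    conv_branches: list[ConvBranchConfig] = field(default_factory=default_conv_branches)
    pca_components: int = 50
    hidden_sizes: tuple[int, ...] = HIDDEN_SIZES
    learning_rate: float = 1e-4
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0
    enable_conv: bool = True
    enable_pca: bool = True

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if any(h < 1 for h in self.hidden_sizes):
            raise ConfigurationError("hidden sizes must be positive")
        if not self.enable_conv and not self.enable_pca:
            raise ConfigurationError("at least one feature branch must be enabled")
        if self.enable_pca and self.pca_components < 1:
            raise ConfigurationError("pca_components must be positive")

    def to_dict(self) -> dict:
        return {
            "conv_branches": [
                {
                    "filters": b.filters,
                    "kernel": list(b.kernel),
                    "pools": [list(p) for p in b.pools],
                    "dropout": b.dropout,
                }
                for b in self.conv_branches
            ],
            "pca_components": self.pca_components,
            "hidden_sizes": list(self.hidden_sizes),
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "seed": self.seed,
            "enable_conv": self.enable_conv,
            "enable_pca": self.enable_pca,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        d = dict(d)
        branches = [
            ConvBranchConfig(
                filters=b["filters"],
                kernel=tuple(b["kernel"]),
                pools=[tuple(p) for p in b["pools"]],
                dropout=b.get("dropout", 0.25),
            )
            for b in d.pop("conv_branches", [])
        ]
        if not branches:
            branches = default_conv_branches()
        return cls(conv_branches=branches, **{k: v for k, v in d.items() if k != "conv_branches"})


@dataclass
class PCAModel:
    """Mean vector and orthonormal component loadings of a fitted PCA."""

    mean: np.ndarray
    components: np.ndarray  # (k, F), orthonormal rows
    explained_variance: np.ndarray


def pca_fit(X: np.ndarray, k: int) -> PCAModel:
    """Fit a k-component PCA on training cells (rows)."""
    X = np.asarray(X, dtype=np.float64)
    n, F = X.shape
    if k > min(n - 1, F):
        raise ValidationError(
            f"k={k} exceeds min(n_cells - 1, n_genes) = {min(n - 1, F)}"
        )
    sk = _SKPCA(n_components=k, svd_solver="full").fit(X)
    return PCAModel(
        mean=sk.mean_.astype(np.float64),
        components=sk.components_.astype(np.float64),
        explained_variance=sk.explained_variance_.astype(np.float64),
    )


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of ``X`` onto the fitted components: (X - mean) @ C.T."""
    X = np.asarray(X, dtype=np.float64)
    return (X - model.mean) @ model.components.T


@dataclass
class TrainingHistory:
    """Per-epoch training loss, validation loss, and validation accuracy."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def _branch_output_shape(
    side: int, branch: ConvBranchConfig
) -> tuple[int, int, int]:
    """(channels, h, w) after the branch's conv and pooling stack."""
    h = side - branch.kernel[0] + 1
    w = side - branch.kernel[1] + 1
    trace = [f"conv {branch.kernel} -> {h}x{w}"]
    if h < 1 or w < 1:
        raise ConfigurationError(
            f"image side {side} too small for the branch: {'; '.join(trace)}"
        )
    for p, q in branch.pools:
        h, w = h // p, w // q
        trace.append(f"pool ({p},{q}) -> {h}x{w}")
        if h < 1 or w < 1:
            raise ConfigurationError(
                f"image side {side} too small for the branch: {'; '.join(trace)}"
            )
    return branch.filters, h, w


class TrainedModel:
    """A (possibly still untrained) model: config plus all parameter arrays."""

    def __init__(
        self,
        config: ModelConfig,
        gene_ids: Sequence[str],
        class_names: Sequence[str],
        conv_params: list[dict[str, np.ndarray]],
        mlp_weights: list[np.ndarray],
        mlp_biases: list[np.ndarray],
        pca_model: PCAModel | None,
    ) -> None:
        self.config = config
        self.gene_ids = [str(g) for g in gene_ids]
        self.class_names = [str(c) for c in class_names]
        self.conv_params = conv_params
        self.mlp_weights = mlp_weights
        self.mlp_biases = mlp_biases
        self.pca_model = pca_model

    # -- construction -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def image_side(self) -> int:
        return image_side(self.n_genes)

    def feature_width(self) -> int:
        width = 0
        if self.config.enable_conv:
            for branch in self.config.conv_branches:
                c, h, w = _branch_output_shape(self.image_side, branch)
                width += c * h * w
        if self.config.enable_pca:
            width += self.config.pca_components
        return width

    def copy(self) -> "TrainedModel":
        return TrainedModel(
            config=copy.deepcopy(self.config),
            gene_ids=list(self.gene_ids),
            class_names=list(self.class_names),
            conv_params=[{k: v.copy() for k, v in p.items()} for p in self.conv_params],
            mlp_weights=[w.copy() for w in self.mlp_weights],
            mlp_biases=[b.copy() for b in self.mlp_biases],
            pca_model=(
                PCAModel(
                    self.pca_model.mean.copy(),
                    self.pca_model.components.copy(),
                    self.pca_model.explained_variance.copy(),
                )
                if self.pca_model is not None
                else None
            ),
        )

    # -- checkpoint state ----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.conv_params):
            arrays[f"conv{i}_kernels"] = p["kernels"]
            arrays[f"conv{i}_bias"] = p["bias"]
        for j, (w, b) in enumerate(zip(self.mlp_weights, self.mlp_biases)):
            arrays[f"mlp{j}_W"] = w
            arrays[f"mlp{j}_b"] = b
        if self.pca_model is not None:
            arrays["pca_mean"] = self.pca_model.mean
            arrays["pca_components"] = self.pca_model.components
            arrays["pca_explained_variance"] = self.pca_model.explained_variance
        return arrays

    @classmethod
    def from_state(
        cls,
        config: ModelConfig,
        gene_ids: Sequence[str],
        class_names: Sequence[str],
        arrays: Mapping[str, np.ndarray],
    ) -> "TrainedModel":
        conv_params = []
        i = 0
        while f"conv{i}_kernels" in arrays:
            conv_params.append(
                {"kernels": arrays[f"conv{i}_kernels"], "bias": arrays[f"conv{i}_bias"]}
            )
            i += 1
        mlp_weights, mlp_biases = [], []
        j = 0
        while f"mlp{j}_W" in arrays:
            mlp_weights.append(arrays[f"mlp{j}_W"])
            mlp_biases.append(arrays[f"mlp{j}_b"])
            j += 1
        pca = None
        if "pca_components" in arrays:
            pca = PCAModel(
                mean=arrays["pca_mean"],
                components=arrays["pca_components"],
                explained_variance=arrays["pca_explained_variance"],
            )
        return cls(config, gene_ids, class_names, conv_params, mlp_weights, mlp_biases, pca)

    # -- forward / backward --------------------------------------------------

    @property
    def dtype(self) -> np.dtype:
        return self.mlp_weights[0].dtype

    def features_for(self, values: np.ndarray) -> tuple[np.ndarray | None, np.ndarray | None]:
        """Precompute the two network inputs from a normalized cells x genes matrix."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape[1] != self.n_genes:
            raise ValidationError(
                f"matrix has {values.shape[1]} genes, model stores {self.n_genes}"
            )
        dtype = self.dtype
        images = (
            embed_matrix(values).astype(dtype) if self.config.enable_conv else None
        )
        pca_feats = None
        if self.config.enable_pca:
            if self.pca_model is None:
                raise MulCNNError("PCA branch enabled but not fitted; train the model first")
            pca_feats = pca_transform(self.pca_model, values).astype(dtype)
        return images, pca_feats

    def _forward(
        self,
        images: np.ndarray | None,
        pca_feats: np.ndarray | None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Run the network; returns softmax probabilities and the backward cache."""
        cache: dict = {"branches": [], "images": images}
        parts: list[np.ndarray] = []
        if self.config.enable_conv:
            assert images is not None
            B = images.shape[0]
            for branch, params in zip(self.config.conv_branches, self.conv_params):
                bc: dict = {}
                if training:
                    a, mask = ops.conv_relu_dropout_forward_batch(
                        images, params["kernels"], params["bias"], branch.dropout, rng
                    )
                    bc["mask"] = mask
                else:
                    a = ops.conv_forward_batch(images, params["kernels"], params["bias"])
                    np.maximum(a, 0, out=a)
                bc["pool_idx"] = []
                bc["pool_shapes"] = []
                for window in branch.pools:
                    bc["pool_shapes"].append(a.shape)
                    a, idx = ops.pool_forward_batch(a, window)
                    bc["pool_idx"].append(idx)
                bc["out_shape"] = a.shape
                parts.append(a.reshape(B, -1))
                cache["branches"].append(bc)
        if self.config.enable_pca:
            assert pca_feats is not None
            parts.append(np.asarray(pca_feats))
        features = np.concatenate(parts, axis=1) if len(parts) > 1 else parts[0]
        if features.shape[1] != self.mlp_weights[0].shape[0]:
            raise ValidationError(
                f"feature width {features.shape[1]} does not match the MLP input "
                f"width {self.mlp_weights[0].shape[0]}"
            )
        cache["part_widths"] = [p.shape[1] for p in parts]

        h = features
        cache["mlp_inputs"] = []
        cache["mlp_relu_masks"] = []
        n_layers = len(self.mlp_weights)
        for j, (W, b) in enumerate(zip(self.mlp_weights, self.mlp_biases)):
            cache["mlp_inputs"].append(h)
            z = h @ W + b
            if j < n_layers - 1:
                mask = z > 0
                cache["mlp_relu_masks"].append(mask)
                h = np.where(mask, z, 0.0)
            else:
                h = z
        probs = ops.softmax(h)
        return probs, cache

    def _backward(self, probs: np.ndarray, y_onehot: np.ndarray, cache: dict) -> dict:
        """Gradients of mean cross-entropy w.r.t. every trainable array."""
        B = probs.shape[0]
        grads: dict = {"mlp_W": [], "mlp_b": [], "conv": []}
        d = (probs - y_onehot) / B
        for j in range(len(self.mlp_weights) - 1, -1, -1):
            h_in = cache["mlp_inputs"][j]
            grads["mlp_W"].insert(0, h_in.T @ d)
            grads["mlp_b"].insert(0, d.sum(axis=0))
            d = d @ self.mlp_weights[j].T
            if j > 0:
                d = d * cache["mlp_relu_masks"][j - 1]
        d_features = d

        offset = 0
        if self.config.enable_conv:
            for branch, params, bc, width in zip(
                self.config.conv_branches,
                self.conv_params,
                cache["branches"],
                cache["part_widths"],
            ):
                d_part = d_features[:, offset : offset + width]
                offset += width
                da = d_part.reshape(bc["out_shape"])
                src_i, src_j = ops.compose_pool_indices(
                    bc["pool_idx"], bc["pool_shapes"], branch.pools
                )
                dk, db = ops.branch_backward_batch(
                    da, src_i, src_j, bc["mask"], cache["images"],
                    params["kernels"].shape,
                )
                grads["conv"].append({"kernels": dk, "bias": db})
        return grads

    def _sgd_step(self, grads: dict, lr: float) -> None:
        for j in range(len(self.mlp_weights)):
            self.mlp_weights[j] -= lr * grads["mlp_W"][j]
            self.mlp_biases[j] -= lr * grads["mlp_b"][j]
        for params, g in zip(self.conv_params, grads["conv"]):
            params["kernels"] -= lr * g["kernels"]
            params["bias"] -= lr * g["bias"]

    # -- inference -----------------------------------------------------------

    def predict_proba_values(self, values: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Class probabilities for a normalized cells x genes array (dropout off)."""
        images, pca_feats = self.features_for(values)
        n = values.shape[0]
        out = np.empty((n, len(self.class_names)), dtype=np.float64)
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            probs, _ = self._forward(
                images[start:stop] if images is not None else None,
                pca_feats[start:stop] if pca_feats is not None else None,
                training=False,
            )
            out[start:stop] = probs
        return out


def build_model(
    config: ModelConfig,
    n_genes: int | None = None,
    n_classes: int | None = None,
    gene_ids: Sequence[str] | None = None,
    class_names: Sequence[str] | None = None,
    dtype: np.dtype = DTYPE,
) -> TrainedModel:
    """Create a model with seeded random initial weights.

    All layers use Glorot-uniform initialization with the Keras fan
    convention (conv fan_in = kh*kw*in_channels, fan_out = kh*kw*filters),
    which keeps the very wide concatenated feature vector at a scale where
    plain SGD at small learning rates is stable.  The PCA branch is fitted
    during training.
    """
    if gene_ids is None:
        if n_genes is None:
            raise ConfigurationError("pass n_genes or gene_ids")
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if class_names is None:
        if n_classes is None:
            raise ConfigurationError("pass n_classes or class_names")
        class_names = [f"class_{i}" for i in range(n_classes)]
    if len(class_names) < 2:
        raise ValidationError("at least two classes are required")

    rng = np.random.default_rng(config.seed)
    side = image_side(len(gene_ids))

    conv_params: list[dict[str, np.ndarray]] = []
    width = 0
    if config.enable_conv:
        for branch in config.conv_branches:
            c, h, w = _branch_output_shape(side, branch)
            width += c * h * w
            fan_in = branch.kernel[0] * branch.kernel[1]
            fan_out = fan_in * branch.filters
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            conv_params.append(
                {
                    "kernels": rng.uniform(
                        -limit, limit, size=(branch.filters, *branch.kernel)
                    ).astype(dtype),
                    "bias": np.zeros(branch.filters, dtype=dtype),
                }
            )
    if config.enable_pca:
        width += config.pca_components

    sizes = [width, *config.hidden_sizes, len(class_names)]
    mlp_weights, mlp_biases = [], []
    for j in range(len(sizes) - 1):
        fan_in, fan_out = sizes[j], sizes[j + 1]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        mlp_weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype))
        mlp_biases.append(np.zeros(fan_out, dtype=dtype))

    return TrainedModel(
        config=config,
        gene_ids=gene_ids,
        class_names=class_names,
        conv_params=conv_params,
        mlp_weights=mlp_weights,
        mlp_biases=mlp_biases,
        pca_model=None,
    )


def _one_hot(labels: Sequence[str], class_names: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_names)}
    unknown = [l for l in labels if l not in index]
    if unknown:
        raise ValidationError(
            f"labels not among the model's classes: {sorted(set(unknown))[:5]}"
        )
    out = np.zeros((len(labels), len(class_names)), dtype=np.float64)
    out[np.arange(len(labels)), [index[l] for l in labels]] = 1.0
    return out


def train(
    model: TrainedModel,
    train_data: tuple[np.ndarray, Sequence[str]],
    val_data: tuple[np.ndarray, Sequence[str]] | None = None,
    epochs: int | None = None,
) -> tuple[TrainedModel, TrainingHistory]:
    """Fit the model with plain SGD on categorical cross-entropy.

    ``train_data``/``val_data`` are (normalized cells x genes array, label
    sequence) pairs.  The PCA branch is fitted on the training cells before
    the first epoch.  Shuffling, dropout, and initialization all derive from
    ``model.config.seed``, so identical seeds give bit-identical histories.
    Returns the checkpoint with the best validation accuracy (final weights
    when no validation set is given) and the per-epoch history.
    """
    cfg = model.config
    X_train, y_train = train_data
    X_train = np.asarray(X_train, dtype=np.float64)
    if len(set(y_train)) < 2:
        raise ValidationError("training set must contain at least two classes")
    n_epochs = cfg.epochs if epochs is None else epochs

    if cfg.enable_pca and model.pca_model is None:
        model.pca_model = pca_fit(X_train, cfg.pca_components)

    images, pca_feats = model.features_for(X_train)
    Y = _one_hot(list(y_train), model.class_names).astype(model.dtype)

    val_values = val_labels = None
    if val_data is not None:
        val_values = np.asarray(val_data[0], dtype=np.float64)
        val_labels = list(val_data[1])
        Y_val = _one_hot(val_labels, model.class_names)

    rng = np.random.default_rng([cfg.seed, 0xF17])
    history = TrainingHistory()
    best_acc = -1.0
    best_state = None
    n = X_train.shape[0]

    for _epoch in range(n_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs, cache = model._forward(
                images[idx] if images is not None else None,
                pca_feats[idx] if pca_feats is not None else None,
                training=True,
                rng=rng,
            )
            loss = ops.categorical_cross_entropy(Y[idx], probs)
            if not np.isfinite(loss):
                raise MulCNNError(
                    f"loss became non-finite at epoch {_epoch}; "
                    "lower the learning rate"
                )
            epoch_loss += loss * len(idx)
            grads = model._backward(probs, Y[idx], cache)
            model._sgd_step(grads, cfg.learning_rate)
        history.train_loss.append(epoch_loss / n)

        if val_values is not None:
            val_probs = model.predict_proba_values(val_values)
            history.val_loss.append(ops.categorical_cross_entropy(Y_val, val_probs))
            pred = np.argmax(val_probs, axis=1)
            truth = np.argmax(Y_val, axis=1)
            acc = float(np.mean(pred == truth))
            history.val_accuracy.append(acc)
            if acc > best_acc:
                best_acc = acc
                best_state = {k: v.copy() for k, v in model.state_arrays().items()}

    if best_state is not None:
        result = TrainedModel.from_state(
            model.config, model.gene_ids, model.class_names, best_state
        )
    else:
        result = model
    return result, history


def fine_tune(
    pretrained: TrainedModel,
    target_data: tuple[np.ndarray, Sequence[str]],
    epochs: int,
    val_data: tuple[np.ndarray, Sequence[str]] | None = None,
    class_names: Sequence[str] | None = None,
) -> tuple[TrainedModel, TrainingHistory]:
    """Continue SGD from pretrained weights on a labeled target subset.

    Conv kernels, PCA loadings and hidden layers are warm-started.  When the
    target class set differs from the pretrained one, the output layer is
    re-initialized (seeded) at the target width; otherwise all weights carry
    over and ``epochs=0`` returns an exact copy.
    """
    X, y = target_data
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] == 0:
        raise ValidationError("fine-tuning target subset is empty")
    target_classes = list(class_names) if class_names is not None else sorted(set(y))
    model = pretrained.copy()

    if target_classes != model.class_names:
        rng = np.random.default_rng([model.config.seed, 0xF7])
        fan_in = model.mlp_weights[-1].shape[0]
        fan_out = len(target_classes)
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        model.mlp_weights[-1] = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        model.mlp_biases[-1] = np.zeros(fan_out)
        model.class_names = target_classes

    if epochs == 0:
        return model, TrainingHistory()
    return train(model, (X, list(y)), val_data=val_data, epochs=epochs)
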