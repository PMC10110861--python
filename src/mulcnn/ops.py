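"""Numeric primitives of the network: convolution, pooling, activations, loss.

All operations are plain NumPy.  Convolution is valid cross-correlation
(S[i,j] = sum_m sum_n I[i+m, j+n] * W[m,n]; no padding, no kernel flip) and
pooling uses non-overlapping windows (stride = window, trailing partial
windows dropped).  Batched variants carry the auxiliary state their backward
passes need, so gradients can be checked against finite differences.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def conv2d_valid(I: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of a single 2-D input with a single kernel."""
    I = np.asarray(I, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if I.ndim != 2 or W.ndim != 2:
        raise ValidationError("conv2d_valid expects 2-D input and kernel")
    H, Wd = I.shape
    m, n = W.shape
    if m > H or n > Wd:
        raise ValidationError(
            f"kernel {W.shape} larger than input {I.shape}"
        )
    cols = _im2col(I[None, :, :], m, n)[0]  # (oh*ow, m*n)
    out = cols @ W.ravel()
    return out.reshape(H - m + 1, Wd - n + 1)


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0, x)


def max_pool(x: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Non-overlapping max pooling of a single 2-D map."""
    x = np.asarray(x, dtype=np.float64)
    p, q = window
    H, W = x.shape
    if p > H or q > W:
        raise ValidationError(f"pool window {window} larger than map {x.shape}")
    Ho, Wo = H // p, W // q
    cropped = x[: Ho * p, : Wo * q]
    return cropped.reshape(Ho, p, Wo, q).max(axis=(1, 3))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety.

    Dtype-preserving: float32 logits give float32 probabilities.
    """
    logits = np.asarray(logits)
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def categorical_cross_entropy(
    y: np.ndarray, y_hat: np.ndarray, eps: float = 1e-7
) -> float:
    """Mean categorical cross-entropy J = -(1/n) sum_i sum_k y_ik ln(y_hat_ik).

    Predictions are clipped to ``[eps, 1 - eps]`` before the log.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValidationError(
            f"label matrix {y.shape} and prediction matrix {y_hat.shape} differ"
        )
    clipped = np.clip(y_hat, eps, 1.0 - eps)
    return float(-(y * np.log(clipped)).sum() / y.shape[0])


# ---------------------------------------------------------------------------
# batched forward/backward building blocks used by the training loop
# ---------------------------------------------------------------------------
#
# These wrap the compiled loops in mulcnn._kernels.  Feature maps are
# channels-last (B, H, W, C); the wrappers validate shapes and keep the
# public (F, kh, kw) kernel layout.


def _im2col(images: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """All valid (kh, kw) patches of a batch of 2-D images, row-major.

    Returns (B, oh*ow, kh*kw); a matmul against flattened kernels then
    performs the convolution.  Used by the single-sample reference path.
    """
    B, H, W = images.shape
    oh, ow = H - kh + 1, W - kw + 1
    s0, s1, s2 = images.strides
    windows = np.lib.stride_tricks.as_strided(
        images,
        shape=(B, oh, ow, kh, kw),
        strides=(s0, s1, s2, s1, s2),
        writeable=False,
    )
    return windows.reshape(B, oh * ow, kh * kw)


def conv_forward_batch(
    images: np.ndarray, kernels: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """Batched valid cross-correlation: (B, H, W) x (F, kh, kw) -> (B, oh, ow, F).

    Runs as one im2col matmul so the bulk of the work is a BLAS sgemm.
    """
    F, kh, kw = kernels.shape
    B, H, W = images.shape
    if kh > H or kw > W:
        raise ValidationError(f"kernel ({kh},{kw}) larger than image ({H},{W})")
    oh, ow = H - kh + 1, W - kw + 1
    cols = _im2col(images, kh, kw).reshape(B * oh * ow, kh * kw)
    out = cols @ kernels.reshape(F, kh * kw).T.astype(images.dtype)
    out += bias.astype(images.dtype)
    return out.reshape(B, oh, ow, F)


def conv_relu_dropout_forward_batch(
    images: np.ndarray,
    kernels: np.ndarray,
    bias: np.ndarray,
    dropout: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Fused conv + ReLU + inverted dropout (training path).

    Returns activations (B, oh, ow, F) and the combined multiplicative mask
    kept for the backward pass.  Dropout uniforms are drawn from ``rng`` in
    output order, so the draw is reproducible across implementations.
    """
    from . import _kernels

    F, kh, kw = kernels.shape
    B, H, W = images.shape
    if kh > H or kw > W:
        raise ValidationError(f"kernel ({kh},{kw}) larger than image ({H},{W})")
    oh, ow = H - kh + 1, W - kw + 1
    cols = _im2col(images, kh, kw).reshape(B * oh * ow, kh * kw)
    z = cols @ kernels.reshape(F, kh * kw).T.astype(images.dtype)
    keep = images.dtype.type(1.0 - dropout)
    if dropout > 0.0:
        rand = rng.random((B * oh * ow, F), dtype=images.dtype)
    else:
        rand = np.empty((0, F), dtype=images.dtype)
    mask = _kernels.relu_dropout(z, bias.astype(images.dtype), rand, keep, dropout > 0.0)
    return z.reshape(B, oh, ow, F), mask.reshape(B, oh, ow, F)


def pool_forward_batch(
    x: np.ndarray, window: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pooling on (B, H, W, C) maps; stride = window.

    Returns the pooled maps and the flat within-window argmax (ties resolve
    to the first position) for gradient routing.
    """
    from . import _kernels

    p, q = window
    B, H, W, C = x.shape
    if p > H or q > W:
        raise ValidationError(f"pool window {window} larger than map ({H},{W})")
    return _kernels.pool_forward(np.ascontiguousarray(x), p, q)


def compose_pool_indices(
    pool_idx: list[np.ndarray],
    pool_shapes: list[tuple[int, ...]],
    windows: list[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Compose per-stage argmax routings into conv-map source coordinates.

    For every element of the final pooled map, returns the (row, col) of the
    conv-map activation it descends from, walking the argmax of each pooling
    stage from last to first.
    """
    k = pool_idx[-1].astype(np.int32)
    p, q = windows[-1]
    B, Ho, Wo, C = pool_idx[-1].shape
    src_i = np.arange(Ho, dtype=np.int32)[None, :, None, None] * p + k // q
    src_j = np.arange(Wo, dtype=np.int32)[None, None, :, None] * q + k % q
    src_i = np.broadcast_to(src_i, k.shape).copy()
    src_j = np.broadcast_to(src_j, k.shape).copy()
    b_ix = np.arange(B)[:, None, None, None]
    c_ix = np.arange(C)[None, None, None, :]
    for s in range(len(pool_idx) - 2, -1, -1):
        p, q = windows[s]
        k = pool_idx[s][b_ix, src_i, src_j, c_ix].astype(np.int32)
        src_i = src_i * p + k // q
        src_j = src_j * q + k % q
    return src_i, src_j


def branch_backward_batch(
    d_out: np.ndarray,
    src_i: np.ndarray,
    src_j: np.ndarray,
    mask: np.ndarray,
    images: np.ndarray,
    kernel_shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel/bias gradients of one conv branch from its pooled-output gradient.

    The input gradient is not computed: the convolution is the first
    trainable layer and the gene image is data.
    """
    from . import _kernels

    F, kh, kw = kernel_shape
    dk_t, db = _kernels.branch_backward(
        np.ascontiguousarray(d_out), src_i, src_j, mask, images, kh, kw
    )
    return np.ascontiguousarray(dk_t.transpose(2, 0, 1)), db
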