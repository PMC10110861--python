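"""Numba-compiled batched kernels behind the training loop.

These implement exactly the same arithmetic as the reference operations in
:mod:`mulcnn.ops` (valid cross-correlation, ReLU, inverted dropout,
non-overlapping max pooling with first-position tie-breaking) but fuse the
per-branch work and loop directly over the arrays instead of materializing
large intermediates, which is what makes CPU training practical.  Layout is
channels-last: feature maps are (B, H, W, C) and kernels (kh, kw, F).

Because max pooling keeps a single element per window, the branch backward
pass never forms the dense feature-map gradient: each pooled gradient is
scattered straight through the composed pool index map onto the convolution
kernel gradient.

The test suite checks every kernel against the plain-NumPy reference path.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def relu_dropout(z, bias, rand, keep, use_dropout):
    """Fused bias + ReLU + inverted dropout, applied in place.

    ``z`` is the (B*P, F) pre-activation matrix straight from the im2col
    matmul (bias not yet added); ``rand`` holds pre-drawn uniforms of the
    same shape (ignored when ``use_dropout`` is False).  Returns the
    combined multiplicative mask (0, or 1/keep on surviving positive units)
    used by the backward pass.  Branchless so the loop vectorizes.
    """
    N, F = z.shape
    mask = np.empty_like(z)
    one = z.dtype.type(1.0)
    inv_keep = one / keep
    if use_dropout:
        for i in range(N):
            for f in range(F):
                v = z[i, f] + bias[f]
                m = inv_keep * (v > 0.0) * (rand[i, f] < keep)
                z[i, f] = v * m
                mask[i, f] = m
    else:
        for i in range(N):
            for f in range(F):
                v = z[i, f] + bias[f]
                m = one * (v > 0.0)
                z[i, f] = v * m
                mask[i, f] = m
    return mask


@njit(cache=True)
def pool_forward(x, p, q):
    """Non-overlapping max pooling with stride = window on (B, H, W, C) maps.

    Trailing partial windows are dropped; ties resolve to the first window
    position in row-major order.  Returns the pooled maps and the flat
    within-window argmax (uint8) for gradient routing.
    """
    B, H, W, C = x.shape
    Ho, Wo = H // p, W // q
    out = np.empty((B, Ho, Wo, C), dtype=x.dtype)
    idx = np.zeros((B, Ho, Wo, C), dtype=np.uint8)
    for b in range(B):
        for i in range(Ho):
            for j in range(Wo):
                for c in range(C):
                    out[b, i, j, c] = x[b, i * p, j * q, c]
                for di in range(p):
                    for dj in range(q):
                        if di == 0 and dj == 0:
                            continue
                        k = di * q + dj
                        for c in range(C):
                            v = x[b, i * p + di, j * q + dj, c]
                            if v > out[b, i, j, c]:
                                out[b, i, j, c] = v
                                idx[b, i, j, c] = k
    return out, idx


@njit(cache=True)
def branch_backward(d_out, src_i, src_j, mask, images, kh, kw):
    """Kernel/bias gradients of one conv branch, skipping dense intermediates.

    ``d_out`` (B, Ho, Wo, F) is the gradient at the branch's pooled output;
    ``src_i``/``src_j`` map each pooled element to its conv-map position
    (the composition of the argmax routing of every pooling stage);
    ``mask`` is the combined ReLU/dropout multiplier at conv-map positions.
    Returns dK (kh, kw, F) and db (F,).
    """
    B, Ho, Wo, F = d_out.shape
    d_kernels = np.zeros((kh, kw, F), dtype=d_out.dtype)
    d_bias = np.zeros(F, dtype=d_out.dtype)
    for b in range(B):
        for i in range(Ho):
            for j in range(Wo):
                for f in range(F):
                    g = d_out[b, i, j, f]
                    if g == 0.0:
                        continue
                    ii = src_i[b, i, j, f]
                    jj = src_j[b, i, j, f]
                    g *= mask[b, ii, jj, f]
                    if g == 0.0:
                        continue
                    d_bias[f] += g
                    for m in range(kh):
                        for n in range(kw):
                            d_kernels[m, n, f] += images[b, ii + m, jj + n] * g
    return d_kernels, d_bias
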