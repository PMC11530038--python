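"""Structured array operations (convolution, pooling, resampling, losses).

All functions take and return :class:`~lesionseg.nn.tensor.Tensor` in NCHW
layout and register their own backward closures.
"""

from __future__ import annotations

import functools
from typing import Tuple

import numpy as np

from .tensor import DTYPE, Tensor, _wire


def _conv_raw(x: np.ndarray, w: np.ndarray, padding: int):
    """Plain-array stride-1 convolution via per-offset GEMMs.

    Returns (out NCHW, padded input); the padded input is reused by the
    weight-gradient pass.
    """
    n, c, h, wd = x.shape
    cout, cin, kh, kw = w.shape
    ho = h + 2 * padding - kh + 1
    wo = wd + 2 * padding - kw + 1
    if kh == kw == 1 and padding == 0:
        xf = x.reshape(n, c, h * wd)
        out = np.matmul(w.reshape(cout, cin), xf)
        return out.reshape(n, cout, h, wd), x
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    wt = np.ascontiguousarray(w.transpose(2, 3, 0, 1))  # (kh, kw, O, C)
    out = np.zeros((n, cout, ho * wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            v = np.ascontiguousarray(xp[:, :, i : i + ho, j : j + wo]).reshape(
                n, c, ho * wo
            )
            out += np.matmul(wt[i, j], v)
    return out.reshape(n, cout, ho, wo), xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), stride 1.

    x: (N, Cin, H, W); weight: (Cout, Cin, k, k); bias: (Cout,) or None.
    The input gradient is computed as a convolution of the output gradient
    with the spatially flipped, channel-transposed kernel.
    """
    n, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")
    out_arr, xp = _conv_raw(x.data, weight.data, padding)
    if bias is not None:
        out_arr += bias.data[None, :, None, None]
    out = Tensor(out_arr)
    parents = (x, weight) if bias is None else (x, weight, bias)
    if _wire(out, parents):
        ho, wo = out_arr.shape[2:]

        def bw(g):
            gf = np.ascontiguousarray(g).reshape(n, cout, ho * wo)
            if weight.requires_grad or weight._parents:
                gw = np.empty_like(weight.data)
                for i in range(kh):
                    for j in range(kw):
                        v = np.ascontiguousarray(
                            xp[:, :, i : i + ho, j : j + wo]
                        ).reshape(n, cin, ho * wo)
                        gw[:, :, i, j] = np.einsum("nop,ncp->oc", gf, v, optimize=True)
                weight._accumulate_owned(gw)
            if bias is not None and (bias.requires_grad or bias._parents):
                bias._accumulate_owned(gf.sum(axis=(0, 2)))
            if x.requires_grad or x._parents:
                w_flip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                gx, _ = _conv_raw(
                    gf.reshape(n, cout, ho, wo), np.ascontiguousarray(w_flip),
                    kh - 1 - padding,
                )
                x._accumulate_owned(gx)

        out._backward = bw
    return out


def batch_norm(x: Tensor, weight: Tensor, bias: Tensor, mean: np.ndarray,
               var: np.ndarray, eps: float, use_batch_stats: bool) -> Tensor:
    """Fused batch normalization over (N, H, W) per channel.

    With ``use_batch_stats`` the supplied mean/var are the batch statistics
    and the full backward (through the statistics) is applied; otherwise they
    are treated as constants (running averages at evaluation time).
    """
    n, c, h, w = x.data.shape
    m = mean.reshape(1, c, 1, 1)
    inv = (1.0 / np.sqrt(var + eps)).reshape(1, c, 1, 1).astype(DTYPE)
    xhat = (x.data - m) * inv
    out = Tensor(xhat * weight.data.reshape(1, c, 1, 1) + bias.data.reshape(1, c, 1, 1))
    if _wire(out, (x, weight, bias)):

        def bw(g):
            axes = (0, 2, 3)
            if weight.requires_grad or weight._parents:
                weight._accumulate_owned((g * xhat).sum(axis=axes))
            if bias.requires_grad or bias._parents:
                bias._accumulate_owned(g.sum(axis=axes))
            if x.requires_grad or x._parents:
                gxhat = g * weight.data.reshape(1, c, 1, 1)
                if use_batch_stats:
                    cnt = n * h * w
                    s1 = gxhat.sum(axis=axes, keepdims=True)
                    s2 = (gxhat * xhat).sum(axis=axes, keepdims=True)
                    gx = inv * (gxhat - (s1 + xhat * s2) / cnt)
                else:
                    gx = inv * gxhat
                x._accumulate_owned(gx.astype(DTYPE, copy=False))

        out._backward = bw
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2; odd trailing rows/cols are dropped."""
    n, c, h, w = x.data.shape
    h2, w2 = h // 2, w // 2
    xv = x.data[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
    out = Tensor(xv.mean(axis=(3, 5)))
    if _wire(out, (x,)):

        def bw(g):
            gx = np.zeros_like(x.data)
            gq = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            gx[:, :, : 2 * h2, : 2 * w2] = gq
            x._accumulate_owned(gx)

        out._backward = bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) mean over the spatial grid."""
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) max over the spatial grid."""
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=2)
    out = Tensor(np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0])
    if _wire(out, (x,)):

        def bw(g):
            gx = np.zeros_like(flat)
            np.put_along_axis(gx, idx[:, :, None], g[:, :, None], axis=2)
            x._accumulate_owned(gx.reshape(x.data.shape))

        out._backward = bw
    return out


@functools.lru_cache(maxsize=128)
def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in), dtype=np.float64)
    if n_in == 1:
        m[:, 0] = 1.0
        return m.astype(DTYPE)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        m[i, lo] += 1.0 - t
        m[i, hi] += t
    return m.astype(DTYPE)


def bilinear_resize(x: Tensor, size: Tuple[int, int]) -> Tensor:
    """Bilinear resampling of (N, C, H, W) to spatial ``size`` (Ho, Wo)."""
    n, c, h, w = x.data.shape
    ho, wo = size
    if (ho, wo) == (h, w):
        return x * 1.0
    ah = _interp_matrix(ho, h)
    aw = _interp_matrix(wo, w)
    # y[n,c] = Ah @ x[n,c] @ Aw.T
    y = np.einsum("oh,nchw,pw->ncop", ah, x.data, aw, optimize=True)
    out = Tensor(y)
    if _wire(out, (x,)):

        def bw(g):
            gx = np.einsum("oh,ncop,pw->nchw", ah, g, aw, optimize=True)
            x._accumulate_owned(gx.astype(DTYPE, copy=False))

        out._backward = bw
    return out


def upsample2(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling."""
    _, _, h, w = x.data.shape
    return bilinear_resize(x, (2 * h, 2 * w))


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy.

    logits: (N, K, H, W); labels: (N, H, W) integer class ids in [0, K).
    """
    n, k, h, w = logits.data.shape
    if labels.shape != (n, h, w):
        raise ValueError(f"labels shape {labels.shape} != {(n, h, w)}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    sm = ez / ez.sum(axis=1, keepdims=True)
    lab = labels.astype(np.int64)
    picked = np.take_along_axis(sm, lab[:, None, :, :], axis=1)[:, 0]
    total = n * h * w
    loss_val = -np.log(np.maximum(picked, 1e-12)).sum() / total
    out = Tensor(loss_val)
    if _wire(out, (logits,)):

        def bw(g):
            onehot = np.zeros_like(sm)
            np.put_along_axis(onehot, lab[:, None, :, :], 1.0, axis=1)
            logits._accumulate_owned((sm - onehot) * (float(g) / total))

        out._backward = bw
    return out


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Plain-array softmax used at inference time."""
    z = logits - logits.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)
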