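"""Independent brute-force oracles used by the tests.

Everything here is written as straight-line scalar/loop code (or calls into
scipy) and deliberately shares no implementation with the package's nn
engine.
"""

import numpy as np
from scipy.ndimage import correlate


def conv2d_loop(x, w, b=None, padding=0):
    """Direct convolution oracle via scipy correlate, channel by channel."""
    n, cin, h, wd = x.shape
    cout = w.shape[0]
    k = w.shape[2]
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho, wo = x.shape[2] - k + 1, x.shape[3] - k + 1
    out = np.zeros((n, cout, ho, wo))
    for ni in range(n):
        for oc in range(cout):
            acc = np.zeros((x.shape[2], x.shape[3]))
            for ic in range(cin):
                acc += correlate(x[ni, ic].astype(np.float64), w[oc, ic].astype(np.float64),
                                 mode="constant")
            off = k // 2
            out[ni, oc] = acc[off : off + ho, off : off + wo]
            if b is not None:
                out[ni, oc] += b[oc]
    return out


def bilinear_resize_loop(x, ho, wo):
    """Per-pixel bilinear resampling (half-pixel centers, edge clamped)."""
    n, c, h, w = x.shape
    out = np.zeros((n, c, ho, wo))
    for i in range(ho):
        src_y = min(max((i + 0.5) * h / ho - 0.5, 0.0), h - 1.0) if h > 1 else 0.0
        y0 = int(np.floor(src_y))
        y1 = min(y0 + 1, h - 1)
        ty = src_y - y0
        for j in range(wo):
            src_x = min(max((j + 0.5) * w / wo - 0.5, 0.0), w - 1.0) if w > 1 else 0.0
            x0 = int(np.floor(src_x))
            x1 = min(x0 + 1, w - 1)
            tx = src_x - x0
            top = (1 - tx) * x[:, :, y0, x0] + tx * x[:, :, y0, x1]
            bot = (1 - tx) * x[:, :, y1, x0] + tx * x[:, :, y1, x1]
            out[:, :, i, j] = (1 - ty) * top + ty * bot
    return out


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def attention_gate_loop(x, g, wx, wg, bg, psi, b_psi):
    """Per-pixel scalar evaluation of the additive gate.

    wx: (F_int, Cx); wg: (F_int, Cg); bg: (F_int,); psi: (F_int,); b_psi scalar.
    g must already be on x's spatial grid.
    """
    n, cx, h, w = x.shape
    alpha = np.zeros((n, 1, h, w))
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                q = wx @ x[ni, :, i, j] + wg @ g[ni, :, i, j] + bg
                q = np.maximum(q, 0.0)
                alpha[ni, 0, i, j] = sigmoid(float(psi @ q) + b_psi)
    return alpha * x, alpha


def channel_attention_loop(x, w1, b1, w2, b2):
    """Explicit dual-pool + shared-MLP channel attention with residual."""
    n, c, h, w = x.shape
    out = np.zeros_like(x, dtype=np.float64)
    for ni in range(n):
        avg = x[ni].reshape(c, -1).mean(axis=1)
        mx = x[ni].reshape(c, -1).max(axis=1)
        za = w2 @ np.maximum(w1 @ avg + b1, 0.0) + b2
        zm = w2 @ np.maximum(w1 @ mx + b1, 0.0) + b2
        beta = sigmoid(za + zm)
        out[ni] = x[ni] * beta[:, None, None] + x[ni]
    return out


def batch_norm_loop(x, gamma, beta, eps=1e-5):
    """Training-mode batch normalization by explicit formula."""
    mean = x.mean(axis=(0, 2, 3), keepdims=True)
    var = x.var(axis=(0, 2, 3), keepdims=True)
    xhat = (x - mean) / np.sqrt(var + eps)
    return xhat * gamma.reshape(1, -1, 1, 1) + beta.reshape(1, -1, 1, 1)


def cross_entropy_loop(logits, labels):
    """Per-pixel -log softmax, averaged, by explicit looping."""
    n, k, h, w = logits.shape
    total = 0.0
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                z = logits[ni, :, i, j].astype(np.float64)
                z = z - z.max()
                p = np.exp(z) / np.exp(z).sum()
                total += -np.log(p[labels[ni, i, j]])
    return total / (n * h * w)


def numeric_gradient(f, x, eps=1e-2):
    """Central-difference gradient of scalar f wrt array x (float32 scale)."""
    grad = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gflat = grad.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return grad
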