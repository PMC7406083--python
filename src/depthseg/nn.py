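"""Minimal numpy CNN primitives with manual backpropagation.

Only what the depth-parametric classifier family needs: same-size 3x3
convolution (im2col + BLAS matmul), ReLU, 2x2 average pooling, global average
pooling, a linear readout, and softmax cross-entropy.  Forward functions
return the caches their backward counterparts need; all arrays are float32
in NCHW layout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "he_conv", "he_linear", "conv3x3_forward", "conv3x3_backward",
    "relu_forward", "relu_backward", "avgpool2_forward", "avgpool2_backward",
    "gap_forward", "gap_backward", "linear_forward", "linear_backward",
    "softmax_xent", "SGD",
]


def he_conv(rng: np.random.Generator, c_in: int, c_out: int, k: int = 3):
    """He-normal conv kernel (c_out, c_in, k, k) and zero bias."""
    w = rng.standard_normal((c_out, c_in, k, k)).astype(np.float32)
    w *= np.float32(np.sqrt(2.0 / (c_in * k * k)))
    return w, np.zeros(c_out, dtype=np.float32)


def he_linear(rng: np.random.Generator, n_in: int, n_out: int):
    w = rng.standard_normal((n_in, n_out)).astype(np.float32)
    w *= np.float32(np.sqrt(2.0 / n_in))
    return w, np.zeros(n_out, dtype=np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patches of the zero-padded input."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))     # (N,C,H,W,k,k)
    cols = win.transpose(0, 2, 3, 1, 4, 5)                 # (N,H,W,C,k,k)
    n, h, w = x.shape[0], x.shape[2], x.shape[3]
    return np.ascontiguousarray(cols).reshape(n * h * w, -1)


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-size stride-1 convolution. Returns (out, cache)."""
    n, c, h, wd = x.shape
    f, _, k, _ = w.shape
    cols = _im2col(x, k)
    out = cols @ w.reshape(f, -1).T + b
    out = out.reshape(n, h, wd, f).transpose(0, 3, 1, 2)
    return out, (cols, x.shape, w)


def conv3x3_backward(dout: np.ndarray, cache):
    cols, x_shape, w = cache
    n, c, h, wd = x_shape
    f, _, k, _ = w.shape
    dflat = dout.transpose(0, 2, 3, 1).reshape(-1, f)      # (N*H*W, F)
    dw = (dflat.T @ cols).reshape(w.shape)
    db = dflat.sum(axis=0)
    dcols = dflat @ w.reshape(f, -1)                       # (N*H*W, C*k*k)
    dcols = dcols.reshape(n, h, wd, c, k, k)
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, wd + 2 * p), dtype=dout.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + h, kj:kj + wd] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
    dx = dxp[:, :, p:p + h, p:p + wd]
    return dx, dw, db


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0)
    return out, (x > 0)


def relu_backward(dout: np.ndarray, mask) -> np.ndarray:
    return dout * mask


def avgpool2_forward(x: np.ndarray):
    n, c, h, w = x.shape
    out = x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    return out, x.shape


def avgpool2_backward(dout: np.ndarray, x_shape) -> np.ndarray:
    n, c, h, w = x_shape
    d = dout[:, :, :, None, :, None] / np.float32(4.0)
    return np.broadcast_to(d, (n, c, h // 2, 2, w // 2, 2)).reshape(n, c, h, w)


def gap_forward(x: np.ndarray):
    return x.mean(axis=(2, 3)), x.shape


def gap_backward(dout: np.ndarray, x_shape) -> np.ndarray:
    n, c, h, w = x_shape
    return np.broadcast_to(dout[:, :, None, None] / np.float32(h * w), x_shape).copy()


def linear_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w + b, x


def linear_backward(dout: np.ndarray, x: np.ndarray, w: np.ndarray):
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)


def softmax_xent(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class SGD:
    """Plain SGD with momentum and decoupled weight decay on the kernels."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.1,
                 momentum: float = 0.9, weight_decay: float = 1e-4,
                 clip_norm: float = 5.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.vel = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        scale = 1.0
        if self.clip_norm:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for k, p in self.params.items():
            g = grads[k] * scale if scale != 1.0 else grads[k]
            if self.weight_decay and not k.endswith("_b"):
                g = g + self.weight_decay * p
            v = self.vel[k]
            v *= self.momentum
            v -= self.lr * g
            p += v
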