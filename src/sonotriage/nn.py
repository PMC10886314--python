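"""Minimal numpy neural-network layers with exact analytic gradients.

Just enough machinery for a desk-scale encoder–decoder pixel classifier:
3x3/1x1 convolutions (im2col), batch normalization, ReLU, 2x2 max pooling,
nearest-neighbour upsampling, channel concatenation, softmax cross-entropy,
and Adam.  Everything is float32, pure numpy, and bit-deterministic for a
fixed parameter seed and data order.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "UpsampleNearest2",
    "Adam",
    "softmax_cross_entropy",
]


class Conv2d:
    """2-D convolution, stride 1, 'same' padding for odd kernels."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n,c,h,w,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )
        y = cols @ self.w.reshape(self.cout, -1).T + self.b
        if train:
            self._cols, self._shape = cols, x.shape
        return np.ascontiguousarray(y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        p, k = self.pad, self.k
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.dw[...] = (dyf.T @ self._cols).reshape(self.w.shape)
        self.db[...] = dyf.sum(axis=0)
        dcols = (dyf @ self.w.reshape(self.cout, -1)).reshape(n, h, w, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (n,c,h,w,k,k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j]
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat.astype(np.float32), invstd.astype(np.float32))
        return (self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]).astype(
            np.float32
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * invstd[None, :, None, None]
        sum_dy = dy.sum(axis=(0, 2, 3), keepdims=True)
        sum_dy_xhat = (dy * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (g / m * (m * dy - sum_dy - xhat * sum_dy_xhat)).astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool2:
    """2x2 max pooling, stride 2; ties route gradient to the first maximum."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        view = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = np.ascontiguousarray(view.transpose(0, 1, 2, 4, 3, 5)).reshape(
            n, c, h // 2, w // 2, 4
        )
        if train:
            self._idx = flat.argmax(axis=-1)
            self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        scatter = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(scatter, self._idx[..., None], dy[..., None], axis=-1)
        self._idx = None
        out = scatter.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(out).reshape(n, c, h, w)


class UpsampleNearest2:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params  # list of (value, grad) array pairs
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy and its gradient w.r.t. the logits.

    ``logits`` is (N, K, H, W); ``labels`` is (N, H, W) with values in
    [0, K).  Optional per-class weights reweight each pixel's contribution
    (normalized by the total weight).
    """
    n, k, h, w = logits.shape
    shifted = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    probs = exp / exp.sum(axis=1, keepdims=True)
    flat = probs.transpose(0, 2, 3, 1).reshape(-1, k)
    y = labels.reshape(-1)
    if class_weights is None:
        wts = np.ones(len(y), dtype=np.float32)
    else:
        wts = np.asarray(class_weights, dtype=np.float32)[y]
    total = wts.sum()
    eps = np.float32(1e-12)
    loss = float(-(wts * np.log(flat[np.arange(len(y)), y] + eps)).sum() / total)
    dflat = flat.copy()
    dflat[np.arange(len(y)), y] -= 1.0
    dflat *= (wts / total)[:, None]
    dlogits = dflat.reshape(n, h, w, k).transpose(0, 3, 1, 2).astype(np.float32)
    return loss, dlogits
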