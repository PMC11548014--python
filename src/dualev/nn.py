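"""Minimal CPU neural-network core (float32, NHWC layout).

Provides exactly the pieces the package's two models need: 3x3 (strided)
convolutions via im2col/col2im, transpose convolutions as their exact
adjoint, batch normalization, ReLU, dense layers, and Adam.  Gradients are
hand-derived and covered by numeric-gradient tests.  All randomness flows
through an explicit ``numpy.random.Generator``, so runs are reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm",
    "ReLU",
    "Dense",
    "Adam",
]

F32 = np.float32


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,H,W,C) -> (N,Ho,Wo,k,k,C) patch tensor (copied, contiguous)."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    n, h, w, c = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, ho, wo, k, k, c),
        strides=(s0, s1 * stride, s2 * stride, s1, s2, s3),
        writeable=False,
    )
    return np.ascontiguousarray(view)


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back onto the input."""
    n, h, w, c = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = dcols.shape[1], dcols.shape[2]
    dxp = np.zeros((n, hp, wp, c), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + stride * ho : stride, j : j + stride * wo : stride, :] += dcols[
                :, :, :, i, j, :
            ]
    if pad:
        return dxp[:, pad:-pad, pad:-pad, :]
    return dxp


class Conv2D:
    """k x k convolution, 'same' padding (pad = k // 2), optional stride."""

    def __init__(self, cin, cout, k=3, stride=1, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, k // 2
        self.cin, self.cout = cin, cout
        scale = np.sqrt(2.0 / (k * k * cin))
        self.w = rng.normal(0.0, scale, size=(k * k * cin, cout)).astype(F32)
        self.b = np.zeros(cout, dtype=F32) if bias else None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b) if bias else None
        self._cache = None

    def forward(self, x, train=True):
        cols = _im2col(x, self.k, self.stride, self.pad)
        n, ho, wo = cols.shape[:3]
        y = cols.reshape(-1, self.k * self.k * self.cin) @ self.w
        y = y.reshape(n, ho, wo, self.cout)
        if self.b is not None:
            y += self.b
        if train:
            self._cache = (cols, x.shape)
        return y

    def backward(self, dy):
        cols, x_shape = self._cache
        n, ho, wo = dy.shape[:3]
        dyf = dy.reshape(-1, self.cout)
        self.dw[...] = cols.reshape(-1, self.k * self.k * self.cin).T @ dyf
        if self.b is not None:
            self.db[...] = dyf.sum(axis=0)
        dcols = (dyf @ self.w.T).reshape(n, ho, wo, self.k, self.k, self.cin)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)

    def params(self):
        if self.b is None:
            return [(self.w, self.dw)]
        return [(self.w, self.dw), (self.b, self.db)]


class ConvTranspose2D:
    """k x k transpose convolution upsampling by ``stride`` (output = stride * input).

    Implemented as the exact adjoint of a strided convolution, with the
    asymmetric crop chosen so the output side is exactly ``stride * H``
    (the usual output_padding = stride - 1 convention for k = 3, pad = 1).
    """

    def __init__(self, cin, cout, k=3, stride=2, rng=None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, k // 2
        self.cin, self.cout = cin, cout
        scale = np.sqrt(2.0 / (k * k * cin))
        self.w = rng.normal(0.0, scale, size=(cin, k * k * cout)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def _full_shape(self, h, w):
        return self.stride * (h - 1) + self.k, self.stride * (w - 1) + self.k

    def forward(self, x, train=True):
        n, h, w, _ = x.shape
        k, s, p = self.k, self.stride, self.pad
        t = (x.reshape(-1, self.cin) @ self.w).reshape(n, h, w, k, k, self.cout)
        fh, fw = self._full_shape(h, w)
        out = np.zeros((n, fh, fw, self.cout), dtype=F32)
        for i in range(k):
            for j in range(k):
                out[:, i : i + s * h : s, j : j + s * w : s, :] += t[:, :, :, i, j, :]
        y = out[:, p : p + s * h, p : p + s * w, :] + self.b
        if train:
            self._cache = (x, (h, w))
        return y

    def backward(self, dy):
        x, (h, w) = self._cache
        n = x.shape[0]
        k, s, p = self.k, self.stride, self.pad
        fh, fw = self._full_shape(h, w)
        dy_full = np.zeros((n, fh, fw, self.cout), dtype=F32)
        dy_full[:, p : p + s * h, p : p + s * w, :] = dy
        cols = np.empty((n, h, w, k, k, self.cout), dtype=F32)
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i, j, :] = dy_full[:, i : i + s * h : s, j : j + s * w : s, :]
        colsf = cols.reshape(-1, k * k * self.cout)
        self.dw[...] = x.reshape(-1, self.cin).T @ colsf
        self.db[...] = dy.reshape(-1, self.cout).sum(axis=0)
        dx = (colsf @ self.w.T).reshape(n, h, w, self.cin)
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class BatchNorm:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=True):
        if train:
            axes = tuple(range(x.ndim - 1))
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mu) * inv_std
        if train:
            self._cache = (xhat, inv_std, x.shape)
        y = xhat * self.gamma
        y += self.beta
        return y

    def backward(self, dy):
        xhat, inv_std, shape = self._cache
        axes = tuple(range(dy.ndim - 1))
        m = float(np.prod([shape[a] for a in range(len(shape) - 1)]))
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        dx = (
            self.gamma
            * inv_std
            * (dy - self.dbeta / m - xhat * (self.dgamma / m))
        )
        return dx.astype(F32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        dy = dy if dy.flags.writeable else dy.copy()
        dy *= self._mask
        return dy

    def params(self):
        return []


class Dense:
    def __init__(self, nin, nout, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / nin)
        self.w = rng.normal(0.0, scale, size=(nin, nout)).astype(F32)
        self.b = np.zeros(nout, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x, train=True):
        if train:
            self._cache = x
        return x @ self.w + self.b

    def backward(self, dy):
        x = self._cache
        self.dw[...] = x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Adam:
    """Adam over an explicit (value, gradient) parameter list."""

    def __init__(self, param_pairs, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = list(param_pairs)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def collect_params(layers):
    pairs = []
    for layer in layers:
        pairs.extend(layer.params())
    return pairs
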