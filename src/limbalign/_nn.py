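"""Minimal NumPy neural-network primitives for the landmark detector.

Implements exactly the layers the two-branch network needs — 2D
convolution (im2col + BLAS matmul), ReLU, nearest-neighbour upsampling,
global average pooling and a dense layer — each with a hand-written
backward pass, plus an Adam optimizer.  Deliberately small: a fixed layer
menu with cached forward activations, not a general autograd.

Array convention: feature maps are (N, C, H, W) float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "Upsample2x", "GlobalAvgPool", "Dense", "Adam"]


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    N, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(N, C * k * k, Ho * Wo)
    return np.ascontiguousarray(cols), Ho, Wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add the patch-matrix gradient back onto the input grid."""
    N, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    xg = np.zeros((N, C, Hp, Wp))
    cols = cols.reshape(N, C, k, k, Ho, Wo)
    for i in range(k):
        for j in range(k):
            xg[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += cols[
                :, :, i, j
            ]
    if pad:
        xg = xg[:, :, pad:-pad, pad:-pad]
    return xg


class Conv2D:
    """k x k convolution with same-style padding (pad = k // 2)."""

    def __init__(self, rng, c_in, c_out, k=3, stride=1):
        self.k, self.stride, self.pad = k, stride, k // 2
        self.c_in, self.c_out = c_in, c_out
        self.W = _he_init(rng, c_in * k * k, (c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        cols, Ho, Wo = _im2col(x, self.k, self.stride, self.pad)
        out = np.einsum("of,nfl->nol", self.W, cols, optimize=True)
        out += self.b[None, :, None]
        self._cache = (cols, x.shape)
        return out.reshape(x.shape[0], self.c_out, Ho, Wo)

    def backward(self, dout):
        cols, x_shape = self._cache
        N = dout.shape[0]
        dflat = dout.reshape(N, self.c_out, -1)
        self.dW += np.einsum("nol,nfl->of", dflat, cols, optimize=True)
        self.db += dflat.sum(axis=(0, 2))
        dcols = np.einsum("of,nol->nfl", self.W, dflat, optimize=True)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)


class ReLU:
    def __init__(self):
        self._mask = None

    params = ()

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Upsample2x:
    """Nearest-neighbour 2x spatial upsampling."""

    params = ()

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        N, C, H, W = dout.shape
        return dout.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool:
    def __init__(self):
        self._hw = None

    params = ()

    def forward(self, x):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        H, W = self._hw
        return dout[:, :, None, None] * np.full((1, 1, H, W), 1.0 / (H * W))


class Dense:
    def __init__(self, rng, d_in, d_out):
        self.W = _he_init(rng, d_in, (d_out, d_in))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW += dout.T @ self._x
        self.db += dout.sum(axis=0)
        return dout @ self.W


class Adam:
    """Adam with the usual bias correction; lr is mutable for schedules."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)  # list of (value, grad) array pairs
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
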