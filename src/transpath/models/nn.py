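"""Minimal float32 convolutional-network engine (numpy, CPU).

Implements exactly the layers the distance-matrix models need — 3x3 "same"
convolutions via im2col GEMM, 1x1 convolutions, ReLU and single-conv
residual blocks — with hand-written backward passes and plain stochastic
gradient descent.  Deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "Conv1x1", "relu", "Sequential", "ResidualBlock"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, L, L) -> (C*9, L*L) patch matrix for a 3x3 same convolution."""
    c, h, w = x.shape
    xp = np.zeros((c, h + 2, w + 2), dtype=x.dtype)
    xp[:, 1:-1, 1:-1] = x
    cols = np.empty((c, 9, h, w), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, k] = xp[:, di:di + h, dj:dj + w]
            k += 1
    return cols.reshape(c * 9, h * w)


def _col2im(dcol: np.ndarray, c: int, h: int, w: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    dcols = dcol.reshape(c, 9, h, w)
    dxp = np.zeros((c, h + 2, w + 2), dtype=dcol.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, di:di + h, dj:dj + w] += dcols[:, k]
            k += 1
    return dxp[:, 1:-1, 1:-1]


class Conv3x3:
    """3x3 same-padding convolution, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 std: float | None = None):
        if std is None:
            std = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, std, (c_out, c_in * 9)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        col = _im2col(x)
        y = self.w @ col + self.b[:, None]
        self._cache = (col, c, h, w)
        return y.reshape(-1, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, c, h, w = self._cache
        dyf = dy.reshape(dy.shape[0], -1)
        self.dw = dyf @ col.T
        self.db = dyf.sum(axis=1)
        dcol = self.w.T @ dyf
        return _col2im(dcol, c, h, w)

    def params(self):
        return [(self, "w", "dw"), (self, "b", "db")]


class Conv1x1:
    """Per-position linear map (the "fully connected" head cells)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 std: float | None = None):
        if std is None:
            std = np.sqrt(2.0 / c_in)
        self.w = rng.normal(0.0, std, (c_out, c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        xf = x.reshape(c, -1)
        y = self.w @ xf + self.b[:, None]
        self._cache = (xf, h, w)
        return y.reshape(-1, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf, h, w = self._cache
        dyf = dy.reshape(dy.shape[0], -1)
        self.dw = dyf @ xf.T
        self.db = dyf.sum(axis=1)
        return (self.w.T @ dyf).reshape(-1, h, w)

    def params(self):
        return [(self, "w", "dw"), (self, "b", "db")]


class Relu:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


def relu(x):
    return np.maximum(x, 0.0)


class ResidualBlock:
    """y = x + conv3x3(relu(x)); identity skip keeps deep stacks stable.

    The block convolution is initialized near zero so the untrained stack
    is close to the identity, which keeps plain SGD stable without any
    normalization layers.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 std: float = 0.01):
        self.act = Relu()
        self.conv = Conv3x3(channels, channels, rng, std=std)

    def forward(self, x):
        return x + self.conv.forward(self.act.forward(x))

    def backward(self, dy):
        return dy + self.act.backward(self.conv.backward(dy))

    def params(self):
        return self.conv.params()


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out
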