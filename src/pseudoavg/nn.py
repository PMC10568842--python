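"""Minimal CNN building blocks in numpy (channels-last, float32).

Implements exactly what the patch U-Net needs — 3x3 'same' convolution,
ReLU, 2x2 max-pool, nearest-neighbour upsampling, channel concatenation and
a sigmoid head — with hand-written backward passes.  Convolutions use an
im2col layout chosen so the single matmul per layer dominates runtime on one
CPU core.  All operations are deterministic.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, 9*C) patch matrix for a 3x3 'same' conv."""
    b, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    col = np.empty((b, h, w, 9 * c), dtype=F32)
    t = 0
    for ki in range(3):
        for kj in range(3):
            col[..., t * c : (t + 1) * c] = xp[:, ki : ki + h, kj : kj + w, :]
            t += 1
    return col.reshape(b * h * w, 9 * c)


class Conv3x3:
    """3x3 convolution, stride 1, zero 'same' padding, optional fused ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, relu: bool = True):
        fan_in = 9 * c_in
        scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU stacks
        self.w = (rng.standard_normal((fan_in, c_out)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.c_in, self.c_out, self.relu = c_in, c_out, relu
        self._col = None
        self._act = None
        self._in_shape = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, _ = x.shape
        col = _im2col(x)
        y = col @ self.w
        y += self.b
        y = y.reshape(b, h, w, self.c_out)
        if self.relu:
            np.maximum(y, 0.0, out=y)
        if train:  # keep col for the weight gradient (im2col is the hot path)
            self._col = col
            self._act = y
            self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray):
        if self.relu:
            dy = dy * (self._act > 0)
        b, h, w, _ = self._in_shape
        dy = dy.astype(F32, copy=False)
        dy_flat = dy.reshape(b * h * w, self.c_out)
        self.dw = self._col.T @ dy_flat
        self.db = dy_flat.sum(axis=0)
        # input gradient = correlation of dy with the flipped, transposed kernel
        w4 = self.w.reshape(3, 3, self.c_in, self.c_out)
        w_rot = w4[::-1, ::-1].transpose(0, 1, 3, 2).reshape(9 * self.c_out, self.c_in)
        w_rot = np.ascontiguousarray(w_rot)
        dx = (_im2col(dy) @ w_rot).reshape(b, h, w, self.c_in)
        self._col = self._act = None
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class MaxPool2:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        r = x.reshape(b, h // 2, 2, w // 2, 2, c)
        y = r.max(axis=(2, 4))
        if train:
            self._shape = x.shape
            self._x = x
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        r = self._x.reshape(b, h // 2, 2, w // 2, 2, c)
        winners = r == self._y[:, :, None, :, None, :]
        # split gradient among ties so the total is conserved
        counts = winners.sum(axis=(2, 4), keepdims=True).astype(F32)
        dx = winners * (dy[:, :, None, :, None, :].astype(F32, copy=False) / counts)
        self._x = self._y = None
        return dx.reshape(b, h, w, c).astype(F32)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = dy.shape
        return dy.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(F32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
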