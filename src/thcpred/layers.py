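"""Minimal NumPy building blocks for the 3-D multitask network.

Each layer stores its parameters and, after ``backward``, the matching
gradients; the :class:`Adam` optimizer walks the exposed parameter list.
Arrays are channels-last (B, D, H, W, C): a stride-1 'same' 3x3x3
convolution is computed as a sum of 27 shifted channel-mixing products,
each a single broadcasted ``matmul`` over the trailing channel axis, which
keeps memory flat relative to im2col on volumetric inputs and avoids
layout copies.

Everything is float32 end to end; given the same seed and inputs the
arithmetic is deterministic, which the training loop relies on for
reproducibility guarantees.
"""

from __future__ import annotations

from typing import List

import numpy as np

DT = np.float32


class Layer:
    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []


class Conv3d(Layer):
    """3x3x3 convolution, stride 1, same padding, channels-last."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 27
        self.w = (rng.standard_normal((3, 3, 3, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(DT)
        self.b = np.zeros(c_out, dtype=DT)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, d, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        self._xp, self._dims = xp, (b, d, h, w, c)
        n = b * d * h * w
        out2d = np.empty((n, self.b.size), dtype=DT)
        out2d[:] = self.b
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = np.ascontiguousarray(
                        xp[:, i : i + d, j : j + h, k : k + w, :]
                    ).reshape(n, c)
                    out2d += xs @ self.w[i, j, k]
        return out2d.reshape(b, d, h, w, self.b.size)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        b, d, h, w, c = self._dims
        n = b * d * h * w
        dout2d = np.ascontiguousarray(dout).reshape(n, -1)
        dxp = np.zeros_like(xp)
        self.db[:] = dout2d.sum(axis=0)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = np.ascontiguousarray(
                        xp[:, i : i + d, j : j + h, k : k + w, :]
                    ).reshape(n, c)
                    self.dw[i, j, k] = xs.T @ dout2d
                    dxp[:, i : i + d, j : j + h, k : k + w, :] += (
                        dout2d @ self.w[i, j, k].T
                    ).reshape(b, d, h, w, c)
        return dxp[:, 1:-1, 1:-1, 1:-1, :]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DT, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0).astype(DT, copy=False)


class MaxPool3d(Layer):
    """2x2x2 max pooling; spatial dims must be even (channels-last)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, d, h, w, c = x.shape
        xr = (
            x.reshape(b, d // 2, 2, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 7, 2, 4, 6)
            .reshape(b, d // 2, h // 2, w // 2, c, 8)
        )
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, d, h, w, c = self._shape
        dxw = np.zeros(dout.shape + (8,), dtype=DT)
        np.put_along_axis(dxw, self._idx[..., None], dout[..., None], axis=-1)
        return (
            dxw.reshape(b, d // 2, h // 2, w // 2, c, 2, 2, 2)
            .transpose(0, 1, 5, 2, 6, 3, 7, 4)
            .reshape(b, d, h, w, c)
        )


class Upsample3d(Layer):
    """Nearest-neighbour x2 upsampling in all three spatial dims."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, d, h, w, c = x.shape
        out = np.broadcast_to(
            x[:, :, None, :, None, :, None, :], (b, d, 2, h, 2, w, 2, c)
        ).reshape(b, 2 * d, 2 * h, 2 * w, c)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, d2, h2, w2, c = dout.shape
        return dout.reshape(b, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4, 6))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(DT)
        self.b = np.zeros(n_out, dtype=DT)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw[:] = self._x.T @ dout
        self.db[:] = dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam over the flat parameter lists exposed by a set of layers."""

    def __init__(self, layers: List[Layer], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params()]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for l in self.layers for p in l.params()]
        self.v = [np.zeros_like(p) for l in self.layers for p in l.params()]

    def step(self) -> None:
        self.t += 1
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params(), layer.grads()):
                m, v = self.m[i], self.v[i]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
                i += 1
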