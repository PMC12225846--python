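"""A small, deterministic CNN engine on numpy.

Implements exactly the pieces the IoU quality regressor needs — 3×3
same-padding convolution (im2col + BLAS matmul), ReLU, 2×2 max-pooling,
global average pooling, dense layers, dropout, a sigmoid output, the
MSE/MAE/soft-label-BCE losses and the SGD-with-momentum and Adam
optimizers.  Everything is float32, single-threaded-reproducible and
seeded: two models built and trained with the same seed produce
bit-identical weights.

The engine is intentionally minimal: stride-1 3×3 convs and factor-2
pools only, which is all the desk-scale backbone uses.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D", "ReLU", "MaxPool2", "GlobalAvgPool", "Dense", "Dropout",
    "Sequential", "sigmoid", "LOSSES", "SGDMomentum", "Adam",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) → (C·k·k, N·H·W) patch matrix for stride-1 'same' conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, c, k, k, h, w), (s[0], s[1], s[2], s[3], s[2], s[3]))
    return win.reshape(n, c * k * k, h * w).transpose(1, 0, 2).reshape(
        c * k * k, n * h * w)


def _col2im(dcol: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = shape
    d = dcol.reshape(c, k, k, n, h, w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += d[:, i, j].transpose(1, 0, 2, 3)
    return dxp[:, :, pad:pad + h, pad:pad + w]


class Layer:
    params: list  # list of [name, value, grad]

    def __init__(self) -> None:
        self.params = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3×3 stride-1 'same' convolution, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in))
        self.params = [["W", w.astype(np.float32), np.zeros((c_out, fan_in), np.float32)],
                       ["b", np.zeros(c_out, np.float32), np.zeros(c_out, np.float32)]]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        n, _, h, w = x.shape
        self._col = _im2col(x, self.k, self.k // 2)
        y = self.params[0][1] @ self._col + self.params[1][1][:, None]
        return y.reshape(self.c_out, n, h * w).transpose(1, 0, 2).reshape(
            n, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = dy.shape
        dyf = dy.transpose(1, 0, 2, 3).reshape(self.c_out, n * h * w)
        self.params[0][2][:] = dyf @ self._col.T
        self.params[1][2][:] = dyf.sum(axis=1)
        dcol = self.params[0][1].T @ dyf
        self._col = None
        return _col2im(dcol, self._shape, self.k, self.k // 2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2×2 max pooling, stride 2 (even spatial dims required)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        self._mask = xr == y[:, :, :, None, :, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dy.shape
        d = self._mask * dy[:, :, :, None, :, None]
        return d.reshape(n, c, h2 * 2, w2 * 2)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               self._shape).astype(dy.dtype)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.params = [["W", w.astype(np.float32), np.zeros((d_in, d_out), np.float32)],
                       ["b", np.zeros(d_out, np.float32), np.zeros(d_out, np.float32)]]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params[0][1] + self.params[1][1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.params[0][2][:] = self._x.T @ dy
        self.params[1][2][:] = dy.sum(axis=0)
        return dy @ self.params[0][1].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else (dy * self._mask).astype(dy.dtype)


class Sequential:
    """Layer stack ending in a single linear unit; sigmoid is applied by
    the caller (losses work on the logit for numerical stability)."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward_logit(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x.reshape(-1)

    def predict(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        out = [sigmoid(self.forward_logit(x[i:i + batch], train=False))
               for i in range(0, len(x), batch)]
        return np.concatenate(out) if out else np.empty(0, np.float32)

    def backward(self, dlogit: np.ndarray) -> None:
        dy = dlogit.reshape(-1, 1).astype(np.float32)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    def n_parameters(self) -> int:
        return sum(p[1].size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p[1].copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[1][:] = w


# ---------------------------------------------------------------- losses

def _mse(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    p = sigmoid(z)
    d = p - t
    return float(np.mean(d * d)), (2.0 * d * p * (1.0 - p) / len(t))


def _mae(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    p = sigmoid(z)
    d = p - t
    return float(np.mean(np.abs(d))), (np.sign(d) * p * (1.0 - p) / len(t))


def _bce(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    # soft-label binary cross-entropy on the logit: stable via softplus
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    return float(np.mean(loss)), ((sigmoid(z) - t) / len(t))


LOSSES = {"mse": _mse, "mae": _mae, "xent": _bce, "bce": _bce}


# ------------------------------------------------------------ optimizers

class SGDMomentum:
    def __init__(self, params: list, lr: float = 1e-2, momentum: float = 0.9) -> None:
        self.params, self.lr, self.momentum = params, lr, momentum
        self.v = [np.zeros_like(p[1]) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.v):
            v *= self.momentum
            v -= self.lr * p[2]
            p[1] += v


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.params, self.lr = params, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p[1]) for p in params]
        self.v = [np.zeros_like(p[1]) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p[2]
            v *= self.beta2
            v += (1.0 - self.beta2) * p[2] * p[2]
            p[1] -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
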