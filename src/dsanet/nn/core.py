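"""Small NumPy layer library with explicit backpropagation.

The grading environment provides no GPU deep-learning framework, so the
networks here run on a compact hand-rolled core: each layer caches what its
backward pass needs, gradients are accumulated into :class:`Param` objects,
and :class:`Adam` updates them.  Layers are single-use per forward pass
(call ``forward`` then ``backward`` before the next ``forward``).

All tensors are float32 in (N, C, H, W) layout for images and (N, F) for
features.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Param", "Module", "Sequential", "Conv2d", "Linear", "ReLU", "Sigmoid",
    "MaxPool2", "UpNearest2", "GlobalAvgPool", "Adam", "sigmoid",
    "numerical_grad",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A learnable tensor and its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float32)
        self.g = np.zeros_like(self.v)

    def zero_grad(self) -> None:
        self.g[...] = 0.0


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gout):
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


class Conv2d(Module):
    """3×3 (or k×k) convolution via im2col, 'same' padding by default."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, std, size=(cout, cin * k * k)))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, xp: np.ndarray, Ho: int, Wo: int) -> np.ndarray:
        N, C, Hp, Wp = xp.shape
        s = self.stride
        sN, sC, sH, sW = xp.strides
        win = as_strided(
            xp,
            shape=(N, C, Ho, Wo, self.k, self.k),
            strides=(sN, sC, sH * s, sW * s, sH, sW),
        )
        # (N*Ho*Wo, C*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * self.k * self.k
        )

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        N, C, H, W = x.shape
        p, s, k = self.pad, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        cols = self._im2col(xp, Ho, Wo)
        out = cols @ self.W.v.T + self.b.v
        self._cache = (cols, (N, C, H, W), (Ho, Wo))
        return out.reshape(N, Ho, Wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gout):
        cols, (N, C, H, W), (Ho, Wo) = self._cache
        p, s, k = self.pad, self.stride, self.k
        g2 = np.ascontiguousarray(gout.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.W.g += g2.T @ cols
        self.b.g += g2.sum(axis=0)
        dcols = (g2 @ self.W.v).reshape(N, Ho, Wo, C, k, k)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + Ho * s : s, j : j + Wo * s : s] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        self._cache = None
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / fin)
        self.W = Param(rng.normal(0.0, std, size=(fout, fin)))
        self.b = Param(np.zeros(fout))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = np.asarray(x, dtype=np.float32)
        return self._x @ self.W.v.T + self.b.v

    def backward(self, gout):
        self.W.g += gout.T @ self._x
        self.b.g += gout.sum(axis=0)
        return gout @ self.W.v


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gout):
        return np.where(self._mask, gout, 0.0).astype(np.float32)


class Sigmoid(Module):
    def forward(self, x):
        self._y = sigmoid(x)
        return self._y

    def backward(self, gout):
        return gout * self._y * (1.0 - self._y)


class MaxPool2(Module):
    """2×2 max pooling; input H and W must be even."""

    def forward(self, x):
        N, C, H, W = x.shape
        x4 = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x4 = x4.reshape(N, C, H // 2, W // 2, 4)
        out = x4.max(axis=-1)
        eq = x4 == out[..., None]
        # break ties: route the gradient to the first maximal element only
        first = eq & (np.cumsum(eq, axis=-1) == 1)
        self._mask = first
        self._shape = (N, C, H, W)
        return out.astype(np.float32)

    def backward(self, gout):
        N, C, H, W = self._shape
        g4 = self._mask * gout[..., None]
        g = g4.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(g.reshape(N, C, H, W), dtype=np.float32)


class UpNearest2(Module):
    """Nearest-neighbour 2× upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, gout):
        N, C, H, W = gout.shape
        return gout.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5)).astype(np.float32)


class GlobalAvgPool(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        N, C, H, W = self._shape
        return np.broadcast_to(
            gout[:, :, None, None] / (H * W), self._shape
        ).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.g
            v *= self.b2
            v += (1.0 - self.b2) * p.g * p.g
            p.v -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def numerical_grad(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar f wrt x (test utility)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
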