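"""Minimal numpy neural-network primitives for the convolutional VAE.

Implements exactly the building blocks the autoencoder needs — strided 2-D
convolution (im2col + matmul), its adjoint as the transposed convolution,
dense layers, ReLU/sigmoid, and an Adam optimizer.  Everything operates on
NHWC float64 arrays, keeps explicit forward caches, and takes its random
state from a caller-supplied generator so training is reproducible bit for
bit on one platform.

The transposed convolution is implemented as the exact adjoint (col2im) of
the corresponding strided convolution, which is both the textbook
definition and a large code saving: the conv backward pass and the
transposed-conv forward pass share one primitive.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ConvTranspose2D",
    "Dense",
    "ReLU",
    "Sigmoid",
    "Adam",
    "im2col",
    "col2im",
]


def im2col(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """Extract sliding k x k patches with stride ``s`` after padding ``p``.

    x: (B, H, W, C)  ->  (B, Ho, Wo, k, k, C) with Ho = (H + 2p - k)//s + 1.
    """
    B, H, W, C = x.shape
    ho = (H + 2 * p - k) // s + 1
    wo = (W + 2 * p - k) // s + 1
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    sb, sh, sw, sc = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(B, ho, wo, k, k, C),
        strides=(sb, sh * s, sw * s, sh, sw, sc),
        writeable=False,
    )
    return np.ascontiguousarray(cols)


def col2im(
    cols: np.ndarray, H: int, W: int, k: int, s: int, p: int
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back onto the image."""
    B, ho, wo = cols.shape[:3]
    C = cols.shape[-1]
    xp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=cols.dtype)
    for ki in range(k):
        for kj in range(k):
            xp[:, ki : ki + s * ho : s, kj : kj + s * wo : s, :] += cols[
                :, :, :, ki, kj, :
            ]
    return xp[:, p : p + H, p : p + W, :]


class Layer:
    """Base class: parameterized layers expose ``params`` / ``grads`` lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Strided 2-D convolution, NHWC, 'same'-style padding (k-1)//2."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        s: int,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, k, s
        self.p = (k - 1) // 2
        fan_in = k * k * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        b = np.zeros(c_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        w, b = self.params
        cols = im2col(x, self.k, self.s, self.p)
        B, ho, wo = cols.shape[:3]
        flat = cols.reshape(B * ho * wo, -1)
        y = (flat @ w + b).reshape(B, ho, wo, self.c_out)
        self._cache = (x.shape, flat, (B, ho, wo))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        x_shape, flat, (B, ho, wo) = self._cache
        dy_flat = dy.reshape(B * ho * wo, self.c_out)
        self.grads[0][...] = flat.T @ dy_flat
        self.grads[1][...] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ w.T).reshape(B, ho, wo, self.k, self.k, self.c_in)
        return col2im(dcols, x_shape[1], x_shape[2], self.k, self.s, self.p)


class ConvTranspose2D(Layer):
    """Transposed (fractionally strided) convolution: adjoint of Conv2D.

    Maps (B, h, w, c_in) -> (B, out_h, out_w, c_out) where the paired
    forward convolution would map (out_h, out_w, c_out) -> (h, w, c_in).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        s: int,
        out_hw: tuple[int, int],
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, k, s
        self.p = (k - 1) // 2
        self.out_hw = out_hw
        # each output pixel receives ~k*k/s^2 contributions
        w = rng.normal(
            0.0, np.sqrt(2.0 / (self.k * self.k * c_in / (s * s))),
            size=(k * k * c_out, c_in),
        )
        b = np.zeros(c_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        w, b = self.params
        B, h, wdt, _ = x.shape
        flat = x.reshape(B * h * wdt, self.c_in)
        dcols = (flat @ w.T).reshape(B, h, wdt, self.k, self.k, self.c_out)
        y = col2im(dcols, *self.out_hw, self.k, self.s, self.p)
        self._cache = (x, (B, h, wdt))
        return y + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        x, (B, h, wdt) = self._cache
        cols = im2col(dy, self.k, self.s, self.p)  # (B, h, w, k, k, c_out)
        cols_flat = cols.reshape(B * h * wdt, -1)
        x_flat = x.reshape(B * h * wdt, self.c_in)
        self.grads[0][...] = cols_flat.T @ x_flat
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        return (cols_flat @ w).reshape(B, h, wdt, self.c_in)


class Dense(Layer):
    def __init__(
        self, n_in: int, n_out: int, rng: np.random.Generator, w_scale: float | None = None
    ) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in) if w_scale is None else w_scale
        w = rng.normal(0.0, scale, size=(n_in, n_out))
        b = np.zeros(n_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.params[0].T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Adam:
    """Adam optimizer over a flat list of (param, grad) pairs."""

    def __init__(
        self,
        layers: list[Layer],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.pairs = [
            (p, g) for layer in layers for p, g in zip(layer.params, layer.grads)
        ]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
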