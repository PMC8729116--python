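"""Minimal convolutional-network engine (numpy, float32, CPU).

Implements exactly the pieces the bowel-sound classifier needs: "same"
convolutions (computed as one shifted BLAS matmul per kernel tap, which
avoids large im2col transposes), ReLU, max pooling along the Mel axis,
inverted dropout, dense layers, a softmax/cross-entropy head and the
Adadelta update rule (rho = 0.95, eps = 1e-6, step size 1.0 as in the
original formulation, which needs no tuned learning rate).

Tensors are channels-last ``(N, H, W, C)``.  All randomness (weight
init, dropout masks) flows through a single ``numpy.random.Generator``
supplied by the caller, so training is deterministic given a seed.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs; empty for stateless layers."""
        return []


class Conv2D(Layer):
    """Convolution with edge-preserving (same) zero padding.

    Weights have shape ``(kh, kw, C_in, C_out)``; the output at (h, w) is
    ``sum_ij x_padded[h+i, w+j, :] @ W[i, j]``.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        self.W = (rng.standard_normal((kh, kw, in_ch, out_ch))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.pad = (kh // 2, kw // 2)

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        kh, kw = self.kernel
        ph, pw = self.pad
        f = self.W.shape[-1]
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        # im2col, tap-major: column block k = (i*kw + j) holds channel
        # values of the input shifted by tap (i, j)
        col = np.empty((n * h * w, kh * kw * c), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                k = i * kw + j
                col[:, k * c:(k + 1) * c] = \
                    xp[:, i:i + h, j:j + w, :].reshape(-1, c)
        out = col @ self.W.reshape(-1, f) + self.b
        self._col = col
        self._xshape = x.shape
        return out.reshape(n, h, w, f)

    def backward(self, grad):
        n, h, w, c = self._xshape
        kh, kw = self.kernel
        ph, pw = self.pad
        f = self.W.shape[-1]
        g = grad.reshape(-1, f)
        self.db[...] = g.sum(axis=0)
        self.dW[...] = (self._col.T @ g).reshape(self.dW.shape)
        dcol = g @ self.W.reshape(-1, f).T
        dxp = np.zeros((n, h + 2 * ph, w + 2 * pw, c), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                k = i * kw + j
                dxp[:, i:i + h, j:j + w, :] += \
                    dcol[:, k * c:(k + 1) * c].reshape(n, h, w, c)
        self._col = None
        return dxp[:, ph:ph + h, pw:pw + w, :]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling; pool size must divide the input."""

    def __init__(self, pool: tuple[int, int]):
        self.pool = pool

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        ph, pw = self.pool
        if h % ph or w % pw:
            raise ValueError(
                f"pool {self.pool} does not divide feature map {h}x{w}"
            )
        r = x.reshape(n, h // ph, ph, w // pw, pw, c)
        m = r.max(axis=(2, 4))
        # mask of maxima for gradient routing (ties share the gradient)
        self._mask = r == m[:, :, None, :, None, :]
        self._r_shape = r.shape
        return m

    def backward(self, grad):
        n, hp, ph, wp, pw, c = self._r_shape
        g = grad[:, :, None, :, None, :] * self._mask
        # ties (equal values in one window) would duplicate gradient;
        # normalize by the number of maxima per window
        cnt = self._mask.sum(axis=(2, 4), keepdims=True, dtype=np.float32)
        g = g / cnt
        return g.reshape(n, hp * ph, wp * pw, c)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape, dtype=np.float32) < keep)
                      .astype(np.float32) / np.float32(keep))
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((in_dim, out_dim))
                  * np.sqrt(2.0 / in_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(weights) != len(own):
            raise ValueError("weight list length mismatch")
        for (p, _), w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


class Adadelta:
    """Adadelta: per-parameter RMS-scaled steps, no tuned learning rate."""

    def __init__(self, params, rho: float = 0.95, eps: float = 1e-6,
                 lr: float = 1.0):
        self.params = params
        self.rho = rho
        self.eps = eps
        self.lr = lr
        self.Eg = [np.zeros_like(p) for p, _ in params]
        self.Ed = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        for (p, g), Eg, Ed in zip(self.params, self.Eg, self.Ed):
            Eg *= self.rho
            Eg += (1.0 - self.rho) * g * g
            dx = -np.sqrt(Ed + self.eps) / np.sqrt(Eg + self.eps) * g
            Ed *= self.rho
            Ed += (1.0 - self.rho) * dx * dx
            p += self.lr * dx


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / np.float32(n)
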