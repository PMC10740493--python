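"""Minimal numpy neural-network core for the 1-D DCGAN.

Layers operate on ``(batch, channels, length)`` arrays (Dense on
``(batch, features)``), store their parameters/gradients in :class:`Param`
objects, and implement explicit ``forward``/``backward`` passes.  Gradients
accumulate across backward calls until ``zero_grad``; :class:`Adam` updates
parameters in place.  All stochastic layers draw from an injected
``numpy.random.Generator`` so training is bit-reproducible per seed.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=float)
        self.g = np.zeros_like(self.v)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_std: float = 0.02):
        self.W = Param(rng.normal(0.0, init_std, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, grad):
        self.W.g += self._x.T @ grad
        self.b.g += grad.sum(axis=0)
        return grad @ self.W.v.T


class Conv1d(Layer):
    """'same'-padded 1-D convolution with stride, via an im2col matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, init_std: float = 0.02):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.W = Param(rng.normal(0.0, init_std, size=(c_out, c_in * kernel)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def _geometry(self, L: int):
        L_out = -(-L // self.stride)  # ceil
        pad_total = max((L_out - 1) * self.stride + self.k - L, 0)
        return L_out, pad_total // 2, pad_total - pad_total // 2

    def forward(self, x, training):
        B, C, L = x.shape
        L_out, pl, pr = self._geometry(L)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # cols: (B, L_out, C*k) via a strided window view (one copy)
        view = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = np.ascontiguousarray(
            view[:, :, ::self.stride, :].transpose(0, 2, 1, 3)
        ).reshape(B, L_out, C * self.k)
        self._cols, self._shape, self._pads = cols, (B, C, L), (pl, pr)
        y = cols @ self.W.v.T + self.b.v  # (B, L_out, c_out)
        return y.transpose(0, 2, 1)

    def backward(self, grad):
        B, C, L = self._shape
        gt = grad.transpose(0, 2, 1)  # (B, L_out, c_out)
        L_out = gt.shape[1]
        gt2 = gt.reshape(-1, gt.shape[2])
        self.W.g += gt2.T @ self._cols.reshape(-1, self._cols.shape[2])
        self.b.g += gt2.sum(axis=0)
        gcols = gt @ self.W.v  # (B, L_out, C*k)
        pl, pr = self._pads
        gxp = np.zeros((B, C, L + pl + pr))
        starts = np.arange(L_out) * self.stride
        # per tap j the scatter indices are unique, so buffered += is exact
        for j in range(self.k):
            gxp[:, :, starts + j] += gcols[:, :, j::self.k].transpose(0, 2, 1)
        return gxp[:, :, pl:pl + L]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        self._cache = (xhat, std, training, x.shape)
        return self.gamma.v[None, :, None] * xhat + self.beta.v[None, :, None]

    def backward(self, grad):
        xhat, std, training, shape = self._cache
        B, C, L = shape
        self.gamma.g += (grad * xhat).sum(axis=(0, 2))
        self.beta.g += grad.sum(axis=(0, 2))
        gxhat = grad * self.gamma.v[None, :, None]
        if not training:
            return gxhat / std[None, :, None]
        N = B * L
        s1 = gxhat.sum(axis=(0, 2))[None, :, None]
        s2 = (gxhat * xhat).sum(axis=(0, 2))[None, :, None]
        return (gxhat - s1 / N - xhat * s2 / N) / std[None, :, None]


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Tanh(Layer):
    def forward(self, x, training):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, training):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout p must lie in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x, training):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class UpsampleNN(Layer):
    """Nearest-neighbour upsampling by an integer factor along length."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x, training):
        return np.repeat(x, self.factor, axis=2)

    def backward(self, grad):
        B, C, L = grad.shape
        return grad.reshape(B, C, L // self.factor, self.factor).sum(axis=3)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape  # per-sample shape

    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Flatten(Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def zero_grad(params: list[Param]) -> None:
    for p in params:
        p.g[...] = 0.0


class Adam:
    def __init__(self, params: list[Param], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, s in zip(self.params, self.m, self.s):
            m[...] = self.b1 * m + (1 - self.b1) * p.g
            s[...] = self.b2 * s + (1 - self.b2) * p.g**2
            mhat = m / (1 - self.b1**self.t)
            shat = s / (1 - self.b2**self.t)
            p.v -= self.lr * mhat / (np.sqrt(shat) + self.eps)


def rfft_magnitude_forward(x: np.ndarray):
    """One-sided FFT magnitude of the last axis, with a backward cache."""
    X = np.fft.rfft(x, axis=-1)
    mag = np.abs(X)
    return mag, (X, mag, x.shape[-1])


def rfft_magnitude_backward(grad_mag: np.ndarray, cache) -> np.ndarray:
    """Exact adjoint of ``rfft_magnitude_forward``.

    d|X_k|/dx is X_k/|X_k| pulled back through the one-sided real FFT; the
    interior bins of the Hermitian-extended spectrum are halved before the
    inverse transform so the adjoint matches the one-sided parameterisation.
    """
    X, mag, n = cache
    safe = np.where(mag > 0, mag, 1.0)
    h = grad_mag * X / safe
    h = h.copy()
    if n % 2 == 0:
        h[..., 1:-1] *= 0.5
    else:
        h[..., 1:] *= 0.5
    return n * np.fft.irfft(h, n=n, axis=-1)
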