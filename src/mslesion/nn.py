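"""Minimal NumPy neural-network engine with exact backpropagation.

Supports the two architectures used for spectral-cube classification: a
channels-last 2D conv net and a 3D-convolutional VGG variant.  Layers are
plain Python objects with ``forward``/``backward`` methods; convolutions use
im2col (``sliding_window_view``) with SAME padding, so output spatial size is
``ceil(n / stride)``.  All randomness flows through explicit
``numpy.random.Generator`` instances, making training bit-reproducible.

Gradients for every layer are verified against central finite differences in
the test suite; this engine is deliberately small, not fast, and is sized for
desk-scale cubes (tens of pixels per side).
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float64


def he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    """SAME-padding split for one axis: (out_size, pad_before, pad_after)."""
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    before = total // 2
    return out, before, total - before


class Layer:
    """Base layer; parameter-free layers inherit the empty defaults."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """SAME-padded 2D convolution on (N, H, W, C) input, optional ReLU."""

    def __init__(self, in_channels: int, filters: int, kernel: int = 3,
                 stride: int = 1, activation: str = "relu",
                 init: str = "glorot_uniform", rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.k, self.s, self.activation = kernel, stride, activation
        fan_in = kernel * kernel * in_channels
        fan_out = kernel * kernel * filters
        if init == "he_uniform":
            w = he_uniform(rng, fan_in, (fan_in, filters))
        else:
            w = glorot_uniform(rng, fan_in, fan_out, (fan_in, filters))
        self.W = w
        self.b = np.zeros(filters, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        k, s = self.k, self.s
        ho, pt, pb = _same_pad(h, k, s)
        wo, pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))   # N, Hv, Wv, C, k, k
        win = win[:, ::s, ::s][:, :ho, :wo]
        cols = np.ascontiguousarray(np.moveaxis(win, 3, 5))  # N, Ho, Wo, k, k, C
        self._cols = cols.reshape(n, ho, wo, k * k * c)
        self._in_shape, self._pads = x.shape, (pt, pb, pl, pr)
        z = self._cols @ self.W + self.b
        self._z = z
        return relu(z) if self.activation == "relu" else z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        n, ho, wo, f = grad.shape
        k, s = self.k, self.s
        _, h, w, c = self._in_shape
        pt, pb, pl, pr = self._pads
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        g2 = grad.reshape(-1, f)
        self.grads[0][...] = cols2.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        dcols = (g2 @ self.W.T).reshape(n, ho, wo, k, k, c)
        dxp = np.zeros((n, h + pt + pb, w + pl + pr, c), dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, pt:pt + h, pl:pl + w, :]


class Conv3D(Layer):
    """SAME-padded 3D convolution on (N, H, W, D, C) input, optional ReLU."""

    def __init__(self, in_channels: int, filters: int, kernel: int = 3,
                 stride: int = 1, activation: str = "relu",
                 init: str = "he_uniform", rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.k, self.s, self.activation = kernel, stride, activation
        fan_in = kernel ** 3 * in_channels
        fan_out = kernel ** 3 * filters
        if init == "he_uniform":
            w = he_uniform(rng, fan_in, (fan_in, filters))
        else:
            w = glorot_uniform(rng, fan_in, fan_out, (fan_in, filters))
        self.W = w
        self.b = np.zeros(filters, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        n, h, w, d, c = x.shape
        k, s = self.k, self.s
        ho, p0a, p0b = _same_pad(h, k, s)
        wo, p1a, p1b = _same_pad(w, k, s)
        do, p2a, p2b = _same_pad(d, k, s)
        xp = np.pad(x, ((0, 0), (p0a, p0b), (p1a, p1b), (p2a, p2b), (0, 0)))
        win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        win = win[:, ::s, ::s, ::s][:, :ho, :wo, :do]        # N,Ho,Wo,Do,C,k,k,k
        cols = np.ascontiguousarray(np.moveaxis(win, 4, 7))  # N,Ho,Wo,Do,k,k,k,C
        self._cols = cols.reshape(n, ho, wo, do, k ** 3 * c)
        self._in_shape = x.shape
        self._pads = (p0a, p0b, p1a, p1b, p2a, p2b)
        z = self._cols @ self.W + self.b
        self._z = z
        return relu(z) if self.activation == "relu" else z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        n, ho, wo, do, f = grad.shape
        k, s = self.k, self.s
        _, h, w, d, c = self._in_shape
        p0a, p0b, p1a, p1b, p2a, p2b = self._pads
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        g2 = grad.reshape(-1, f)
        self.grads[0][...] = cols2.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        dcols = (g2 @ self.W.T).reshape(n, ho, wo, do, k, k, k, c)
        dxp = np.zeros((n, h + p0a + p0b, w + p1a + p1b, d + p2a + p2b, c), dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                for kd in range(k):
                    dxp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, kd:kd + s * do:s, :] += \
                        dcols[:, :, :, :, ki, kj, kd, :]
        return dxp[:, p0a:p0a + h, p1a:p1a + w, p2a:p2a + d, :]


class MaxPool3D(Layer):
    """2x2x2 max pooling with ceil-mode (odd axes padded with -inf)."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.p = pool

    def forward(self, x, train=False, rng=None):
        p = self.p
        n, h, w, d, c = x.shape
        pads = [(-s) % p for s in (h, w, d)]
        xp = np.pad(x, ((0, 0), (0, pads[0]), (0, pads[1]), (0, pads[2]), (0, 0)),
                    constant_values=-np.inf)
        ho, wo, do = xp.shape[1] // p, xp.shape[2] // p, xp.shape[3] // p
        win = xp.reshape(n, ho, p, wo, p, do, p, c)
        out = win.max(axis=(2, 4, 6))
        self._win, self._out = win, out
        self._in_shape, self._pads = x.shape, pads
        return out

    def backward(self, grad):
        n, h, w, d, c = self._in_shape
        win, out = self._win, self._out
        mask = win == out[:, :, None, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4, 6), keepdims=True)
        g = mask * (grad[:, :, None, :, None, :, None, :] / counts)
        hp, wp, dp = (s + pad for s, pad in zip((h, w, d), self._pads))
        dxp = g.reshape(n, hp, wp, dp, c)
        return dxp[:, :h, :w, :d, :]


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, activation: str = "none",
                 init: str = "glorot_uniform", rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if init == "he_uniform":
            self.W = he_uniform(rng, in_features, (in_features, units))
        else:
            self.W = glorot_uniform(rng, in_features, units, (in_features, units))
        self.b = np.zeros(units, dtype=DTYPE)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        z = x @ self.W + self.b
        self._z = z
        return relu(z) if self.activation == "relu" else z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Network:
    """A feed-forward stack ending in class logits (softmax applied outside)."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        out = [softmax(self.forward(x[i:i + batch_size]))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        """Gradient of the given class logit w.r.t. the input (eval mode)."""
        logits = self.forward(x, train=False)
        seed = np.zeros_like(logits)
        seed[:, class_index] = 1.0
        return self.backward(seed)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * math.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def cross_entropy_with_logits(logits: np.ndarray, onehot: np.ndarray,
                              sample_weights: np.ndarray | None = None,
                              eps: float = 1e-7) -> tuple[float, np.ndarray]:
    """Mean weighted categorical cross-entropy and its gradient w.r.t. logits."""
    n = logits.shape[0]
    s = softmax(logits)
    w = np.ones(n, dtype=DTYPE) if sample_weights is None else sample_weights
    per = -(onehot * np.log(np.maximum(s, eps))).sum(axis=1)
    loss = float(np.mean(w * per))
    dlogits = (s - onehot) * (w / n)[:, None]
    return loss, dlogits
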