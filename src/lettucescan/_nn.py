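"""Minimal NumPy neural-network framework for small patch classifiers.

Implements exactly the layers the 20x20-patch model needs — 3x3 same-padding
convolution (im2col, BLAS matmul), spatial batch normalisation, ReLU, 2x2 max
pooling, dense layers, inverted dropout — together with an Adam optimiser and
a sigmoid/binary-cross-entropy head.  Everything is float32, single-threaded
deterministic given the supplied :class:`numpy.random.Generator`.

The tensor layout is channels-last ``(N, H, W, C)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base class: stateless by default, no parameters."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def state(self) -> list[np.ndarray]:
        """Arrays to persist beyond params (e.g. BN running stats)."""
        return []

    def forward(self, x, training: bool, rng) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution, stride 1, zero same-padding, channels-last."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        # He initialisation for ReLU stacks.
        std = np.sqrt(2.0 / (9 * cin))
        self.W = rng.normal(0.0, std, size=(cin * 9, cout)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.cin, self.cout = cin, cout
        self._cols = None
        self._shape = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        # (N, H, W, C, 3, 3) -> (N*H*W, C*9); reshape copies into contiguity.
        cols = sliding_window_view(xp, (3, 3), axis=(1, 2))
        cols = cols.reshape(n * h * w, c * 9)
        out = cols @ self.W + self.b
        if training:
            self._cols, self._shape = cols, (n, h, w, c)
        return out.reshape(n, h, w, self.cout)

    def backward(self, g):
        n, h, w, c = self._shape
        g2 = g.reshape(n * h * w, self.cout)
        self.dW[...] = self._cols.T @ g2
        self.db[...] = g2.sum(axis=0)
        dcols = (g2 @ self.W.T).reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=F32)
        for i in range(3):
            for j in range(3):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, :, i, j]
        self._cols = None
        return dxp[:, 1:h + 1, 1:w + 1, :]


class BatchNorm(Layer):
    """Spatial batch normalisation over (N, H, W) per channel."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros(c, dtype=F32)
        self.dbeta = np.zeros(c, dtype=F32)
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._xhat = None
        self._ivar = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def state(self):
        return [self.run_mean, self.run_var]

    def forward(self, x, training, rng):
        if training:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.run_mean[...] = (self.momentum * self.run_mean
                                  + (1 - self.momentum) * mu)
            self.run_var[...] = (self.momentum * self.run_var
                                 + (1 - self.momentum) * var)
        else:
            mu, var = self.run_mean, self.run_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        if training:
            self._xhat, self._ivar = xhat.astype(F32), ivar.astype(F32)
        return (self.gamma * xhat + self.beta).astype(F32)

    def backward(self, g):
        xhat, ivar = self._xhat, self._ivar
        axes = (0, 1, 2)
        m = g.shape[0] * g.shape[1] * g.shape[2]
        self.dgamma[...] = (g * xhat).sum(axis=axes)
        self.dbeta[...] = g.sum(axis=axes)
        dxhat = g * self.gamma
        dx = (ivar / m) * (m * dxhat
                           - dxhat.sum(axis=axes)
                           - xhat * (dxhat * xhat).sum(axis=axes))
        self._xhat = self._ivar = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties share the gradient equally."""

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if training:
            mask = xr == out[:, :, None, :, None, :]
            self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
            self._shape = (n, h, w, c)
        return out

    def backward(self, g):
        n, h, w, c = self._shape
        gx = self._mask * g[:, :, None, :, None, :]
        self._mask = None
        return gx.reshape(n, h, w, c).astype(F32)


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / din)
        self.W = rng.normal(0.0, std, size=(din, dout)).astype(F32)
        self.b = np.zeros(dout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training, rng):
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        dx = g @ self.W.T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p

    def forward(self, x, training, rng):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(F32) / F32(1 - self.p)
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask


class Network:
    """A plain layer sequence with a sigmoid/BCE head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, g) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x) -> np.ndarray:
        z = self.forward(x, training=False).ravel()
        return sigmoid(z)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def state_arrays(self):
        return self.params() + [s for layer in self.layers for s in layer.state()]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss_and_grad(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on logits; returns (mean loss, dL/dz)."""
    z = z.ravel().astype(np.float64)
    p = sigmoid(z)
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    dz = ((p - y) / z.size).astype(F32).reshape(-1, 1)
    return float(loss), dz


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
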