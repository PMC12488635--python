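"""Minimal numpy neural-network layers with explicit backpropagation.

The classifier and the gating network are trained jointly with Adam, so
every layer implements an exact analytic backward pass; the test suite
verifies the gradients against central finite differences.  Tensors are
(batch, channels, length) for the convolutional stages and (batch,
features) for the dense stages.  All stochastic elements (initialization,
dropout masks) draw from generators seeded by the caller, making training
bit-reproducible on one device.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv1D(Layer):
    """1-D convolution, stride 1, zero same-padding, odd kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError("kernel size must be odd and >= 1")
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.W = glorot_uniform(rng, (c_out, c_in, kernel), fan_in, fan_out)
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        out = np.zeros((B, self.W.shape[0], L))
        for k in range(self.kernel):
            out += np.einsum("oc,bcl->bol", self.W[:, :, k], xp[:, :, k:k + L])
        out += self.b[None, :, None]
        self._xp, self._L = xp, L
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, L = self._xp, self._L
        dxp = np.zeros_like(xp)
        dW, db = self.grads
        dW[...] = 0.0
        for k in range(self.kernel):
            dW[:, :, k] = np.einsum("bol,bcl->oc", dout, xp[:, :, k:k + L])
            dxp[:, :, k:k + L] += np.einsum("oc,bol->bcl", self.W[:, :, k], dout)
        db[...] = dout.sum(axis=(0, 2))
        return dxp[:, :, self.pad:self.pad + L] if self.pad else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, x.shape[0] * x.shape[2], train)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, m, train = self._cache
        dgamma, dbeta = self.grads
        dgamma[...] = (dout * xhat).sum(axis=(0, 2))
        dbeta[...] = dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        if not train:
            return dxhat * inv[None, :, None]
        # batch statistics participate in the graph during training
        term = dxhat - dxhat.mean(axis=(0, 2), keepdims=True) \
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        return term * inv[None, :, None]


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, width: int = 2):
        super().__init__()
        self.width = width

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, L = x.shape
        Lo = L // self.width
        if Lo < 1:
            raise ValueError(f"max-pool input length {L} shorter than pool width {self.width}")
        xt = x[:, :, :Lo * self.width].reshape(B, C, Lo, self.width)
        self._argmax = xt.argmax(axis=3)
        self._shape = x.shape
        return xt.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        Lo = dout.shape[2]
        dx = np.zeros((B, C, Lo, self.width))
        np.put_along_axis(dx, self._argmax[..., None], dout[..., None], axis=3)
        out = np.zeros((B, C, L))
        out[:, :, :Lo * self.width] = dx.reshape(B, C, Lo * self.width)
        return out


class GlobalAvgPool(Layer):
    """(B, C, L) -> (B, C) by averaging over length."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, :, None], self._L, axis=2) / self._L


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dW, db = self.grads
        dW[...] = self._x.T @ dout
        db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
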