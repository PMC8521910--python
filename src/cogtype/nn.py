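"""Minimal 1-D convolutional network substrate (numpy, CPU, deterministic).

Implements exactly what the severity models need: same-padding 1-D
convolutions, ReLU, dense layers, mean-squared-error loss and the RMSprop
update rule, with explicit backpropagation.  Everything is seeded through a
``numpy.random.Generator``, so training is bit-stable for a fixed seed on a
given machine.

Layers follow a tiny protocol: ``forward(x, train)``, ``backward(grad)``
(returns the gradient w.r.t. the input and stashes parameter gradients), and
``params()`` yielding ``(weight, grad, state)`` triples for the optimizer.
Shapes: convolution activations are ``(batch, channels, length)``; dense
activations are ``(batch, features)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        return []


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Conv1D(Layer):
    """Same-padding 1-D convolution (cross-correlation), odd kernel size."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float64):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for symmetric same-padding")
        self.k = kernel
        self.W = _he_init(rng, (out_ch, in_ch, kernel), in_ch * kernel, dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._wins = None

    def forward(self, x, train=False):
        p = self.k // 2
        B, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        # (B, C, L, k) -> (B*L, C*k) so the convolution is one matmul
        wins = np.ascontiguousarray(
            sliding_window_view(xp, self.k, axis=2).transpose(0, 2, 1, 3)
        ).reshape(B * L, C * self.k)
        if train:
            self._wins = wins
            self._shape = (B, C, L)
        out = wins @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.reshape(B, L, -1).transpose(0, 2, 1)

    def backward(self, grad):
        p = self.k // 2
        B, C, L = self._shape
        O = self.W.shape[0]
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(B * L, O)
        self.dW = (g2.T @ self._wins).reshape(self.W.shape)
        self.db = g2.sum(axis=0)
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p)))
        gwins = np.ascontiguousarray(
            sliding_window_view(gp, self.k, axis=2).transpose(0, 2, 1, 3)
        ).reshape(B * L, O * self.k)
        Wf = np.ascontiguousarray(self.W[:, :, ::-1].transpose(1, 0, 2))
        dx = gwins @ Wf.reshape(C, O * self.k).T
        return dx.reshape(B, L, C).transpose(0, 2, 1)

    def params(self):
        return [(self.W, lambda: self.dW), (self.b, lambda: self.db)]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.W = _he_init(rng, (n_in, n_out), n_in, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, lambda: self.dW), (self.b, lambda: self.db)]


class ReLU(Layer):
    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(w.size for w, _ in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list does not match architecture")
        for (w, _), new in zip(own, weights):
            w[...] = new


class RMSprop:
    """RMSprop: per-weight learning-rate scaling by a running RMS of gradients."""

    def __init__(self, model: Sequential, lr: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.model = model
        self.cache = [np.zeros_like(w) for w, _ in model.params()]

    def step(self) -> None:
        for (w, grad_fn), c in zip(self.model.params(), self.cache):
            g = grad_fn()
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            w -= self.lr * g / (np.sqrt(c) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, 2.0 * diff / diff.size


def iterate_minibatches(n: int, batch: int, rng: np.random.Generator):
    """Shuffled index minibatches over ``range(n)``."""
    idx = rng.permutation(n)
    for start in range(0, n, batch):
        yield idx[start:start + batch]
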