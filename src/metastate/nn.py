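"""Minimal numpy neural-network engine for the metabolomic state model.

Implements exactly the layer family the state model needs — fully connected
layers, batch normalization, dropout, SiLU — with hand-written backprop, an
Adam optimizer, and a DeepLIFT-style multiplier pass used by the attribution
module.  Inference is deterministic: dropout is disabled and batch
normalization uses running statistics.
"""

from __future__ import annotations

import copy
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "Param",
    "Linear",
    "BatchNorm",
    "SiLU",
    "Dropout",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> List[Param]:
        return []

    def dl_multiplier(self, m: np.ndarray, x_in: np.ndarray, r_in: np.ndarray) -> np.ndarray:
        """Propagate DeepLIFT multipliers from output to input.

        ``m`` has one row per explained sample; ``x_in``/``r_in`` are the
        layer inputs for the samples and the (broadcast) reference.
        """
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # Kaiming-style init, appropriate for the SiLU family
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def params(self):
        return [self.W, self.b]

    def dl_multiplier(self, m, x_in, r_in):
        return m @ self.W.value.T


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * inv_std
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._cache = (xhat, inv_std)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv_std = self._cache
        n = grad.shape[0]
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        dxhat = grad * self.gamma.value
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    def params(self):
        return [self.gamma, self.beta]

    def dl_multiplier(self, m, x_in, r_in):
        # inference-mode batch norm is affine: y = s*x + t
        s = self.gamma.value / np.sqrt(self.running_var + self.eps)
        return m * s


class SiLU(Layer):
    """Sigmoid-weighted linear unit, y = x * sigmoid(x)."""

    def __init__(self):
        self._x = None

    @staticmethod
    def f(x):
        return x * _sigmoid(x)

    def forward(self, x, training):
        self._x = x
        return self.f(x)

    def backward(self, grad):
        s = _sigmoid(self._x)
        return grad * (s * (1.0 + self._x * (1.0 - s)))

    def dl_multiplier(self, m, x_in, r_in):
        dx = x_in - r_in
        dy = self.f(x_in) - self.f(r_in)
        mid = 0.5 * (x_in + r_in)
        s = _sigmoid(mid)
        deriv = s * (1.0 + mid * (1.0 - s))
        small = np.abs(dx) < 1e-9
        ratio = np.where(small, deriv, dy / np.where(small, 1.0, dx))
        return m * ratio


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask

    def dl_multiplier(self, m, x_in, r_in):
        return m


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward_capture(self, x: np.ndarray) -> Tuple[np.ndarray, List[np.ndarray]]:
        """Inference-mode forward that records every layer input."""
        acts = []
        for layer in self.layers:
            acts.append(x)
            x = layer.forward(x, training=False)
        return x, acts

    def dl_pass(
        self, m: np.ndarray, acts_x: List[np.ndarray], acts_r: List[np.ndarray]
    ) -> np.ndarray:
        for layer, ax, ar in zip(reversed(self.layers), reversed(acts_x), reversed(acts_r)):
            m = layer.dl_multiplier(m, ax, ar)
        return m


class Adam:
    """Adam with the customary defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def clone_state(params: Sequence[Param]) -> List[np.ndarray]:
    return [p.value.copy() for p in params]


def load_state(params: Sequence[Param], state: Sequence[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p.value[...] = s


def clone_layers(obj):
    """Deep copy of a layer tree (weights, running stats and all)."""
    return copy.deepcopy(obj)
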