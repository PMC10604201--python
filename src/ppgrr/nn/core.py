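"""Layer base class, dense/activation layers, and the Adam optimizer."""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from ..errors import ShapeError

__all__ = ["Layer", "Dense", "ReLU", "Sequential", "Adam", "he_init"]


def he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> np.ndarray:
    """He-style normal initialization, seeded for reproducibility."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / max(fan_in, 1))).astype(dtype)


class Layer:
    """Base layer: caches what ``backward`` needs during ``forward``."""

    name: str = "layer"

    @property
    def parameters(self) -> List[np.ndarray]:
        return []

    @property
    def gradients(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters))


class Dense(Layer):
    """Affine map on the trailing axis: (..., cin) -> (..., cout)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        self.name = f"dense_{cin}x{cout}"
        self.cin, self.cout = cin, cout
        self.W = he_init(rng, (cin, cout), cin, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def parameters(self):
        return [self.W, self.b]

    @property
    def gradients(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        if x.shape[-1] != self.cin:
            raise ShapeError(f"{self.name}: expected {self.cin} channels, got {x.shape[-1]}")
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        x2 = self._x.reshape(-1, self.cin)
        dy2 = dy.reshape(-1, self.cout)
        self.dW[...] = x2.T @ dy2
        self.db[...] = dy2.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    name = "relu"

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sequential(Layer):
    """A chain of layers; parameters/gradients aggregate over the chain."""

    def __init__(self, layers: Sequence[Layer], name: str = "sequential"):
        self.layers = list(layers)
        self.name = name

    @property
    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters]

    @property
    def gradients(self):
        return [g for layer in self.layers for g in layer.gradients]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam over an explicit parameter list; updates in place."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ShapeError("gradient list does not match parameter list")
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
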