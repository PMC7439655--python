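"""Minimal deterministic feed-forward neural-network core on numpy.

Provides exactly the pieces the pipeline needs — dense layers with Glorot
initialization, ReLU/sigmoid activations, batch normalization, the Adam
optimizer, and MSE / binary cross-entropy losses — with hand-written
backpropagation. Running single-threaded on one process, identical seeds give
bit-identical training trajectories, which the evaluation protocol relies on.
"""

from __future__ import annotations

import copy
from typing import Iterable

import numpy as np


class Param:
    """A named tensor with its gradient and a trainable flag."""

    __slots__ = ("name", "value", "grad", "trainable")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable


class Layer:
    """Base layer; subclasses implement forward/backward and expose params."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def set_trainable(self, flag: bool) -> None:
        for p in self.params():
            p.trainable = flag


class Dense(Layer):
    """Affine map x @ W + b with Glorot-uniform weight initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Param(f"{name}.W", rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Param(f"{name}.b", np.zeros(n_out))
        self._x: np.ndarray | None = None

    @property
    def n_in(self) -> int:
        return self.W.value.shape[0]

    @property
    def n_out(self) -> int:
        return self.W.value.shape[1]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad_out):
        self.W.grad = self._x.T @ grad_out
        self.b.grad = grad_out.sum(axis=0)
        return grad_out @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class Sigmoid(Layer):
    def __init__(self):
        self._out: np.ndarray | None = None

    def forward(self, x, training):
        self._out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))
        return self._out

    def backward(self, grad_out):
        return grad_out * self._out * (1.0 - self._out)


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics for inference."""

    def __init__(self, n: int, momentum: float = 0.99, eps: float = 1e-3, name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(n))
        self.beta = Param(f"{name}.beta", np.zeros(n))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self._cache: tuple | None = None

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._cache = (xhat, ivar)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad_out):
        xhat, ivar = self._cache
        n = xhat.shape[0]
        self.gamma.grad = (grad_out * xhat).sum(axis=0)
        self.beta.grad = grad_out.sum(axis=0)
        dxhat = grad_out * self.gamma.value
        return (ivar / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    def params(self):
        return [self.gamma, self.beta]


class Sequential(Layer):
    """Ordered stack of layers with joint forward/backward."""

    def __init__(self, layers: Iterable[Layer]):
        self.layers = list(layers)

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference forward pass (batch statistics frozen, no stochasticity)."""
        return self.forward(np.asarray(x, dtype=float), training=False)

    def copy(self) -> "Sequential":
        return copy.deepcopy(self)

    def state(self) -> dict[str, np.ndarray]:
        """Snapshot of parameter values keyed by position and name."""
        return {f"{i}:{p.name}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = state[f"{i}:{p.name}"].copy()

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))


class Adam:
    """Adam optimizer; parameters flagged non-trainable are never touched."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if not p.trainable:
                continue
            self._m[i] = b1 * self._m[i] + (1 - b1) * p.grad
            self._v[i] = b2 * self._v[i] + (1 - b2) * p.grad ** 2
            mhat = self._m[i] / (1 - b1 ** self.t)
            vhat = self._v[i] / (1 - b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all cells; returns (loss, dL/dpred)."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, 2.0 * diff / diff.size


def bce_loss(prob: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy; returns (loss, dL/dprob). Probabilities are
    clipped away from {0,1} for numerical safety only."""
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {target.shape}")
    p = np.clip(prob, 1e-7, 1.0 - 1e-7)
    loss = float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))
    grad = (p - target) / (p * (1 - p)) / p.size
    return loss, grad


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Yield index arrays covering 0..n-1 in a shuffled order."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
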