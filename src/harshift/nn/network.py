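"""Network container, losses and the Adam optimizer."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer

_EPS = 1e-12


def cross_entropy_loss(probs: np.ndarray, onehot: np.ndarray):
    """Mean categorical cross-entropy; returns (loss, dL/dprobs)."""
    p = np.clip(probs, _EPS, 1.0)
    n = probs.shape[0]
    loss = -np.sum(onehot * np.log(p)) / n
    dprobs = -onehot / p / n
    return loss, dprobs


def mse_loss(probs: np.ndarray, onehot: np.ndarray):
    """Mean squared error over all entries; returns (loss, dL/dprobs)."""
    diff = probs - onehot
    loss = np.mean(diff**2)
    return loss, 2.0 * diff / diff.size


def bce_loss(p: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy for sigmoid outputs; returns (loss, dL/dp)."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    n = p.size
    loss = -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)) / n
    dp = (p - y) / (p * (1 - p)) / n
    return loss, dp


class Network:
    """An ordered stack of layers with a shared forward/backward contract."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def regularization_loss(self) -> float:
        return float(sum(l.regularization_loss() for l in self.layers))

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)

    def trainable(self):
        """Yield (layer, param_name) pairs in a stable order."""
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.trainable()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (layer, name), w in zip(self.trainable(), weights, strict=True):
            layer.params[name] = w.copy()

    def copy(self) -> "Network":
        return copy.deepcopy(self)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        networks: list[Network],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.slots = [(layer, name) for net in networks for layer, name in net.trainable()]
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.slots]

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for i, (layer, name) in enumerate(self.slots):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            layer.params[name] -= lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)

    def zero_grad(self) -> None:
        for layer, _ in self.slots:
            layer.grads = {}
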