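"""Layers with explicit forward/backward passes.

Shapes: temporal layers take (N, L, C); dense layers take (N, d).
Each layer stores parameters in ``params`` and accumulates gradients in
``grads`` during ``backward``; caches from the last forward pass are
overwritten on every call, so one forward must be paired with one
backward.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _act_forward(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "elu":
        return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "softmax":
        e = np.exp(z - z.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)
    raise ValueError(f"unknown activation {name!r}")


def _act_backward(name: str, a: np.ndarray, da: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. pre-activation z given activation output a and dL/da."""
    if name == "linear":
        return da
    if name == "relu":
        return da * (a > 0)
    if name == "elu":
        return da * np.where(a > 0, 1.0, a + 1.0)
    if name == "sigmoid":
        return da * a * (1.0 - a)
    if name == "softmax":
        return a * (da - np.sum(da * a, axis=-1, keepdims=True))
    raise ValueError(f"unknown activation {name!r}")


class Layer:
    trainable = False

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def regularization_loss(self) -> float:
        return 0.0


class Conv1D(Layer):
    """1D convolution (valid padding) with optional L1+L2 weight penalty."""

    trainable = True

    def __init__(
        self,
        in_channels: int,
        filters: int,
        width: int,
        stride: int = 1,
        activation: str = "relu",
        l1: float = 0.0,
        l2: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.width, self.stride, self.activation = width, stride, activation
        fan_in = width * in_channels
        std = np.sqrt(2.0 / fan_in)  # He init for rectifier nets
        self.params = {
            "W": rng.normal(0.0, std, size=(width, in_channels, filters)),
            "b": np.zeros(filters),
        }
        self.l1, self.l2 = l1, l2

    def forward(self, x, train=False, rng=None):
        win = sliding_window_view(x, self.width, axis=1)  # (N, Lout', C, w)
        win = np.ascontiguousarray(win[:, :: self.stride])
        self._win, self._in_shape = win, x.shape
        N, L_out = win.shape[:2]
        # flatten to a single GEMM; W is stored (w, C, f) so transpose to (C, w, f)
        W_flat = self.params["W"].transpose(1, 0, 2).reshape(-1, self.params["W"].shape[2])
        z = win.reshape(N * L_out, -1) @ W_flat
        z = z.reshape(N, L_out, -1) + self.params["b"]
        self._a = _act_forward(self.activation, z)
        return self._a

    def backward(self, dout):
        dz = _act_backward(self.activation, self._a, dout)
        W = self.params["W"]
        N, L_out, F = dz.shape
        dz_flat = dz.reshape(N * L_out, F)
        dW_flat = self._win.reshape(N * L_out, -1).T @ dz_flat  # (C*w, F)
        dW = dW_flat.reshape(W.shape[1], W.shape[0], F).transpose(1, 0, 2)
        if self.l1:
            dW = dW + self.l1 * np.sign(W)
        if self.l2:
            dW = dW + 2.0 * self.l2 * W
        self.grads = {"W": dW, "b": dz.sum(axis=(0, 1))}
        dx = np.zeros(self._in_shape)
        for k in range(self.width):
            dx[:, k : k + self.stride * L_out : self.stride, :] += dz @ W[k].T
        return dx

    def regularization_loss(self) -> float:
        W = self.params["W"]
        return self.l1 * np.abs(W).sum() + self.l2 * (W**2).sum()


class MaxPool1D(Layer):
    def __init__(self, width: int = 2, stride: int = 1) -> None:
        super().__init__()
        self.width, self.stride = width, stride

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        if self.width == 2 and self.stride == 1:
            # the fast path every shipped architecture uses
            self._first = x[:, :-1] >= x[:, 1:]
            return np.where(self._first, x[:, :-1], x[:, 1:])
        win = sliding_window_view(x, self.width, axis=1)[:, :: self.stride]
        self._argmax = win.argmax(axis=-1)  # (N, Lout, C)
        return win.max(axis=-1)

    def backward(self, dout):
        dx = np.zeros(self._in_shape)
        if self.width == 2 and self.stride == 1:
            dx[:, :-1] += dout * self._first
            dx[:, 1:] += dout * ~self._first
            return dx
        N, L_out, C = dout.shape
        n_idx, l_idx, c_idx = np.ogrid[:N, :L_out, :C]
        pos = l_idx * self.stride + self._argmax
        np.add.at(dx, (np.broadcast_to(n_idx, pos.shape), pos, np.broadcast_to(c_idx, pos.shape)), dout)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :], self._L, axis=1) / self._L


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(
        self,
        in_features: int,
        units: int,
        activation: str = "relu",
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        if activation in ("relu", "elu"):
            std = np.sqrt(2.0 / in_features)
        else:  # Glorot for linear/softmax/sigmoid heads
            std = np.sqrt(2.0 / (in_features + units))
        self.params = {
            "W": rng.normal(0.0, std, size=(in_features, units)),
            "b": np.zeros(units),
        }

    def forward(self, x, train=False, rng=None):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        self._a = _act_forward(self.activation, z)
        return self._a

    def backward(self, dout):
        dz = _act_backward(self.activation, self._a, dout)
        self.grads = {"W": self._x.T @ dz, "b": dz.sum(axis=0)}
        return dz @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout: identity at inference time."""

    def __init__(self, rate: float = 0.5) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GradientReversal(Layer):
    """Identity forward; multiplies the backward gradient by -lambda.

    The adversarial coupling of a DANN: the domain head minimizes its
    loss while the encoder receives the reversed gradient and learns
    domain-invariant features.
    """

    def __init__(self, lam: float = 0.1) -> None:
        super().__init__()
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        self.lam = lam

    def forward(self, x, train=False, rng=None):
        return x

    def backward(self, dout):
        return -self.lam * dout
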