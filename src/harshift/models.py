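"""Declarative CNN architecture specs, parameter counting and training.

The base model is deliberately shallow to resist overfitting on small
wearable datasets: two conv/max-pool blocks (16 then 32 kernels of
width 3, stride 1; pool width 2, stride 1), global average pooling,
50% dropout and a softmax head — 2,103 trainable parameters for 7
classes on 150x6 input. ``family_spec`` extends it into a 5-level
complexity family with strictly increasing parameter counts, standing
in for the heavier literature architectures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import nn
from ._seeds import rng_for
from .data import WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "base_spec",
    "family_spec",
    "count_parameters",
    "ActivityClassifier",
    "ClassifierResults",
    "ARCHITECTURES",
]

_LAYER_KINDS = {"conv1d", "maxpool1d", "global_avg_pool", "flatten", "dense", "dropout"}


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    filters: int = 0
    width: int = 0
    stride: int = 1
    units: int = 0
    rate: float = 0.0
    activation: str = "relu"
    l1l2: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


def conv1d(filters: int, width: int = 3, stride: int = 1, activation: str = "relu", l1l2: float = 1e-3) -> LayerSpec:
    return LayerSpec("conv1d", filters=filters, width=width, stride=stride, activation=activation, l1l2=l1l2)


def maxpool1d(width: int = 2, stride: int = 1) -> LayerSpec:
    return LayerSpec("maxpool1d", width=width, stride=stride)


def global_avg_pool() -> LayerSpec:
    return LayerSpec("global_avg_pool")


def flatten() -> LayerSpec:
    return LayerSpec("flatten")


def dense(units: int, activation: str = "relu") -> LayerSpec:
    return LayerSpec("dense", units=units, activation=activation)


def dropout(rate: float = 0.5) -> LayerSpec:
    return LayerSpec("dropout", rate=rate)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer list plus the input/output contract."""

    layers: tuple[LayerSpec, ...]
    n_classes: int
    input_length: int = 150
    n_channels: int = 6
    name: str = "custom"

    def __post_init__(self) -> None:
        last = self.layers[-1]
        if last.kind != "dense" or last.activation != "softmax" or last.units != self.n_classes:
            raise ValueError("last layer must be dense(n_classes, softmax)")
        self.shape_chain()  # fail fast on inconsistent shapes

    def shape_chain(self) -> list[tuple]:
        """Propagate shapes through the layer list; raises if inconsistent."""
        shape: tuple = (self.input_length, self.n_channels)
        chain = [shape]
        for ls in self.layers:
            if ls.kind == "conv1d":
                L, C = shape
                L_out = (L - ls.width) // ls.stride + 1
                if L_out < 1:
                    raise ValueError(f"conv1d width {ls.width} too large for length {L}")
                shape = (L_out, ls.filters)
            elif ls.kind == "maxpool1d":
                L, C = shape
                L_out = (L - ls.width) // ls.stride + 1
                if L_out < 1:
                    raise ValueError("maxpool window too large")
                shape = (L_out, C)
            elif ls.kind == "global_avg_pool":
                shape = (shape[1],)
            elif ls.kind == "flatten":
                shape = (int(np.prod(shape)),)
            elif ls.kind == "dense":
                if len(shape) != 1:
                    raise ValueError("dense layer needs a flat input")
                shape = (ls.units,)
            chain.append(shape)
        return chain

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "name": self.name,
                "n_classes": self.n_classes,
                "input_length": self.input_length,
                "n_channels": self.n_channels,
                "layers": [asdict(l) for l in self.layers],
            },
            sort_keys=False,
        )

    @staticmethod
    def from_yaml(text: str) -> "ArchitectureSpec":
        d = yaml.safe_load(text)
        return ArchitectureSpec(
            layers=tuple(LayerSpec(**l) for l in d["layers"]),
            n_classes=d["n_classes"],
            input_length=d.get("input_length", 150),
            n_channels=d.get("n_channels", 6),
            name=d.get("name", "custom"),
        )


def count_parameters(spec: ArchitectureSpec) -> int:
    """Trainable weights + biases: conv (w*in+1)*f, dense (in+1)*u, rest 0."""
    total = 0
    shape: tuple = (spec.input_length, spec.n_channels)
    for ls, out_shape in zip(spec.layers, spec.shape_chain()[1:]):
        if ls.kind == "conv1d":
            total += (ls.width * shape[1] + 1) * ls.filters
        elif ls.kind == "dense":
            total += (shape[0] + 1) * ls.units
        shape = out_shape
    return total


def base_spec(n_classes: int = 7, l1l2: float = 1e-3) -> ArchitectureSpec:
    """The shallow base CNN (2,103 parameters at 7 classes)."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return ArchitectureSpec(
        layers=(
            conv1d(16, 3, 1, l1l2=l1l2),
            maxpool1d(2, 1),
            conv1d(32, 3, 1, l1l2=l1l2),
            maxpool1d(2, 1),
            global_avg_pool(),
            dropout(0.5),
            dense(n_classes, activation="softmax"),
        ),
        n_classes=n_classes,
        name="base",
    )


def family_spec(level: int, n_classes: int = 7, l1l2: float = 1e-3) -> ArchitectureSpec:
    """Complexity family, level 1 (= base) to 5, strictly growing in parameters."""
    if not 1 <= level <= 5:
        raise ValueError("level must lie in 1..5")
    if level == 1:
        return base_spec(n_classes, l1l2)
    blocks = {
        2: ((32, 3), (64, 3)),
        3: ((32, 3), (64, 3), (64, 3)),
        4: ((64, 3), (128, 3), (128, 3)),
        5: ((64, 5), (128, 5), (128, 5), (256, 3)),
    }[level]
    head = {2: (), 3: (64,), 4: (128,), 5: (256, 128)}[level]
    layers: list[LayerSpec] = []
    for f, w in blocks:
        layers += [conv1d(f, w, 1, l1l2=l1l2), maxpool1d(2, 1)]
    layers.append(global_avg_pool())
    for u in head:
        layers.append(dense(u))
    layers += [dropout(0.5), dense(n_classes, activation="softmax")]
    return ArchitectureSpec(tuple(layers), n_classes=n_classes, name=f"level-{level}")


#: Extensible architecture registry: name -> spec factory of (n_classes).
ARCHITECTURES = {
    "base": base_spec,
    **{f"level-{k}": (lambda n_classes=7, k=k: family_spec(k, n_classes)) for k in range(1, 6)},
}


def build_network(spec: ArchitectureSpec, seed: int = 0) -> nn.Network:
    """Instantiate a spec as a trainable network with seeded initialization."""
    rng = rng_for(seed, "init", spec.name)
    layers: list[nn.Layer] = []
    shape: tuple = (spec.input_length, spec.n_channels)
    for ls, out_shape in zip(spec.layers, spec.shape_chain()[1:]):
        if ls.kind == "conv1d":
            layers.append(
                nn.Conv1D(
                    shape[1], ls.filters, ls.width, ls.stride,
                    activation=ls.activation, l1=ls.l1l2, l2=ls.l1l2, rng=rng,
                )
            )
        elif ls.kind == "maxpool1d":
            layers.append(nn.MaxPool1D(ls.width, ls.stride))
        elif ls.kind == "global_avg_pool":
            layers.append(nn.GlobalAvgPool())
        elif ls.kind == "flatten":
            layers.append(nn.Flatten())
        elif ls.kind == "dense":
            layers.append(nn.Dense(shape[0], ls.units, activation=ls.activation, rng=rng))
        elif ls.kind == "dropout":
            layers.append(nn.Dropout(ls.rate))
        shape = out_shape
    return nn.Network(layers)


@dataclass
class TrainConfig:
    """Supervised training hyperparameters (defaults are the study settings)."""

    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 1e-3
    loss: str = "categorical_crossentropy"
    early_stopping: bool = False
    patience: int = 10
    shuffle: bool = True

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) <= 0 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.loss not in ("categorical_crossentropy", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")


def one_hot(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    y = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        y[i, index[l]] = 1.0
    return y


class ActivityClassifier:
    """Supervised window classifier; ``fit`` returns a results object.

    Parameters
    ----------
    windows, labels
        Training data: (N, L, 6) normalized windows and N activity labels,
        or a :class:`~harshift.data.WindowSet`.
    spec
        Architecture; defaults to the base model sized to the label set.
    classes
        Explicit class list (order defines the softmax layout); defaults
        to the sorted labels present in the training data.
    """

    def __init__(
        self,
        windows,
        labels=None,
        spec: ArchitectureSpec | None = None,
        classes: list[str] | None = None,
        cfg: TrainConfig | None = None,
    ):
        if isinstance(windows, WindowSet):
            labels = windows.labels
            windows = windows.windows
        if labels is None:
            raise ValueError("labels are required")
        self.windows = np.asarray(windows, dtype=float)
        self.labels = np.asarray(labels, dtype=object)
        if len(self.windows) == 0:
            raise ValueError("empty training set")
        self.classes = list(classes) if classes else sorted(set(self.labels))
        present = set(self.labels)
        if len(present) < len(self.classes):
            warnings.warn(
                f"training labels cover {len(present)}/{len(self.classes)} classes",
                RuntimeWarning,
                stacklevel=2,
            )
        self.spec = spec or base_spec(n_classes=len(self.classes))
        if self.spec.n_classes != len(self.classes):
            raise ValueError("spec n_classes does not match the class list")
        self.cfg = cfg or TrainConfig()

    @classmethod
    def from_windowset(cls, ws: WindowSet, **kwargs) -> "ActivityClassifier":
        return cls(ws.windows, ws.labels, **kwargs)

    def fit(self, seed: int = 0, validation=None) -> "ClassifierResults":
        """Minimize the regularized loss with Adam for ``cfg.epochs`` epochs.

        ``validation`` may be None, a fraction in (0, 1) split off the
        training windows, or an explicit ``(windows, labels)`` pair /
        WindowSet; it drives optional early stopping.
        """
        cfg = self.cfg
        net = build_network(self.spec, seed=seed)
        rng = rng_for(seed, "train", self.spec.name)
        X, y_lab = self.windows, self.labels

        val = None
        if isinstance(validation, float):
            idx = rng.permutation(len(X))
            n_val = max(1, int(round(validation * len(X))))
            val = (X[idx[:n_val]], y_lab[idx[:n_val]])
            X, y_lab = X[idx[n_val:]], y_lab[idx[n_val:]]
        elif isinstance(validation, WindowSet):
            val = (validation.windows, validation.labels)
        elif validation is not None:
            val = (np.asarray(validation[0]), np.asarray(validation[1], dtype=object))

        Y = one_hot(y_lab, self.classes)
        loss_fn = nn.cross_entropy_loss if cfg.loss == "categorical_crossentropy" else nn.mse_loss
        opt = nn.Adam([net], learning_rate=cfg.learning_rate)
        n = len(X)
        history = []
        best_val, best_weights, stale = np.inf, None, 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(n) if cfg.shuffle else np.arange(n)
            epoch_loss, correct = 0.0, 0
            for b0 in range(0, n, cfg.batch_size):
                bi = order[b0 : b0 + cfg.batch_size]
                probs = net.forward(X[bi], train=True, rng=rng)
                loss, dprobs = loss_fn(probs, Y[bi])
                loss += net.regularization_loss()
                net.backward(dprobs)
                opt.step()
                opt.zero_grad()
                epoch_loss += loss * len(bi)
                correct += int((probs.argmax(1) == Y[bi].argmax(1)).sum())
            row = {"epoch": epoch, "loss": epoch_loss / n, "accuracy": correct / n}
            if val is not None:
                vp = _predict_in_batches(net, val[0])
                vY = one_hot(val[1], self.classes)
                vl, _ = loss_fn(vp, vY)
                row["val_loss"] = vl + net.regularization_loss()
                row["val_accuracy"] = float((vp.argmax(1) == vY.argmax(1)).mean())
                if cfg.early_stopping:
                    if row["val_loss"] < best_val - 1e-6:
                        best_val, best_weights, stale = row["val_loss"], net.get_weights(), 0
                    else:
                        stale += 1
                        if stale >= cfg.patience:
                            history.append(row)
                            break
            history.append(row)
        if cfg.early_stopping and best_weights is not None:
            net.set_weights(best_weights)
        return ClassifierResults(
            network=net,
            spec=self.spec,
            classes=self.classes,
            history=pd.DataFrame(history),
            seed=seed,
        )


def _predict_in_batches(net: nn.Network, X: np.ndarray, batch: int = 512) -> np.ndarray:
    outs = [net.forward(X[i : i + batch], train=False) for i in range(0, len(X), batch)]
    return np.concatenate(outs) if outs else np.empty((0, 0))


@dataclass
class ClassifierResults:
    """A trained classifier: predictions, features and training diagnostics."""

    network: nn.Network
    spec: ArchitectureSpec
    classes: list[str]
    history: pd.DataFrame
    seed: int = 0

    def predict_proba(self, windows) -> np.ndarray:
        windows = windows.windows if isinstance(windows, WindowSet) else np.asarray(windows)
        return _predict_in_batches(self.network, windows)

    def predict(self, windows) -> np.ndarray:
        probs = self.predict_proba(windows)
        return np.array([self.classes[i] for i in probs.argmax(axis=1)], dtype=object)

    def extract_features(self, windows) -> np.ndarray:
        """Penultimate representation: activations feeding the softmax head."""
        windows = windows.windows if isinstance(windows, WindowSet) else np.asarray(windows)
        sub = nn.Network(self.network.layers[:-1])
        return _predict_in_batches(sub, windows)

    @property
    def parameter_count(self) -> int:
        return self.network.n_params()

    def summary(self) -> str:
        last = self.history.iloc[-1] if len(self.history) else {}
        lines = [
            f"ActivityClassifier results [{self.spec.name}]",
            f"  classes:     {', '.join(self.classes)}",
            f"  parameters:  {self.parameter_count}",
            f"  epochs run:  {len(self.history)}",
            f"  final loss:  {last.get('loss', float('nan')):.4f}",
            f"  train acc:   {100 * last.get('accuracy', float('nan')):.2f}%",
        ]
        if "val_accuracy" in self.history.columns:
            lines.append(f"  val acc:     {100 * last.get('val_accuracy', float('nan')):.2f}%")
        return "\n".join(lines)
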