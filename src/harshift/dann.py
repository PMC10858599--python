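"""Adversarial domain adaptation with a gradient-reversal layer (DANN).

A shared encoder feeds two heads: a label predictor trained on labeled
*source* windows, and a domain classifier trained to distinguish source
from target windows. The domain head is connected through a
gradient-reversal layer (identity forward, gradient scaled by -lambda
backward), so the encoder is pushed toward features the domain head
cannot separate — domain-invariant but still label-discriminative.
Target labels are never consumed anywhere: :class:`DomainBatch` has no
field to hold them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from ._seeds import rng_for
from .data import WindowSet
from .models import (
    ArchitectureSpec,
    ClassifierResults,
    base_spec,
    build_network,
    one_hot,
)

logger = logging.getLogger(__name__)

__all__ = ["DANNConfig", "DomainBatch", "DomainAdversarialNetwork", "DANNResults", "gradient_reversal"]


def gradient_reversal(lam: float = 0.1) -> nn.GradientReversal:
    """The gradient-reversal layer: forward identity, backward times -lambda."""
    return nn.GradientReversal(lam)


@dataclass(frozen=True)
class DANNConfig:
    """Adaptation hyperparameters (defaults are the study settings).

    The task loss defaults to mean squared error on one-hot targets,
    switchable to categorical cross-entropy; the domain head is trained
    with binary cross-entropy. Training runs for at most ``epochs``
    (kept in the 100-350 band by default) with optional plateau
    detection on the domain loss.
    """

    lam: float = 0.1
    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 200
    task_loss: str = "mse"  # or "categorical_crossentropy"
    domain_hidden: int = 32
    label_dropout: float = 0.5
    patience: int | None = 20  # plateau detection on domain loss; None disables
    min_epochs: int = 50

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 100 <= self.epochs <= 350:
            logger.warning("epochs=%d outside the default 100-350 band", self.epochs)
        if self.task_loss not in ("mse", "categorical_crossentropy"):
            raise ValueError(f"unknown task loss {self.task_loss!r}")


@dataclass(frozen=True)
class DomainBatch:
    """One adversarial minibatch. Deliberately has no target-label field."""

    source_windows: np.ndarray
    source_onehot: np.ndarray
    target_windows: np.ndarray

    @property
    def domain_labels(self) -> np.ndarray:
        """0 for source rows, 1 for target rows, in concatenation order."""
        return np.concatenate(
            [np.zeros(len(self.source_windows)), np.ones(len(self.target_windows))]
        )


def _split_encoder(spec: ArchitectureSpec):
    """Encoder layers = everything before the trailing [dropout?] dense head."""
    layers = list(spec.layers)
    cut = len(layers) - 1  # final dense(softmax)
    if cut > 0 and layers[cut - 1].kind == "dropout":
        cut -= 1
    return tuple(layers[:cut])


class DomainAdversarialNetwork:
    """DANN model; ``fit`` consumes labeled source and *unlabeled* target.

    Built either fresh from an architecture spec or warm-started from a
    trained :class:`~harshift.models.ClassifierResults` (the usual
    protocol: load the best cross-validation model, then adapt).
    """

    def __init__(
        self,
        classifier_spec: ArchitectureSpec | None = None,
        cfg: DANNConfig | None = None,
        n_classes: int | None = None,
        classes: list[str] | None = None,
    ):
        self.cfg = cfg or DANNConfig()
        if classifier_spec is None:
            classifier_spec = base_spec(n_classes=n_classes or len(classes or []) or 7)
        self.spec = classifier_spec
        self.classes = list(classes) if classes else None
        self._init_weights: tuple[list, list] | None = None

    @classmethod
    def from_classifier(cls, fitted: ClassifierResults, cfg: DANNConfig | None = None):
        """Warm-start the encoder and label head from a trained classifier."""
        model = cls(fitted.spec, cfg=cfg, classes=fitted.classes)
        n_enc_layers = len(_split_encoder(fitted.spec))
        # layer list indices of the built network line up with the spec
        enc_weights, head_weights = [], []
        for i, layer in enumerate(fitted.network.layers):
            for name in layer.params:
                (enc_weights if i < n_enc_layers else head_weights).append(
                    layer.params[name].copy()
                )
        model._init_weights = (enc_weights, head_weights)
        return model

    def _build(self, seed: int):
        spec = self.spec
        enc_spec = ArchitectureSpec(
            layers=_split_encoder(spec) + (type(spec.layers[-1])("dense", units=spec.n_classes, activation="softmax"),),
            n_classes=spec.n_classes,
            input_length=spec.input_length,
            n_channels=spec.n_channels,
            name=spec.name,
        )
        full = build_network(enc_spec, seed=seed)
        n_enc = len(_split_encoder(spec))
        encoder = nn.Network(full.layers[:n_enc])
        feat_dim = enc_spec.shape_chain()[n_enc][0]

        rng = rng_for(seed, "dann-heads", spec.name)
        label_head = nn.Network(
            [
                nn.Dropout(self.cfg.label_dropout),
                nn.Dense(feat_dim, spec.n_classes, activation="softmax", rng=rng),
            ]
        )
        domain_head = nn.Network(
            [
                nn.GradientReversal(self.cfg.lam),
                nn.Dense(feat_dim, self.cfg.domain_hidden, activation="elu", rng=rng),
                nn.Dense(self.cfg.domain_hidden, 1, activation="sigmoid", rng=rng),
            ]
        )
        if self._init_weights is not None:
            enc_w, head_w = self._init_weights
            encoder.set_weights(enc_w)
            # label head dense reuses the classifier's softmax weights
            label_dense = label_head.layers[1]
            label_dense.params["W"] = head_w[0].copy()
            label_dense.params["b"] = head_w[1].copy()
        return encoder, label_head, domain_head, feat_dim

    def fit(self, source: WindowSet, target, seed: int = 0) -> "DANNResults":
        """Joint minibatch training of label loss (source) and reversed domain loss.

        ``target`` is a WindowSet or raw array of *unlabeled* windows;
        passing labels is structurally impossible. Deterministic given
        ``seed``.
        """
        cfg = self.cfg
        target_windows = target.windows if isinstance(target, WindowSet) else np.asarray(target)
        if len(source) == 0 or len(target_windows) == 0:
            raise ValueError("source and target must be non-empty")
        classes = self.classes or source.activities
        Xs, Ys = source.windows, one_hot(source.labels, classes)
        Xt = target_windows

        encoder, label_head, domain_head, feat_dim = self._build(seed)
        task_fn = nn.mse_loss if cfg.task_loss == "mse" else nn.cross_entropy_loss
        opt = nn.Adam([encoder, label_head, domain_head], learning_rate=cfg.learning_rate)
        rng = rng_for(seed, "dann-train", self.spec.name)

        bs = cfg.batch_size
        steps = max(1, int(np.ceil(max(len(Xs), len(Xt)) / bs)))
        history = []
        best_domain, stale = np.inf, 0
        for epoch in range(cfg.epochs):
            s_order = rng.permutation(len(Xs))
            t_order = rng.permutation(len(Xt))
            ep_label, ep_domain, ep_dom_correct, ep_n = 0.0, 0.0, 0, 0
            for step in range(steps):
                si = s_order[(step * bs) % len(Xs) : (step * bs) % len(Xs) + bs]
                ti = t_order[(step * bs) % len(Xt) : (step * bs) % len(Xt) + bs]
                if len(si) == 0 or len(ti) == 0:
                    continue
                batch = DomainBatch(Xs[si], Ys[si], Xt[ti])
                n_s = len(batch.source_windows)
                x = np.concatenate([batch.source_windows, batch.target_windows])
                feats = encoder.forward(x, train=True, rng=rng)

                probs = label_head.forward(feats[:n_s], train=True, rng=rng)
                label_loss, dprobs = task_fn(probs, batch.source_onehot)
                g_label = label_head.backward(dprobs)

                dom_p = domain_head.forward(feats, train=True, rng=rng)
                dom_y = batch.domain_labels[:, None]
                domain_loss, ddom = nn.bce_loss(dom_p, dom_y)
                g_dom = domain_head.backward(ddom)  # already scaled by -lambda

                g = g_dom.copy()
                g[:n_s] += g_label
                encoder.backward(g)
                opt.step()
                opt.zero_grad()

                ep_label += label_loss * n_s
                ep_domain += domain_loss * len(x)
                ep_dom_correct += int(((dom_p[:, 0] > 0.5) == (dom_y[:, 0] > 0.5)).sum())
                ep_n += len(x)
            row = {
                "epoch": epoch,
                "label_loss": ep_label / max(len(Xs), 1),
                "domain_loss": ep_domain / max(ep_n, 1),
                "domain_accuracy": ep_dom_correct / max(ep_n, 1),
            }
            history.append(row)
            if cfg.patience is not None and epoch + 1 >= cfg.min_epochs:
                if row["domain_loss"] < best_domain - 1e-5:
                    best_domain, stale = row["domain_loss"], 0
                else:
                    stale += 1
                    if stale >= cfg.patience:
                        logger.info("domain-loss plateau at epoch %d; stopping", epoch)
                        break
            elif row["domain_loss"] < best_domain:
                best_domain = row["domain_loss"]

        return DANNResults(
            encoder=encoder,
            label_head=label_head,
            domain_head=domain_head,
            classes=classes,
            cfg=cfg,
            history=pd.DataFrame(history),
            seed=seed,
        )


@dataclass
class DANNResults:
    """Adapted model: label predictions, features and the domain diagnostic."""

    encoder: nn.Network
    label_head: nn.Network
    domain_head: nn.Network
    classes: list[str]
    cfg: DANNConfig
    history: pd.DataFrame
    seed: int = 0

    def _features(self, windows) -> np.ndarray:
        X = windows.windows if isinstance(windows, WindowSet) else np.asarray(windows)
        outs = [self.encoder.forward(X[i : i + 512], train=False) for i in range(0, len(X), 512)]
        return np.concatenate(outs)

    def extract_features(self, windows) -> np.ndarray:
        return self._features(windows)

    def predict_proba(self, windows) -> np.ndarray:
        return self.label_head.forward(self._features(windows), train=False)

    def predict(self, windows) -> np.ndarray:
        probs = self.predict_proba(windows)
        return np.array([self.classes[i] for i in probs.argmax(axis=1)], dtype=object)

    def domain_accuracy(self, source_windows, target_windows) -> float:
        """Accuracy of the domain head on held-out windows (0.5 = chance).

        Values drifting toward chance indicate the encoder learned
        domain-invariant features.
        """
        fs = self._features(source_windows)
        ft = self._features(target_windows)
        p = np.concatenate(
            [self.domain_head.forward(fs, train=False)[:, 0], self.domain_head.forward(ft, train=False)[:, 0]]
        )
        y = np.concatenate([np.zeros(len(fs)), np.ones(len(ft))])
        return float(((p > 0.5) == (y > 0.5)).mean())

    def summary(self) -> str:
        last = self.history.iloc[-1]
        return "\n".join(
            [
                "DomainAdversarialNetwork results",
                f"  classes:          {', '.join(self.classes)}",
                f"  lambda:           {self.cfg.lam}",
                f"  epochs run:       {len(self.history)}",
                f"  final label loss: {last['label_loss']:.4f}",
                f"  final domain acc: {100 * last['domain_accuracy']:.2f}% (50% = fully aligned)",
            ]
        )


def adapt_and_predict(results: DANNResults, target: WindowSet) -> np.ndarray:
    """Predictions of an adapted model on target windows (labels never read)."""
    return results.predict(target)
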