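"""Leave-one-subject-out cross-validation, cross-domain testing and metrics.

All rates are reported on a 0-100 percent scale. For the imbalanced
3-activity Parkinson-style target, per-activity one-vs-rest (binarized)
accuracy and F1 are used: any prediction outside the target's activity
set counts as the negative class for every activity, which pins the
average binary accuracy of a completely foreign predictor at exactly
2/3 regardless of class proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, f1_score

from ._seeds import rng_for
from .augment import AugmentationConfig, augment_dataset
from .data import NormalizationStats, WindowSet
from .models import ActivityClassifier, ArchitectureSpec, ClassifierResults, TrainConfig
from .preprocess import apply_normalizer, fit_normalizer
from .reorient import AxisMapping, apply_mapping

logger = logging.getLogger(__name__)

PD_ACTIVITIES = ("walking", "sitting", "standing")


@dataclass(frozen=True)
class Fold:
    test_subject: str
    train_subjects: tuple[str, ...]
    tune_subjects: tuple[str, ...]  # inner 20% validation split


@dataclass(frozen=True)
class FoldPlan:
    folds: tuple[Fold, ...]

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def loso_folds(ws: WindowSet, seed: int = 0, tune_fraction: float = 0.2) -> FoldPlan:
    """One fold per subject; remaining subjects split 80/20 for tuning.

    The split is at subject granularity so no subject's windows appear
    on both sides of any boundary.
    """
    subjects = ws.subjects
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    folds = []
    for test_subject in subjects:
        rest = [s for s in subjects if s != test_subject]
        rng = rng_for(seed, "loso", test_subject)
        order = list(np.array(rest)[rng.permutation(len(rest))])
        n_tune = max(1, int(round(tune_fraction * len(rest)))) if len(rest) > 1 else 0
        folds.append(
            Fold(
                test_subject=test_subject,
                train_subjects=tuple(sorted(order[n_tune:])),
                tune_subjects=tuple(sorted(order[:n_tune])),
            )
        )
    return FoldPlan(tuple(folds))


def binarize(y, positive: str) -> np.ndarray:
    """One-vs-rest labels: 1 where y equals the positive activity, else 0.

    Predictions outside the target's activity set therefore collapse to
    the negative class for every choice of positive. Idempotent on
    already-binary input when positive is 1.
    """
    y = np.asarray(y, dtype=object)
    return (y == positive).astype(int)


def binary_metrics_avg(y_true, y_pred, activities=PD_ACTIVITIES):
    """Per-activity one-vs-rest accuracy and F1 (percent) and their averages.

    F1 is defined as 0 when there are no true positives and nothing was
    predicted positive (the degenerate all-negative case). Raises on
    empty input or when true labels fall outside ``activities``.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) == 0:
        raise ValueError("empty input")
    extra = set(y_true) - set(activities)
    if extra:
        raise ValueError(f"true labels outside the activity set: {sorted(extra)}")
    per_activity = {}
    for act in activities:
        yt, yp = binarize(y_true, act), binarize(y_pred, act)
        acc = 100.0 * float((yt == yp).mean())
        f1 = 100.0 * float(f1_score(yt, yp, zero_division=0.0))
        per_activity[act] = {"binary_accuracy": acc, "binary_f1": f1}
    avg_acc = float(np.mean([v["binary_accuracy"] for v in per_activity.values()]))
    avg_f1 = float(np.mean([v["binary_f1"] for v in per_activity.values()]))
    return avg_acc, per_activity, avg_f1


@dataclass
class ExperimentResult:
    """Metrics of one evaluation (a CV fold, a CV summary, or a cross-test)."""

    kind: str
    accuracy: float | None = None  # percent
    macro_f1: float | None = None  # percent
    avg_binary_accuracy: float | None = None
    avg_binary_f1: float | None = None
    per_activity: dict = field(default_factory=dict)
    confusion: pd.DataFrame | None = None
    per_fold: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"ExperimentResult [{self.kind}]"]
        for label, val in (
            ("accuracy", self.accuracy),
            ("macro F1", self.macro_f1),
            ("avg binary accuracy", self.avg_binary_accuracy),
            ("avg binary F1", self.avg_binary_f1),
        ):
            if val is not None:
                lines.append(f"  {label + ':':<22}{val:6.2f}%")
        for act, m in self.per_activity.items():
            lines.append(
                f"    {act:<18} acc {m['binary_accuracy']:6.2f}%   F1 {m['binary_f1']:6.2f}%"
            )
        return "\n".join(lines)


def _multiclass_metrics(y_true, y_pred, classes) -> tuple[float, float, pd.DataFrame]:
    acc = 100.0 * float((np.asarray(y_true, dtype=object) == np.asarray(y_pred, dtype=object)).mean())
    f1 = 100.0 * float(
        f1_score(list(y_true), list(y_pred), labels=list(classes), average="macro", zero_division=0.0)
    )
    cm = confusion_matrix(list(y_true), list(y_pred), labels=list(classes))
    cm = pd.DataFrame(cm, index=list(classes), columns=list(classes))
    return acc, f1, cm


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold metrics plus the best fold model."""

    result: ExperimentResult
    best_model: ClassifierResults
    best_stats: NormalizationStats
    best_fold: str
    fold_models: list[ClassifierResults] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.result.per_fold["accuracy"].mean())

    @property
    def mean_macro_f1(self) -> float:
        return float(self.result.per_fold["macro_f1"].mean())


def run_cv(
    ws: WindowSet,
    spec: ArchitectureSpec | None = None,
    train_cfg: TrainConfig | None = None,
    augment_cfg: AugmentationConfig | None = None,
    seed: int = 0,
    keep_fold_models: bool = False,
) -> CVResult:
    """LOSO cross-validation with per-fold normalization (and augmentation).

    Augmentation, when configured, is applied to the training windows of
    each fold only — never to the tuning or held-out subject's windows —
    and the normalizer is fitted on the augmented training set. The
    returned best model is the fold with the highest held-out accuracy
    (ties break to the lowest fold index).
    """
    train_cfg = train_cfg or TrainConfig()
    plan = loso_folds(ws, seed=seed)
    classes = ws.activities
    rows, models, stats_list, confusions = [], [], [], []
    for i, fold in enumerate(plan):
        train = ws.for_subjects(fold.train_subjects)
        if augment_cfg is not None:
            train = augment_dataset(
                train,
                AugmentationConfig(
                    **{
                        **augment_cfg.__dict__,
                        "seed": int(rng_for(seed, "fold-aug", fold.test_subject).integers(2**31)),
                    }
                ),
            )
        stats = fit_normalizer(train)
        train_n = apply_normalizer(train, stats)
        tune = ws.for_subjects(fold.tune_subjects)
        tune_n = apply_normalizer(tune, stats) if len(tune) else None
        test_n = apply_normalizer(ws.for_subjects([fold.test_subject]), stats)

        clf = ActivityClassifier(train_n, spec=spec, classes=classes, cfg=train_cfg)
        fitted = clf.fit(seed=int(rng_for(seed, "fold", fold.test_subject).integers(2**31)), validation=tune_n)
        y_pred = fitted.predict(test_n)
        acc, f1, cm = _multiclass_metrics(test_n.labels, y_pred, classes)
        rows.append(
            {"fold": i, "test_subject": fold.test_subject, "accuracy": acc, "macro_f1": f1,
             "n_train": len(train_n), "n_test": len(test_n)}
        )
        models.append(fitted)
        stats_list.append(stats)
        confusions.append(cm)
        logger.info("fold %d (%s): accuracy %.2f%%", i, fold.test_subject, acc)

    per_fold = pd.DataFrame(rows)
    best_idx = int(per_fold["accuracy"].idxmax())  # idxmax takes the first max: lowest fold wins ties
    total_cm = sum(confusions[1:], confusions[0].copy())
    result = ExperimentResult(
        kind="loso-cv",
        accuracy=float(per_fold["accuracy"].mean()),
        macro_f1=float(per_fold["macro_f1"].mean()),
        confusion=total_cm,
        per_fold=per_fold,
        config={"spec": (spec.name if spec else "base"), "augmented": augment_cfg is not None, "seed": seed},
    )
    return CVResult(
        result=result,
        best_model=models[best_idx],
        best_stats=stats_list[best_idx],
        best_fold=plan.folds[best_idx].test_subject,
        fold_models=models if keep_fold_models else [],
    )


def cross_test(
    model: ClassifierResults,
    source_stats: NormalizationStats,
    target: WindowSet,
    mapping: AxisMapping | None = None,
    binarize_activities=None,
) -> ExperimentResult:
    """Apply a source-trained model to a target dataset.

    The target is optionally reoriented to the source convention, then
    normalized with the *source* statistics and predicted. When the
    target's label set matches the model's classes, multiclass metrics
    are reported; when it is a strict subset (the 3-activity PD-style
    case), binarized one-vs-rest metrics over that set are reported.
    """
    if mapping is not None:
        target = apply_mapping(target, mapping)
    target_n = apply_normalizer(target, source_stats)
    y_pred = model.predict(target_n)
    target_labels = set(target.labels)
    model_classes = set(model.classes)
    if not target_labels <= model_classes:
        raise ValueError(
            f"target labels {sorted(target_labels - model_classes)} unknown to the model"
        )
    cm = pd.DataFrame(
        confusion_matrix(list(target.labels), list(y_pred), labels=model.classes),
        index=model.classes,
        columns=model.classes,
    ).loc[sorted(target_labels)]

    if binarize_activities is None and target_labels == model_classes:
        acc, f1, cm_full = _multiclass_metrics(target.labels, y_pred, model.classes)
        return ExperimentResult(kind="cross-test", accuracy=acc, macro_f1=f1, confusion=cm_full)

    activities = tuple(binarize_activities or sorted(target_labels))
    avg_acc, per_activity, avg_f1 = binary_metrics_avg(target.labels, y_pred, activities)
    acc = 100.0 * float((target.labels == y_pred).mean())
    return ExperimentResult(
        kind="cross-test-binarized",
        accuracy=acc,
        avg_binary_accuracy=avg_acc,
        avg_binary_f1=avg_f1,
        per_activity=per_activity,
        confusion=cm,
    )
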