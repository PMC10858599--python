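"""Config-driven experiment grids over synthetic cohorts.

A grid cell is (architecture, augmentation on/off, reorientation
on/off, adaptation on/off) x seed, executed as: generate cohorts ->
preprocess -> LOSO cross-validation on the source (augmenting training
folds only) -> cross-test the best fold model on the target (reoriented
with the ground-truth inter-convention mapping when enabled,
normalized with source statistics) -> optionally adapt with DANN and
re-test. Results are written as CSV tables on a percent scale with the
cell key in the row, plus per-cell confusion matrices and a provenance
log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .augment import AugmentationConfig
from .dann import DANNConfig, DomainAdversarialNetwork
from .data import WindowSet
from .evaluate import cross_test, run_cv
from .models import ARCHITECTURES, TrainConfig
from .preprocess import preprocess_recordings
from .reorient import mapping_between
from .synthetic import generate_cohort, preset

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_grid", "incremental_source_curve"]


@dataclass
class ExperimentConfig:
    source_preset: str = "mhealth-like"
    target_preset: str = "pd-like"
    architectures: tuple[str, ...] = ("base",)
    augmentation: tuple[bool, ...] = (False, True)
    reorientation: tuple[bool, ...] = (False, True)
    adaptation: tuple[bool, ...] = (False,)
    seeds: tuple[int, ...] = (0,)
    combine_sources: tuple[str, ...] = ()  # extra source presets, reoriented and concatenated
    n_subjects: int | None = None  # scaled-down cohorts for quick runs
    target_subjects: int | None = None
    duration_scale: float = 1.0
    augment_copies: int = 8
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    dann: dict = field(default_factory=dict)  # DANNConfig overrides
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("seeds must be non-empty")
        for arch in self.architectures:
            if arch not in ARCHITECTURES:
                raise ValueError(f"unknown architecture {arch!r}")

    @staticmethod
    def from_yaml(path: str | Path) -> "ExperimentConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        for key in ("architectures", "augmentation", "reorientation", "adaptation", "seeds", "combine_sources"):
            if key in d:
                d[key] = tuple(d[key])
        return ExperimentConfig(**d)

    def fingerprint(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _windows_for(preset_name: str, n_subjects, duration_scale, seed: int) -> tuple[WindowSet, object]:
    spec = preset(preset_name, n_subjects=n_subjects, duration_scale=duration_scale)
    recs = generate_cohort(spec, seed=derive_seed(seed, "cohort", preset_name))
    return preprocess_recordings(recs), spec


def run_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Execute every grid cell; returns (and writes) the result table."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for seed in config.seeds:
        source_ws, source_spec = _windows_for(
            config.source_preset, config.n_subjects, config.duration_scale, seed
        )
        for extra in config.combine_sources:
            extra_ws, extra_spec = _windows_for(extra, config.n_subjects, config.duration_scale, seed)
            m = mapping_between(extra_spec.axis_convention, source_spec.axis_convention)
            from .reorient import apply_mapping

            extra_ws = apply_mapping(extra_ws, m)
            extra_ws = WindowSet(
                extra_ws.windows,
                extra_ws.labels,
                np.array([f"{extra}:{s}" for s in extra_ws.subject_ids], dtype=object),
                source_ws.dataset_name,
                extra_ws.sample_rate,
            )
            source_ws = WindowSet.concatenate([source_ws, extra_ws], source_ws.dataset_name)
        target_ws, target_spec = _windows_for(
            config.target_preset, config.target_subjects, config.duration_scale, seed
        )
        true_mapping = mapping_between(target_spec.axis_convention, source_spec.axis_convention)

        for arch in config.architectures:
            spec = ARCHITECTURES[arch](n_classes=len(source_ws.activities))
            for augment in config.augmentation:
                aug_cfg = (
                    AugmentationConfig(copies_per_window=config.augment_copies, seed=derive_seed(seed, "aug"))
                    if augment
                    else None
                )
                try:
                    cv = run_cv(
                        source_ws,
                        spec=spec,
                        train_cfg=TrainConfig(**config.train),
                        augment_cfg=aug_cfg,
                        seed=derive_seed(seed, "cv", arch, augment),
                    )
                except Exception:  # noqa: BLE001 - a failed cell must not kill the grid
                    logger.exception("CV failed for cell arch=%s aug=%s seed=%d", arch, augment, seed)
                    continue
                for reorient in config.reorientation:
                    mapping = true_mapping if reorient else None
                    for adapt in config.adaptation:
                        cell = dict(
                            source=config.source_preset,
                            target=config.target_preset,
                            architecture=arch,
                            augmented=augment,
                            reoriented=reorient,
                            adapted=adapt,
                            seed=seed,
                        )
                        try:
                            if adapt:
                                from .preprocess import apply_normalizer
                                from .reorient import apply_mapping

                                tgt = apply_mapping(target_ws, mapping) if mapping else target_ws
                                tgt_n = apply_normalizer(tgt, cv.best_stats)
                                src_n = apply_normalizer(
                                    source_ws.for_subjects(
                                        [s for s in source_ws.subjects if s != cv.best_fold]
                                    ),
                                    cv.best_stats,
                                )
                                dann = DomainAdversarialNetwork.from_classifier(
                                    cv.best_model, cfg=DANNConfig(**config.dann)
                                )
                                adapted = dann.fit(src_n, tgt_n.windows, seed=derive_seed(seed, "dann", arch))
                                y_pred = adapted.predict(tgt_n)
                                from .evaluate import binary_metrics_avg

                                avg_acc, per_act, avg_f1 = binary_metrics_avg(
                                    tgt.labels, y_pred, tuple(sorted(set(tgt.labels)))
                                )
                                res_row = dict(
                                    cv_accuracy=cv.mean_accuracy,
                                    avg_binary_accuracy=avg_acc,
                                    avg_binary_f1=avg_f1,
                                )
                            else:
                                res = cross_test(cv.best_model, cv.best_stats, target_ws, mapping=mapping)
                                res_row = dict(
                                    cv_accuracy=cv.mean_accuracy,
                                    accuracy=res.accuracy,
                                    macro_f1=res.macro_f1,
                                    avg_binary_accuracy=res.avg_binary_accuracy,
                                    avg_binary_f1=res.avg_binary_f1,
                                )
                                if res.confusion is not None:
                                    name = "_".join(
                                        str(v) for v in cell.values()
                                    ).replace("/", "-")
                                    res.confusion.to_csv(out / f"confusion_{name}.csv")
                            rows.append({**cell, **{k: v for k, v in res_row.items() if v is not None}})
                        except Exception:  # noqa: BLE001
                            logger.exception("cell failed: %s", cell)
    table = pd.DataFrame(rows).round(2)
    table.to_csv(out / "results.csv", index=False)
    provenance = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in config.__dict__.items()},
        "fingerprint": config.fingerprint(),
        "python": sys.version,
        "numpy": np.__version__,
    }
    (out / "run_log.json").write_text(json.dumps(provenance, indent=2, default=str))
    return table


def incremental_source_curve(config: ExperimentConfig, step_subjects: int = 2) -> pd.DataFrame:
    """Target metrics as the source training set grows by ``step_subjects``.

    Reported per seed, never silently averaged; no monotonicity is
    implied (adding subjects does not reliably help).
    """
    if step_subjects < 1:
        raise ValueError("step_subjects must be >= 1")
    rows = []
    arch = config.architectures[0]
    for seed in config.seeds:
        source_ws, source_spec = _windows_for(
            config.source_preset, config.n_subjects, config.duration_scale, seed
        )
        target_ws, target_spec = _windows_for(
            config.target_preset, config.target_subjects, config.duration_scale, seed
        )
        mapping = mapping_between(target_spec.axis_convention, source_spec.axis_convention)
        subjects = source_ws.subjects
        for k in range(step_subjects, len(subjects) + 1, step_subjects):
            subset = source_ws.for_subjects(subjects[:k])
            spec = ARCHITECTURES[arch](n_classes=len(subset.activities))
            cv = run_cv(
                subset,
                spec=spec,
                train_cfg=TrainConfig(**config.train),
                seed=derive_seed(seed, "curve", k),
            )
            res = cross_test(cv.best_model, cv.best_stats, target_ws, mapping=mapping)
            rows.append(
                dict(
                    seed=seed,
                    n_subjects=k,
                    cv_accuracy=cv.mean_accuracy,
                    avg_binary_accuracy=res.avg_binary_accuracy,
                    avg_binary_f1=res.avg_binary_f1,
                    accuracy=res.accuracy,
                )
            )
    curve = pd.DataFrame(rows).round(2)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    curve.to_csv(out / "incremental_curve.csv", index=False)
    return curve
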