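"""The five-stage data preparation pipeline.

Fixed stage order: read -> drop_invalid -> resample -> convert_units ->
trim_transients -> segment_windows -> map_activities -> normalize.
Re-running the pipeline on identical input is bit-identical; no window
ever spans two activity labels (windows are drawn inside single-label
runs by construction).
"""

from __future__ import annotations

import logging
import math
import warnings
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .data import (
    CHANNELS,
    NULL_LABEL,
    STANDARD_GRAVITY,
    NormalizationStats,
    Recording,
    WindowSet,
)

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 150  # 3 s at 50 Hz
TARGET_HZ = 50.0


class ActivityMap:
    """Mapping from source activity labels to canonical labels.

    Labels listed in ``drop`` are removed; any other unmapped label is
    an error (the map must be total over the labels it is applied to).
    """

    def __init__(self, mapping: dict[str, str], drop: set[str] | None = None):
        self.mapping = dict(mapping)
        self.drop = set(drop or ())

    def __call__(self, label: str) -> str | None:
        if label in self.mapping:
            return self.mapping[label]
        if label in self.drop:
            return None
        raise KeyError(f"activity {label!r} is neither mapped nor droppable")


#: The printed PD-to-common activity mapping.
PD_ACTIVITY_MAP = ActivityMap(
    {
        "ambulation": "walking",
        "arms_resting": "sitting",
        "cutting": "sitting",
        "dressing": "standing",
        "drinking": "sitting",
        "unpacking_groceries": "sitting",
    }
)


def _runs(labels: np.ndarray):
    """Yield (start, stop, label) for maximal contiguous single-label runs."""
    n = len(labels)
    if n == 0:
        return
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            yield start, i, labels[start]
            start = i


def drop_invalid(rec: Recording) -> Recording:
    """Remove null-class-labeled and missing (NaN) samples, keeping order."""
    finite = np.isfinite(rec.samples).all(axis=1)
    labeled = np.array([l != NULL_LABEL for l in rec.labels])
    keep = finite & labeled
    if not keep.any():
        logger.warning("%s: all samples invalid; empty recording", rec.subject_id)
    return Recording(
        rec.subject_id, rec.dataset_name, rec.sample_rate, rec.samples[keep], rec.labels[keep]
    )


def resample_to(rec: Recording, target_hz: float = TARGET_HZ) -> Recording:
    """Anti-aliased polyphase down-sampling; labels by nearest original sample.

    Up-sampling is refused: the pipeline only ever brings faster sensors
    down to the common 50 Hz rate.
    """
    if rec.sample_rate < target_hz:
        raise ValueError(
            f"upsampling {rec.sample_rate} -> {target_hz} Hz is not supported"
        )
    if rec.sample_rate == target_hz:
        return rec
    frac = Fraction(target_hz / rec.sample_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if len(rec) == 0:
        samples = rec.samples
        labels = rec.labels
    elif math.isclose(up / down, target_hz / rec.sample_rate, rel_tol=1e-9):
        samples = sps.resample_poly(rec.samples, up, down, axis=0)
        n_out = samples.shape[0]
        src_idx = np.clip(
            np.round(np.arange(n_out) * down / up).astype(int), 0, len(rec) - 1
        )
        labels = rec.labels[src_idx]
    else:  # non-rational ratio: linear interpolation fallback
        n_out = int(math.floor(len(rec) * target_hz / rec.sample_rate))
        t_out = np.arange(n_out) / target_hz
        t_in = np.arange(len(rec)) / rec.sample_rate
        samples = np.column_stack(
            [np.interp(t_out, t_in, rec.samples[:, c]) for c in range(len(CHANNELS))]
        )
        src_idx = np.clip(np.round(t_out * rec.sample_rate).astype(int), 0, len(rec) - 1)
        labels = rec.labels[src_idx]
    return Recording(rec.subject_id, rec.dataset_name, target_hz, samples, labels)


def convert_units(rec: Recording, from_unit: str = "m/s2") -> Recording:
    """Convert g to m/s**2 (factor 9.80665); m/s**2 input is returned as is."""
    unit = from_unit.replace("²", "2").replace("m/s^2", "m/s2")
    if unit == "m/s2":
        return rec
    if unit == "g":
        return Recording(
            rec.subject_id,
            rec.dataset_name,
            rec.sample_rate,
            rec.samples * STANDARD_GRAVITY,
            rec.labels,
        )
    raise ValueError(f"unknown acceleration unit {from_unit!r}")


def trim_transients(rec: Recording, trim_s: float = 5.0) -> Recording:
    """Drop ``trim_s`` seconds from both ends of every labeled activity run.

    Runs shorter than twice the trim vanish entirely (with a warning):
    they contain only transient data.
    """
    if trim_s < 0:
        raise ValueError("trim_s must be >= 0")
    k = int(round(trim_s * rec.sample_rate))
    if k == 0:
        return rec
    keep = np.zeros(len(rec), dtype=bool)
    for start, stop, label in _runs(rec.labels):
        if stop - start <= 2 * k:
            logger.warning(
                "%s: %s run of %d samples shorter than 2x trim; removed",
                rec.subject_id,
                label,
                stop - start,
            )
            continue
        keep[start + k : stop - k] = True
    return Recording(
        rec.subject_id, rec.dataset_name, rec.sample_rate, rec.samples[keep], rec.labels[keep]
    )


def segment_windows(
    rec: Recording, length: int = WINDOW_LENGTH, step: int | None = None
) -> WindowSet:
    """Segment into fixed-length windows drawn inside single-label runs.

    A run of L samples yields floor((L - length)/step) + 1 windows (zero
    when L < length). The default step equals the window length
    (non-overlapping).
    """
    if rec.sample_rate != TARGET_HZ:
        raise ValueError(
            f"segment_windows expects {TARGET_HZ:g} Hz input, got {rec.sample_rate:g};"
            " resample first"
        )
    step = step or length
    windows, labels = [], []
    for start, stop, label in _runs(rec.labels):
        for w0 in range(start, stop - length + 1, step):
            windows.append(rec.samples[w0 : w0 + length])
            labels.append(label)
    n = len(windows)
    return WindowSet(
        np.array(windows) if n else np.empty((0, length, len(CHANNELS))),
        np.array(labels, dtype=object),
        np.array([rec.subject_id] * n, dtype=object),
        rec.dataset_name,
        rec.sample_rate,
    )


def map_activities(ws: WindowSet, amap: ActivityMap) -> WindowSet:
    """Replace labels per the map; windows with droppable labels are removed."""
    new_labels, keep = [], []
    for l in ws.labels:
        target = amap(l)
        keep.append(target is not None)
        new_labels.append(target if target is not None else l)
    keep = np.array(keep)
    return WindowSet(
        ws.windows[keep],
        np.array(new_labels, dtype=object)[keep],
        ws.subject_ids[keep],
        ws.dataset_name,
        ws.sample_rate,
    )


def fit_normalizer(train: WindowSet) -> NormalizationStats:
    """Per-channel mean/sd over all training timestamps.

    When augmentation is used, the normalizer is fitted on the augmented
    training windows (augment first, then fit).
    """
    if len(train) == 0:
        raise ValueError("cannot fit a normalizer on an empty window set")
    flat = train.windows.reshape(-1, train.windows.shape[2])
    return NormalizationStats(
        mean=flat.mean(axis=0), std=flat.std(axis=0), fitted_on=train.dataset_name
    )


def apply_normalizer(ws: WindowSet, stats: NormalizationStats) -> WindowSet:
    return WindowSet(
        (ws.windows - stats.mean) / stats.std,
        ws.labels.copy(),
        ws.subject_ids.copy(),
        ws.dataset_name,
        ws.sample_rate,
    )


def preprocess_recordings(
    recordings: list[Recording],
    *,
    target_hz: float = TARGET_HZ,
    from_unit: str = "m/s2",
    trim_s: float = 5.0,
    length: int = WINDOW_LENGTH,
    step: int | None = None,
    activity_map: ActivityMap | None = None,
    dataset_name: str | None = None,
) -> WindowSet:
    """Run the full fixed-order pipeline over a cohort and pool the windows.

    Normalization is *not* applied here: it is fitted on training folds
    only (see :func:`harshift.evaluate.run_cv`).
    """
    sets = []
    for rec in recordings:
        r = drop_invalid(rec)
        r = resample_to(r, target_hz)
        r = convert_units(r, from_unit)
        r = trim_transients(r, trim_s)
        ws = segment_windows(r, length=length, step=step)
        if activity_map is not None:
            ws = map_activities(ws, activity_map)
        sets.append(ws)
    non_empty = [s for s in sets if len(s)] or sets[:1]
    return WindowSet.concatenate(non_empty, dataset_name or recordings[0].dataset_name)
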