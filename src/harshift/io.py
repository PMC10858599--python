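"""Readers and writers for recordings.

The canonical on-disk format is ``repo-tsv``: a header line, then
tab-separated columns ``time_s``, the six acceleration channels
(``wrist_x .. ankle_z``, m/s**2) and ``activity``. Synthetic and
converted real data both flow through this dialect, so the rest of the
pipeline never cares where a recording came from.

Optional readers handle the space-separated PAMAP2 ``.dat`` column
layout and the MHEALTH ``.log`` layout; only the wrist and ankle
accelerometer columns are read, everything else (gyroscope,
magnetometer, chest sensor, heart rate) is ignored. Samples with
missing acceleration values are kept as NaN rows and flagged for
:func:`harshift.preprocess.drop_invalid`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CHANNELS, NULL_LABEL, Recording

logger = logging.getLogger(__name__)

DIALECTS = ("repo-tsv", "pamap2-dat", "mhealth-log")

#: Default column indices of the wrist/ankle 3D accelerometers in the
#: space-separated PAMAP2 layout (time, activity id, heart rate, then
#: three 17-column IMU blocks: hand, chest, ankle).
PAMAP2_COLUMNS = {
    "time": 0,
    "activity": 1,
    "wrist": (4, 5, 6),
    "ankle": (38, 39, 40),
}

#: Default column indices in the MHEALTH log layout (23 space/tab
#: separated columns; right-lower-arm acc at 14-16, ankle acc at 5-7,
#: label last).
MHEALTH_COLUMNS = {
    "wrist": (14, 15, 16),
    "ankle": (5, 6, 7),
    "activity": 23,
}


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording in the repo-tsv dialect."""
    t = np.arange(len(rec)) / rec.sample_rate
    df = pd.DataFrame(rec.samples, columns=list(CHANNELS))
    df.insert(0, "time_s", t)
    df["activity"] = rec.labels
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _from_frame(
    acc: np.ndarray,
    labels: np.ndarray,
    subject_id: str,
    dataset_name: str,
    sample_rate: float,
) -> Recording:
    labels = np.array(
        [NULL_LABEL if (isinstance(l, float) and np.isnan(l)) else str(l) for l in labels],
        dtype=object,
    )
    return Recording(
        subject_id=subject_id,
        dataset_name=dataset_name,
        sample_rate=sample_rate,
        samples=acc,
        labels=labels,
    )


def read_recording(
    path: str | Path,
    dialect: str = "repo-tsv",
    *,
    subject_id: str | None = None,
    dataset_name: str | None = None,
    sample_rate: float | None = None,
    columns: dict | None = None,
    activity_names: dict | None = None,
    bad_line_tolerance: float = 0.01,
) -> Recording:
    """Read a recording file in one of the supported dialects.

    ``activity_names`` optionally maps raw activity codes (e.g. PAMAP2
    integer ids) to label strings; unmapped codes and the reserved id 0
    become the null label. Files whose fraction of malformed rows
    exceeds ``bad_line_tolerance`` raise a parse error.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    subject_id = subject_id or path.stem
    dataset_name = dataset_name or dialect

    if dialect == "repo-tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ("time_s", *CHANNELS, "activity") if c not in df.columns]
        if missing:
            raise ValueError(f"repo-tsv file missing columns {missing}")
        if sample_rate is None:
            dt = np.diff(df["time_s"].to_numpy())
            if len(dt) == 0 or np.median(dt) <= 0:
                raise ValueError("cannot infer sample rate from time column")
            sample_rate = float(round(1.0 / np.median(dt)))
        acc = df[list(CHANNELS)].to_numpy(dtype=float)
        return _from_frame(acc, df["activity"].to_numpy(), subject_id, dataset_name, sample_rate)

    sep = r"\s+"
    n_bad = 0

    if dialect == "pamap2-dat":
        cols = {**PAMAP2_COLUMNS, **(columns or {})}
        raw = pd.read_csv(path, sep=sep, header=None)
        needed = [cols["time"], cols["activity"], *cols["wrist"], *cols["ankle"]]
        if raw.shape[1] <= max(needed):
            n_bad = len(raw)
        if len(raw) and n_bad / max(len(raw), 1) > bad_line_tolerance:
            raise ValueError(f"{path}: too few columns for the PAMAP2 layout")
        acc = raw[[*cols["wrist"], *cols["ankle"]]].to_numpy(dtype=float)
        act = raw[cols["activity"]].to_numpy()
        rate = sample_rate or 100.0
    else:  # mhealth-log
        cols = {**MHEALTH_COLUMNS, **(columns or {})}
        raw = pd.read_csv(path, sep=sep, header=None)
        if raw.shape[1] <= max(cols["activity"], *cols["wrist"], *cols["ankle"]):
            raise ValueError(f"{path}: too few columns for the MHEALTH layout")
        acc = raw[[*cols["wrist"], *cols["ankle"]]].to_numpy(dtype=float)
        act = raw[cols["activity"]].to_numpy()
        rate = sample_rate or 50.0

    names = activity_names or {}
    out = []
    for a in act:
        if pd.isna(a):
            out.append(NULL_LABEL)
            continue
        key = a
        if key not in names:
            try:
                key = int(a)
            except (TypeError, ValueError):
                pass
        if names:
            out.append(str(names[key]) if key in names else NULL_LABEL)
        else:
            # activity id 0 is the conventional null class in both layouts
            try:
                is_null = float(a) == 0.0
            except (TypeError, ValueError):
                is_null = False
            out.append(NULL_LABEL if is_null else str(a))
    labels = np.array(out, dtype=object)
    return Recording(
        subject_id=subject_id,
        dataset_name=dataset_name,
        sample_rate=rate,
        samples=acc,
        labels=labels,
    )


def write_cohort(recordings, directory: str | Path) -> list[Path]:
    """Write every recording of a cohort as repo-tsv files; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        p = directory / f"{rec.subject_id}.tsv"
        write_recording(rec, p)
        paths.append(p)
    return paths


def read_cohort(directory: str | Path, dialect: str = "repo-tsv", **kwargs) -> list[Recording]:
    directory = Path(directory)
    suffix = {"repo-tsv": "*.tsv", "pamap2-dat": "*.dat", "mhealth-log": "*.log"}[dialect]
    paths = sorted(directory.glob(suffix))
    if not paths:
        raise FileNotFoundError(f"no {suffix} files in {directory}")
    return [read_recording(p, dialect, **kwargs) for p in paths]
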