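"""Core data containers: recordings, window sets and normalization stats.

All sensor data are 6-channel accelerations in m/s**2 ordered as two
3-axis blocks: wrist (x, y, z) then ankle (x, y, z).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

logger = logging.getLogger(__name__)

#: Canonical channel order: wrist block then ankle block.
CHANNELS: tuple[str, ...] = (
    "wrist_x",
    "wrist_y",
    "wrist_z",
    "ankle_x",
    "ankle_y",
    "ankle_z",
)

#: Reserved label for transient / unspecified activity samples.
NULL_LABEL = "null"

#: Standard gravity, used to convert g to m/s**2.
STANDARD_GRAVITY = 9.80665


@dataclass
class Recording:
    """One subject's continuous labeled multichannel acceleration trace.

    Missing samples are encoded as NaN rows; they are removed by
    :func:`harshift.preprocess.drop_invalid`.
    """

    subject_id: str
    dataset_name: str
    sample_rate: float
    samples: np.ndarray  # (T, 6) in m/s**2
    labels: np.ndarray  # (T,) str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(CHANNELS):
            raise ValueError(
                f"samples must be (T, {len(CHANNELS)}), got {self.samples.shape}"
            )
        if len(self.labels) != len(self.samples):
            raise ValueError("samples and labels must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate


@dataclass
class WindowSet:
    """Fixed-length labeled windows; the unit of all training and testing."""

    windows: np.ndarray  # (N, length, 6)
    labels: np.ndarray  # (N,) str
    subject_ids: np.ndarray  # (N,) str
    dataset_name: str = ""
    sample_rate: float = 50.0

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.windows.ndim != 3 or self.windows.shape[2] != len(CHANNELS):
            raise ValueError(f"windows must be (N, L, 6), got {self.windows.shape}")
        if not (len(self.windows) == len(self.labels) == len(self.subject_ids)):
            raise ValueError("windows, labels and subject_ids must align")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def window_length(self) -> int:
        return self.windows.shape[1]

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.subject_ids))

    @property
    def activities(self) -> list[str]:
        return sorted(set(self.labels))

    def subset(self, mask: np.ndarray) -> "WindowSet":
        mask = np.asarray(mask)
        return WindowSet(
            self.windows[mask],
            self.labels[mask],
            self.subject_ids[mask],
            self.dataset_name,
            self.sample_rate,
        )

    def for_subjects(self, subjects) -> "WindowSet":
        wanted = set(subjects)
        return self.subset(np.array([s in wanted for s in self.subject_ids]))

    @staticmethod
    def concatenate(sets: list["WindowSet"], dataset_name: str = "") -> "WindowSet":
        if not sets:
            raise ValueError("cannot concatenate zero window sets")
        rate = sets[0].sample_rate
        if any(ws.sample_rate != rate for ws in sets):
            raise ValueError("sample rates differ")
        return WindowSet(
            np.concatenate([ws.windows for ws in sets]),
            np.concatenate([ws.labels for ws in sets]),
            np.concatenate([ws.subject_ids for ws in sets]),
            dataset_name or sets[0].dataset_name,
            rate,
        )

    def save(self, path: str | Path) -> None:
        """Persist as an HDF5 container with named arrays."""
        with h5py.File(path, "w") as f:
            f.create_dataset("windows", data=self.windows)
            f.create_dataset("labels", data=np.array(self.labels, dtype="S64"))
            f.create_dataset("subjects", data=np.array(self.subject_ids, dtype="S64"))
            f.attrs["dataset_name"] = self.dataset_name
            f.attrs["sample_rate"] = self.sample_rate

    @staticmethod
    def load(path: str | Path) -> "WindowSet":
        with h5py.File(path, "r") as f:
            return WindowSet(
                f["windows"][:],
                np.array([s.decode() for s in f["labels"][:]], dtype=object),
                np.array([s.decode() for s in f["subjects"][:]], dtype=object),
                str(f.attrs.get("dataset_name", "")),
                float(f.attrs.get("sample_rate", 50.0)),
            )


@dataclass
class NormalizationStats:
    """Per-channel z-score statistics, fitted on a training set.

    In cross-domain testing the *source*-fitted statistics are applied to
    the target data; the target is never re-normalized with its own
    statistics.
    """

    mean: np.ndarray  # (6,)
    std: np.ndarray  # (6,)
    fitted_on: str = ""
    clamp: float = 1e-8

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != (len(CHANNELS),) or self.std.shape != (len(CHANNELS),):
            raise ValueError("stats must have one entry per channel")
        if np.any(self.std < self.clamp):
            warnings.warn(
                "zero-variance channel; clamping standard deviation",
                RuntimeWarning,
                stacklevel=2,
            )
            self.std = np.maximum(self.std, self.clamp)
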