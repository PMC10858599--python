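"""Training-set augmentation: rotation, jitter and scaling.

Each augmented copy applies, in order, a random 3D rotation per sensor
block (simulating different sensor placements, bounded to +/-90 degrees
so activity patterns are not corrupted), a single random amplitude
scalar per window, and i.i.d. Gaussian jitter. At the study settings
each original window spawns eight combined-augmentation copies, so the
augmented set is nine times the original. Augmentation is applied to
training data only; a held-out target set is never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import rng_for
from .data import WindowSet

__all__ = [
    "AugmentationConfig",
    "rotate_window",
    "jitter_window",
    "scale_window",
    "augment_dataset",
]


@dataclass(frozen=True)
class AugmentationConfig:
    rotation_range_deg: float = 90.0  # angle drawn from U(-range, +range)
    jitter_sd: float = 0.05
    scale_sd: float = 0.1
    scale_mean: float = 1.0
    copies_per_window: int = 8
    shared_rotation: bool = False  # one rotation for both sensor blocks
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rotation_range_deg <= 90:
            raise ValueError("rotation range must lie within [0, 90] degrees")
        if self.jitter_sd < 0 or self.scale_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.copies_per_window < 0:
            raise ValueError("copies_per_window must be >= 0")


def _rotation_matrices(axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Rodrigues formula, vectorized: axes (..., 3) unit, angles (...)."""
    x, y, z = axes[..., 0], axes[..., 1], axes[..., 2]
    zero = np.zeros_like(x)
    k = np.stack(
        [
            np.stack([zero, -z, y], axis=-1),
            np.stack([z, zero, -x], axis=-1),
            np.stack([-y, x, zero], axis=-1),
        ],
        axis=-2,
    )  # (..., 3, 3) cross-product matrix
    s = np.sin(angles)[..., None, None]
    c = np.cos(angles)[..., None, None]
    eye = np.eye(3)
    return eye + s * k + (1 - c) * (k @ k)


def _draw_rotations(n: int, cfg: AugmentationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw (n, 2, 3, 3) proper rotations: one per sensor block per copy."""
    blocks = 1 if cfg.shared_rotation else 2
    v = rng.normal(size=(n, blocks, 3))
    axes = v / np.linalg.norm(v, axis=-1, keepdims=True)
    angles = rng.uniform(
        -np.deg2rad(cfg.rotation_range_deg), np.deg2rad(cfg.rotation_range_deg), size=(n, blocks)
    )
    mats = _rotation_matrices(axes, angles)
    if cfg.shared_rotation:
        mats = np.repeat(mats, 2, axis=1)
    return mats


def rotate_window(
    window: np.ndarray, cfg: AugmentationConfig | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Rotate each 3-channel sensor block by an independent random rotation.

    The rotation axis is uniform on the sphere and the angle uniform in
    (-range, +range); per-timestamp Euclidean norms of each block are
    preserved exactly (rotations are isometries).
    """
    cfg = cfg or AugmentationConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    mats = _draw_rotations(1, cfg, rng)[0]  # (2, 3, 3)
    return apply_rotations(window[None], mats[None])[0]


def apply_rotations(windows: np.ndarray, mats: np.ndarray) -> np.ndarray:
    """Apply per-window per-block rotations; windows (N, L, 6), mats (N, 2, 3, 3)."""
    out = np.empty_like(windows)
    for b in range(2):
        blk = windows[:, :, 3 * b : 3 * b + 3]  # (N, L, 3)
        out[:, :, 3 * b : 3 * b + 3] = np.einsum("nij,nlj->nli", mats[:, b], blk)
    return out


def jitter_window(
    window: np.ndarray, jitter_sd: float = 0.05, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise to every entry."""
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(0)
    if jitter_sd == 0:
        return window.copy()
    return window + rng.normal(0.0, jitter_sd, size=window.shape)


def scale_window(
    window: np.ndarray,
    scale_mean: float = 1.0,
    scale_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multiply the whole window by one scalar drawn from N(mean, sd**2)."""
    if scale_sd < 0:
        raise ValueError("scale_sd must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(0)
    s = rng.normal(scale_mean, scale_sd) if scale_sd > 0 else scale_mean
    return window * s


def augment_dataset(ws: WindowSet, cfg: AugmentationConfig) -> WindowSet:
    """Original windows plus ``copies_per_window`` combined-augmentation copies.

    Each copy applies rotation, then scaling, then jitter, with
    independent draws per copy; labels and subject ids are replicated,
    so the output size is ``len(ws) * (1 + copies)``. Deterministic
    given ``cfg.seed``.
    """
    if cfg.copies_per_window == 0:
        return ws
    rng = rng_for(cfg.seed, "augment", ws.dataset_name)
    n, L, C = ws.windows.shape
    total = n * cfg.copies_per_window
    mats = _draw_rotations(total, cfg, rng)
    base = np.repeat(ws.windows, cfg.copies_per_window, axis=0)
    copies = apply_rotations(base, mats)
    scales = rng.normal(cfg.scale_mean, cfg.scale_sd, size=total) if cfg.scale_sd > 0 else np.full(total, cfg.scale_mean)
    copies *= scales[:, None, None]
    if cfg.jitter_sd > 0:
        copies += rng.normal(0.0, cfg.jitter_sd, size=copies.shape)
    return WindowSet(
        np.concatenate([ws.windows, copies]),
        np.concatenate([ws.labels, np.repeat(ws.labels, cfg.copies_per_window)]),
        np.concatenate([ws.subject_ids, np.repeat(ws.subject_ids, cfg.copies_per_window)]),
        ws.dataset_name,
        ws.sample_rate,
    )
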