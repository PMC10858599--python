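"""Manual sensor-axis reorientation between dataset conventions.

Different wearable deployments mount the same sensor with different axis
orientations (e.g. x pointing distally vs. proximally). A reorientation
is a *signed permutation* of the 6 channels that is block-respecting:
wrist axes map only to wrist axes and ankle axes only to ankle axes.
In cross-domain testing the target dataset is reoriented to match the
source dataset's convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CHANNELS, WindowSet

_SHORT = {"wx": 0, "wy": 1, "wz": 2, "ax": 3, "ay": 4, "az": 5}
_SHORT_NAMES = {v: k for k, v in _SHORT.items()}


def _block(i: int) -> int:
    return i // 3  # 0 = wrist, 1 = ankle


@dataclass(frozen=True)
class AxisMapping:
    """Signed permutation: output channel c reads sign[c] * input[source[c]]."""

    source: tuple[int, ...]  # length 6, a permutation of 0..5
    sign: tuple[int, ...]  # length 6, entries in {+1, -1}

    def __post_init__(self) -> None:
        if len(self.source) != 6 or len(self.sign) != 6:
            raise ValueError("mapping must cover exactly 6 channels")
        if sorted(self.source) != list(range(6)):
            raise ValueError("source channels must form a permutation of 0..5")
        if any(s not in (-1, 1) for s in self.sign):
            raise ValueError("signs must be +1 or -1")
        for out, src in enumerate(self.source):
            if _block(out) != _block(src):
                raise ValueError(
                    f"cross-block mapping: {CHANNELS[out]} <- {CHANNELS[src]}"
                )

    @property
    def matrix(self) -> np.ndarray:
        """The 6x6 signed permutation matrix M with out = in @ M.T."""
        m = np.zeros((6, 6))
        for out, (src, sg) in enumerate(zip(self.source, self.sign)):
            m[out, src] = sg
        return m

    def is_identity(self) -> bool:
        return self.source == tuple(range(6)) and all(s == 1 for s in self.sign)

    def to_string(self) -> str:
        parts = []
        for out, (src, sg) in enumerate(zip(self.source, self.sign)):
            src_name = _SHORT_NAMES[src]
            parts.append(f"{_SHORT_NAMES[out]}:{'-' if sg < 0 else ''}{src_name}")
        return ", ".join(parts)


IDENTITY_MAPPING = AxisMapping(tuple(range(6)), (1,) * 6)


def parse_mapping(text: str) -> AxisMapping:
    """Parse a mapping string like ``"wx:-wy, wy:wx, wz:wz, ax:ax, ay:-az, az:ay"``.

    Each entry reads ``output:signed-source``. Raises ``ValueError`` on
    unknown channels, non-permutations or cross-block assignments.
    """
    source = [-1] * 6
    sign = [0] * 6
    entries = [e.strip() for e in text.split(",") if e.strip()]
    if len(entries) != 6:
        raise ValueError(f"expected 6 channel assignments, got {len(entries)}")
    for entry in entries:
        try:
            out_name, src_name = (p.strip() for p in entry.split(":"))
        except ValueError as exc:
            raise ValueError(f"malformed entry {entry!r}") from exc
        sg = 1
        if src_name.startswith("-"):
            sg = -1
            src_name = src_name[1:].strip()
        if out_name not in _SHORT or src_name not in _SHORT:
            raise ValueError(f"unknown channel in entry {entry!r}")
        out = _SHORT[out_name]
        if source[out] != -1:
            raise ValueError(f"duplicate assignment for channel {out_name}")
        source[out] = _SHORT[src_name]
        sign[out] = sg
    return AxisMapping(tuple(source), tuple(sign))


def apply_to_array(samples: np.ndarray, mapping: AxisMapping) -> np.ndarray:
    """Apply a mapping along the last (channel) axis of an array."""
    out = samples[..., list(mapping.source)] * np.asarray(mapping.sign, dtype=float)
    return out


def apply_mapping(ws: WindowSet, mapping: AxisMapping) -> WindowSet:
    """Reorient every window; labels and subject ids are untouched."""
    return WindowSet(
        apply_to_array(ws.windows, mapping),
        ws.labels.copy(),
        ws.subject_ids.copy(),
        ws.dataset_name,
        ws.sample_rate,
    )


def invert_mapping(m: AxisMapping) -> AxisMapping:
    """Inverse mapping: apply(invert(m)) o apply(m) is the identity."""
    source = [0] * 6
    sign = [1] * 6
    for out, (src, sg) in enumerate(zip(m.source, m.sign)):
        source[src] = out
        sign[src] = sg
    return AxisMapping(tuple(source), tuple(sign))


def compose_mappings(outer: AxisMapping, inner: AxisMapping) -> AxisMapping:
    """Mapping equivalent to applying ``inner`` first, then ``outer``."""
    source = tuple(inner.source[s] for s in outer.source)
    sign = tuple(outer.sign[c] * inner.sign[outer.source[c]] for c in range(6))
    return AxisMapping(source, sign)


def mapping_between(target_convention: AxisMapping, source_convention: AxisMapping) -> AxisMapping:
    """Mapping that re-expresses target-convention data in the source convention.

    Both arguments are each dataset's convention relative to a common
    canonical frame (data_in_convention = convention applied to canonical
    data), so target -> source is source_conv o target_conv^-1.
    """
    return compose_mappings(source_convention, invert_mapping(target_convention))


def suggest_mapping(source_ws: WindowSet, target_ws: WindowSet) -> AxisMapping:
    """Score candidate block-respecting signed permutations by channel statistics.

    A diagnostic helper only: it matches channels by comparing per-channel
    means (gravity direction) and standard deviations across shared
    activities, mirroring how one would align axes by eye. The chosen
    mapping should always remain explicit, user-visible configuration.
    """
    shared = sorted(set(source_ws.labels) & set(target_ws.labels))
    if not shared:
        raise ValueError("no shared activities to compare")

    def profile(ws: WindowSet) -> np.ndarray:
        rows = []
        for act in shared:
            w = ws.windows[ws.labels == act]
            rows.append(np.concatenate([w.mean(axis=(0, 1)), w.std(axis=(0, 1))]))
        return np.array(rows)  # (n_act, 12)

    ps, pt = profile(source_ws), profile(target_ws)
    source = [0] * 6
    sign = [1] * 6
    for blk in (0, 1):
        idx = range(3 * blk, 3 * blk + 3)
        # greedy per-block assignment over signed candidates
        used: set[int] = set()
        for out in idx:
            best, best_score = None, -np.inf
            for src in idx:
                if src in used:
                    continue
                for sg in (1, -1):
                    # compare target channel (candidate source) to source channel out
                    score = -np.sum(
                        (ps[:, [out, out + 6]] - np.column_stack(
                            [sg * pt[:, src], pt[:, src + 6]]
                        )) ** 2
                    )
                    if score > best_score:
                        best, best_score = (src, sg), score
            assert best is not None
            used.add(best[0])
            source[out], sign[out] = best
    return AxisMapping(tuple(source), tuple(sign))
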