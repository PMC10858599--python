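"""Synthetic accelerometer cohorts for healthy and Parkinson-like subjects.

The generator is a harmonic-plus-noise model, not a biomechanical one:
each activity is a quasi-periodic 3-axis signal per sensor (fundamental
plus decaying harmonics on top of a gravity baseline), with per-subject
log-normal amplitude scaling and uniform phase offsets to make
leave-one-subject-out folds genuinely heterogeneous. A Parkinson-like
phenotype adds a 4-6 Hz resting-tremor sinusoid, attenuates the dynamic
(gait) component, and inflates between-subject variability.

Three presets mirror the shapes of the study datasets: a 10-subject
50 Hz cohort ("mhealth-like"), an 8-subject 100 Hz cohort
("pamap2-like") and a 14-subject 128 Hz Parkinson-like cohort
("pd-like") whose per-activity durations are chosen so that the
post-pipeline window counts are 654 walking / 2843 sitting / 3042
standing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import derive_seed
from .data import Recording
from .reorient import IDENTITY_MAPPING, AxisMapping, apply_to_array, parse_mapping

__all__ = [
    "ActivitySignalSpec",
    "PdPhenotype",
    "CohortSpec",
    "generate_recording",
    "generate_cohort",
    "preset",
    "PRESET_NAMES",
]


class InvalidSpecError(ValueError):
    """Raised when a cohort specification violates its invariants."""


@dataclass(frozen=True)
class ActivitySignalSpec:
    """Signal parameters for one activity.

    ``fundamental_hz = 0`` encodes a static posture (no harmonic
    component, only the gravity baseline plus noise).
    """

    activity_name: str
    fundamental_hz: float
    per_channel_amplitude: tuple[float, ...]  # (6,) m/s**2
    baseline_offset: tuple[float, ...]  # (6,) m/s**2, gravity component
    harmonic_count: int = 2
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.fundamental_hz < 0:
            raise InvalidSpecError("fundamental_hz must be >= 0")
        if len(self.per_channel_amplitude) != 6 or len(self.baseline_offset) != 6:
            raise InvalidSpecError("amplitude/baseline need 6 channels")
        if not np.all(np.isfinite(self.per_channel_amplitude)):
            raise InvalidSpecError("amplitudes must be finite")
        if min(self.per_channel_amplitude) < 0:
            raise InvalidSpecError("amplitudes must be nonnegative")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PdPhenotype:
    """Parkinson-like signal alterations.

    tremor_hz
        Resting-tremor frequency in the clinical 4-6 Hz band.
    tremor_amplitude
        Tremor sinusoid amplitude (m/s**2), applied at full strength on
        the wrist channels and half strength on the ankle.
    gait_attenuation
        Multiplier in (0, 1] on the dynamic (harmonic) component,
        emulating bradykinetic, reduced-amplitude movement.
    variability_inflation
        Factor >= 1 on the between-subject variability.
    """

    tremor_hz: float = 5.0
    tremor_amplitude: float = 0.6
    gait_attenuation: float = 0.55
    variability_inflation: float = 1.5

    def __post_init__(self) -> None:
        if not 4.0 <= self.tremor_hz <= 6.0:
            raise InvalidSpecError("tremor_hz must lie in [4, 6] Hz")
        if not 0.0 < self.gait_attenuation <= 1.0:
            raise InvalidSpecError("gait_attenuation must lie in (0, 1]")
        if self.variability_inflation < 1.0:
            raise InvalidSpecError("variability_inflation must be >= 1")
        if self.tremor_amplitude < 0:
            raise InvalidSpecError("tremor_amplitude must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    ``per_activity_duration_s`` maps activity name to either a scalar
    duration (seconds, same for every subject) or a per-subject sequence
    of length ``n_subjects``; per-activity durations are the lever used
    to induce class imbalance.

    ``mounting_rotation_deg`` bounds a per-subject random rotation of
    each sensor block (axis uniform on the sphere, angle uniform within
    the bound), constant over the recording. It emulates how the same
    nominal placement still differs continuously between subjects and
    deployments — the residual orientation shift that a signed-
    permutation reorientation cannot remove, and the reason rotation
    augmentation exists.
    """

    dataset_name: str
    n_subjects: int
    sample_rate: float
    activities: tuple[ActivitySignalSpec, ...]
    per_activity_duration_s: dict
    axis_convention: AxisMapping = IDENTITY_MAPPING
    subject_variability: float = 0.15
    mounting_rotation_deg: float = 0.0
    pd_phenotype: PdPhenotype | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidSpecError("n_subjects must be >= 2 (LOSO needs >= 2)")
        if self.sample_rate <= 0:
            raise InvalidSpecError("sample_rate must be positive")
        if not self.activities:
            raise InvalidSpecError("at least one activity required")
        for act in self.activities:
            if act.activity_name not in self.per_activity_duration_s:
                raise InvalidSpecError(f"no duration for {act.activity_name!r}")

    def duration_for(self, activity_name: str, subject_index: int) -> float:
        d = self.per_activity_duration_s[activity_name]
        if np.ndim(d) > 0:
            if len(d) != self.n_subjects:
                raise InvalidSpecError(
                    f"per-subject durations for {activity_name!r} must have "
                    f"length {self.n_subjects}"
                )
            d = d[subject_index]
        return float(d)

    def subject_id(self, subject_index: int) -> str:
        return f"{self.dataset_name}_s{subject_index + 1:02d}"


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _mounting_rotations(bound_deg: float, rng: np.random.Generator):
    """Per-subject sensor-mounting rotations, one per block (or None)."""
    if bound_deg <= 0:
        return None
    mats = []
    for _ in range(2):
        v = rng.normal(size=3)
        axis = v / np.linalg.norm(v)
        angle = rng.uniform(-np.deg2rad(bound_deg), np.deg2rad(bound_deg))
        mats.append(_rodrigues(axis, angle))
    return mats


def _activity_segment(
    act: ActivitySignalSpec,
    duration_s: float,
    sample_rate: float,
    variability: float,
    phenotype: PdPhenotype | None,
    rng: np.random.Generator,
) -> np.ndarray:
    if duration_s <= 0:
        raise InvalidSpecError("activity duration must be positive")
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    sig = np.tile(np.asarray(act.baseline_offset, dtype=float), (n, 1))

    # per-subject, per-activity perturbations (drawn even when unused so
    # that healthy/PD cohorts with the same seed share the same stream)
    amp_scale = np.exp(rng.normal(0.0, variability, size=6))
    phases = rng.uniform(0.0, 2 * np.pi, size=(act.harmonic_count, 6))
    tremor_phase = rng.uniform(0.0, 2 * np.pi, size=6)

    if act.fundamental_hz > 0:
        dynamic = np.zeros((n, 6))
        amp = np.asarray(act.per_channel_amplitude, dtype=float) * amp_scale
        for h in range(1, act.harmonic_count + 1):
            dynamic += (amp / h) * np.sin(
                2 * np.pi * h * act.fundamental_hz * t[:, None] + phases[h - 1]
            )
        if phenotype is not None:
            dynamic *= phenotype.gait_attenuation
        sig += dynamic

    if phenotype is not None and phenotype.tremor_amplitude > 0:
        tremor_amp = phenotype.tremor_amplitude * np.array(
            [1.0, 1.0, 1.0, 0.5, 0.5, 0.5]
        )
        sig += tremor_amp * np.sin(
            2 * np.pi * phenotype.tremor_hz * t[:, None] + tremor_phase
        )

    if act.noise_sd > 0:
        sig += rng.normal(0.0, act.noise_sd, size=sig.shape)
    return sig


def generate_recording(spec: CohortSpec, subject_index: int, seed: int) -> Recording:
    """Generate one subject's labeled recording; pure in (spec, subject, seed).

    Activities are emitted as contiguous labeled segments in the order
    they appear in ``spec.activities``, in the dataset's own axis
    convention.
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise InvalidSpecError(
            f"subject_index {subject_index} out of range for {spec.n_subjects} subjects"
        )
    subject_id = spec.subject_id(subject_index)
    rng = np.random.default_rng(derive_seed(seed, subject_id))
    variability = spec.subject_variability
    if spec.pd_phenotype is not None:
        variability *= spec.pd_phenotype.variability_inflation

    # drawn before the activity loop so healthy/PD variants of the same
    # spec and seed consume the stream identically
    mount = _mounting_rotations(spec.mounting_rotation_deg, rng)

    segments, labels = [], []
    for act in spec.activities:
        dur = spec.duration_for(act.activity_name, subject_index)
        seg = _activity_segment(
            act, dur, spec.sample_rate, variability, spec.pd_phenotype, rng
        )
        segments.append(seg)
        labels.extend([act.activity_name] * len(seg))

    samples = np.concatenate(segments)
    if mount is not None:
        for b in range(2):
            blk = samples[:, 3 * b : 3 * b + 3]
            samples[:, 3 * b : 3 * b + 3] = blk @ mount[b].T
    samples = apply_to_array(samples, spec.axis_convention)
    return Recording(
        subject_id=subject_id,
        dataset_name=spec.dataset_name,
        sample_rate=spec.sample_rate,
        samples=samples,
        labels=np.array(labels, dtype=object),
    )


def generate_cohort(spec: CohortSpec, seed: int) -> list[Recording]:
    """One recording per subject, each on its own deterministic sub-stream."""
    return [generate_recording(spec, i, seed) for i in range(spec.n_subjects)]


# --- canonical activity inventory -----------------------------------------
# Baselines encode the gravity direction of typical postures; dynamic
# amplitudes put most of the energy on the ankle for lower-limb activities.

_G = 9.6

ACTIVITY_LIBRARY: dict[str, ActivitySignalSpec] = {
    "standing": ActivitySignalSpec(
        "standing", 0.0, (0.0,) * 6, (0.5, 0.3, _G, 0.2, 0.1, _G), noise_sd=0.12
    ),
    "sitting": ActivitySignalSpec(
        "sitting", 0.0, (0.0,) * 6, (6.5, 1.0, 7.0, 4.8, 0.5, 8.3), noise_sd=0.10
    ),
    "lying": ActivitySignalSpec(
        "lying", 0.0, (0.0,) * 6, (9.3, 1.5, 1.0, 8.8, 0.8, 2.5), noise_sd=0.08
    ),
    "walking": ActivitySignalSpec(
        "walking",
        1.9,
        (1.2, 0.8, 0.6, 2.5, 1.5, 3.0),
        (1.0, 0.5, 9.4, 0.5, 0.3, 9.4),
        harmonic_count=3,
        noise_sd=0.35,
    ),
    "climbing_stairs": ActivitySignalSpec(
        "climbing_stairs",
        1.4,
        (1.0, 1.4, 0.9, 3.5, 2.0, 4.2),
        (1.2, 0.8, 9.2, 0.6, 0.4, 9.3),
        harmonic_count=3,
        noise_sd=0.40,
    ),
    "cycling": ActivitySignalSpec(
        "cycling",
        1.1,
        (0.4, 0.3, 0.3, 4.0, 3.2, 2.2),
        (5.5, 1.2, 7.6, 2.0, 1.0, 9.2),
        harmonic_count=2,
        noise_sd=0.30,
    ),
    "running": ActivitySignalSpec(
        "running",
        2.8,
        (3.5, 2.5, 2.0, 6.0, 4.0, 7.0),
        (1.0, 0.6, 9.2, 0.5, 0.4, 9.2),
        harmonic_count=3,
        noise_sd=0.60,
    ),
}

SEVEN_ACTIVITIES = (
    "standing",
    "sitting",
    "lying",
    "walking",
    "climbing_stairs",
    "cycling",
    "running",
)

#: Dataset axis conventions relative to the canonical frame.
PRESET_CONVENTIONS: dict[str, AxisMapping] = {
    "mhealth-like": IDENTITY_MAPPING,
    "pamap2-like": parse_mapping("wx:wy, wy:-wx, wz:wz, ax:ax, ay:-az, az:ay"),
    "pd-like": parse_mapping("wx:-wx, wy:wz, wz:wy, ax:-ay, ay:ax, az:az"),
}

PRESET_NAMES = ("mhealth-like", "pamap2-like", "pd-like")

# Post-pipeline PD window targets (walking, sitting, standing). With the
# standard pipeline (resample to 50 Hz, 5 s trims, non-overlapping
# 150-sample windows), a run of duration 11 + 3k seconds yields exactly
# k windows with a 1 s safety margin against resampling edge effects.
PD_WINDOW_COUNTS = {"walking": 654, "sitting": 2843, "standing": 3042}


def _pd_durations(total_windows: int, n_subjects: int) -> list[float]:
    base, extra = divmod(total_windows, n_subjects)
    counts = [base + 1] * extra + [base] * (n_subjects - extra)
    return [11.0 + 3.0 * k for k in counts]


def preset(name: str, n_subjects: int | None = None, duration_scale: float = 1.0) -> CohortSpec:
    """Build one of the named cohort presets.

    ``n_subjects``/``duration_scale`` allow scaled-down variants for quick
    experiments; the defaults are the full-size cohorts. Scaling is not
    applied to the pd-like preset's window-count calibration when
    ``duration_scale`` is 1.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    if name == "mhealth-like":
        n = n_subjects or 10
        acts = tuple(ACTIVITY_LIBRARY[a] for a in SEVEN_ACTIVITIES)
        durations = {a: 60.0 * duration_scale for a in SEVEN_ACTIVITIES}
        return CohortSpec(
            dataset_name="mhealth-like",
            n_subjects=n,
            sample_rate=50.0,
            activities=acts,
            per_activity_duration_s=durations,
            axis_convention=PRESET_CONVENTIONS[name],
            mounting_rotation_deg=10.0,
        )
    if name == "pamap2-like":
        n = n_subjects or 8
        acts = tuple(ACTIVITY_LIBRARY[a] for a in SEVEN_ACTIVITIES)
        durations = {a: 168.0 * duration_scale for a in SEVEN_ACTIVITIES}
        return CohortSpec(
            dataset_name="pamap2-like",
            n_subjects=n,
            sample_rate=100.0,
            activities=acts,
            per_activity_duration_s=durations,
            axis_convention=PRESET_CONVENTIONS[name],
            mounting_rotation_deg=10.0,
        )

    n = n_subjects or 14
    acts = tuple(ACTIVITY_LIBRARY[a] for a in ("walking", "sitting", "standing"))
    durations = {}
    for act, total in PD_WINDOW_COUNTS.items():
        scaled_total = max(n, int(round(total * duration_scale)))
        durations[act] = _pd_durations(scaled_total, n)
    return CohortSpec(
        dataset_name="pd-like",
        n_subjects=n,
        sample_rate=128.0,
        activities=acts,
        per_activity_duration_s=durations,
        axis_convention=PRESET_CONVENTIONS[name],
        mounting_rotation_deg=25.0,
        pd_phenotype=PdPhenotype(),
    )
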