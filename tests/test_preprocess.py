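"""IO dialects and the five-stage preparation pipeline."""

import warnings

import numpy as np
import pytest

from harshift.data import CHANNELS, NULL_LABEL, Recording, WindowSet
from harshift.io import read_recording, write_recording
from harshift.preprocess import (
    PD_ACTIVITY_MAP,
    ActivityMap,
    apply_normalizer,
    convert_units,
    drop_invalid,
    fit_normalizer,
    map_activities,
    preprocess_recordings,
    resample_to,
    segment_windows,
    trim_transients,
)
from harshift.synthetic import generate_cohort, generate_recording, preset


def _toy_recording(n=100, rate=50.0, label="walking", null_every=None):
    rng = np.random.default_rng(0)
    samples = rng.normal(size=(n, 6))
    labels = np.array([label] * n, dtype=object)
    if null_every:
        labels[::null_every] = NULL_LABEL
    return Recording("s1", "toy", rate, samples, labels)


# --- io -------------------------------------------------------------------


def test_repo_tsv_roundtrip(tmp_path):
    rec = _toy_recording(100)
    path = tmp_path / "s1.tsv"
    write_recording(rec, path)
    back = read_recording(path)
    assert len(back) == 100
    assert back.sample_rate == 50.0
    np.testing.assert_allclose(back.samples, rec.samples, atol=1e-5)
    assert list(back.labels) == list(rec.labels)


def test_unknown_dialect_rejected(tmp_path):
    with pytest.raises(ValueError):
        read_recording(tmp_path / "x.csv", dialect="opportunity")


def test_pamap2_dat_missing_values_marked(tmp_path):
    # minimal space-separated fixture in the 54-column PAMAP2 layout
    rng = np.random.default_rng(1)
    rows = []
    for i in range(20):
        row = ["0"] * 54
        row[0] = f"{i / 100:.2f}"
        row[1] = "4"  # a non-null activity id
        for c in (4, 5, 6, 38, 39, 40):
            row[c] = f"{rng.normal():.4f}"
        if i == 7:
            row[4] = "NaN"
        rows.append(" ".join(row))
    path = tmp_path / "subject101.dat"
    path.write_text("\n".join(rows) + "\n")
    rec = read_recording(path, "pamap2-dat", activity_names={4: "walking"})
    assert len(rec) == 20
    assert np.isnan(rec.samples[7, 0])
    assert set(rec.labels) == {"walking"}
    assert len(drop_invalid(rec)) == 19


def test_mhealth_log_reads_wrist_and_ankle_columns(tmp_path):
    rows = []
    for i in range(10):
        row = ["0.0"] * 24
        for c in (14, 15, 16, 5, 6, 7):
            row[c] = str(float(c + i))
        row[23] = "1" if i < 6 else "0"  # 0 = null class
        rows.append("\t".join(row))
    path = tmp_path / "mHealth_subject1.log"
    path.write_text("\n".join(rows) + "\n")
    rec = read_recording(path, "mhealth-log", activity_names={1: "standing"})
    assert rec.sample_rate == 50.0
    assert rec.samples[0, 0] == 14.0 and rec.samples[0, 3] == 5.0
    assert list(rec.labels[:6]) == ["standing"] * 6
    assert list(rec.labels[6:]) == [NULL_LABEL] * 4


# --- drop_invalid ---------------------------------------------------------


def test_drop_invalid_removes_null_class():
    rec = _toy_recording(100, null_every=10)  # 10 null samples
    out = drop_invalid(rec)
    assert len(out) == 90
    assert NULL_LABEL not in set(out.labels)


def test_drop_invalid_is_identity_on_clean_data():
    rec = _toy_recording(50)
    out = drop_invalid(rec)
    np.testing.assert_array_equal(out.samples, rec.samples)


def test_drop_invalid_all_null_gives_empty():
    rec = _toy_recording(10, null_every=1)
    assert len(drop_invalid(rec)) == 0


# --- resampling -----------------------------------------------------------


def test_resample_100hz_halves_length():
    rec = _toy_recording(10_000, rate=100.0)
    out = resample_to(rec, 50.0)
    assert abs(len(out) - 5_000) <= 1
    assert out.sample_rate == 50.0


def test_resample_128hz_length_matches_decimation_oracle():
    # brute-force oracle: output samples are the times j/50 with j/50 < T/128,
    # i.e. ceil(T * 25 / 64) samples
    T = 12_800
    rec = _toy_recording(T, rate=128.0)
    out = resample_to(rec, 50.0)
    oracle = int(np.ceil(T * 25 / 64))
    assert len(out) == oracle == 5_000


def test_resample_identity_at_target_rate():
    rec = _toy_recording(500, rate=50.0)
    assert resample_to(rec, 50.0) is rec


def test_resample_refuses_upsampling():
    with pytest.raises(ValueError):
        resample_to(_toy_recording(100, rate=50.0), 100.0)


def test_resample_preserves_label_runs_approximately():
    rec = _toy_recording(1000, rate=100.0)
    rec.labels[:500] = "sitting"
    rec.labels[500:] = "walking"
    out = resample_to(rec, 50.0)
    sitting = int((out.labels == "sitting").sum())
    assert abs(sitting - 250) <= 1


# --- unit conversion ------------------------------------------------------


def test_convert_units_g_to_ms2():
    rec = _toy_recording(10)
    out = convert_units(rec, "g")
    np.testing.assert_allclose(out.samples, rec.samples * 9.80665)
    # identity for m/s2, including the unicode spelling
    assert convert_units(rec, "m/s²") is rec
    with pytest.raises(ValueError):
        convert_units(rec, "ft/s2")


# --- trimming -------------------------------------------------------------


def test_trim_keeps_50s_of_a_60s_run():
    rec = _toy_recording(3000, rate=50.0)  # one 60 s run
    out = trim_transients(rec, 5.0)
    assert len(out) == 2500


def test_trim_removes_short_runs_entirely():
    rec = _toy_recording(400, rate=50.0)  # 8 s < 2 * 5 s
    assert len(trim_transients(rec, 5.0)) == 0


def test_trim_zero_is_identity():
    rec = _toy_recording(100)
    assert trim_transients(rec, 0.0) is rec


def test_trim_applies_per_run():
    rec = _toy_recording(2000, rate=50.0)
    rec.labels[:1000] = "sitting"
    rec.labels[1000:] = "walking"
    out = trim_transients(rec, 2.0)
    assert len(out) == 2000 - 4 * 100  # 2 s off both ends of both runs


# --- segmentation ---------------------------------------------------------


def test_segment_window_yield_formula():
    rec = _toy_recording(2500)
    ws = segment_windows(rec, length=150, step=150)
    assert len(ws) == 16  # floor((2500 - 150)/150) + 1
    assert ws.window_length == 150


def test_segment_too_short_run_yields_nothing():
    assert len(segment_windows(_toy_recording(149))) == 0


def test_segment_overlapping_step_matches_enumeration_oracle():
    rec = _toy_recording(300)
    ws = segment_windows(rec, length=150, step=75)
    oracle = len([s for s in range(0, 300 - 150 + 1, 75)])
    assert len(ws) == oracle == 3


def test_segment_never_spans_two_labels():
    rec = _toy_recording(450)
    rec.labels[:200] = "sitting"
    rec.labels[200:] = "walking"
    ws = segment_windows(rec)
    # runs of 200 and 250 -> 1 + 1 windows, none mixed
    assert len(ws) == 2
    assert sorted(ws.labels) == ["sitting", "walking"]


def test_segment_requires_50hz():
    with pytest.raises(ValueError):
        segment_windows(_toy_recording(300, rate=100.0))


# --- activity mapping -----------------------------------------------------


def test_pd_activity_map_printed_entries(random_ws):
    assert PD_ACTIVITY_MAP("ambulation") == "walking"
    assert PD_ACTIVITY_MAP("drinking") == "sitting"
    assert PD_ACTIVITY_MAP("cutting") == "sitting"
    assert PD_ACTIVITY_MAP("dressing") == "standing"


def test_map_activities_identity(random_ws):
    identity = ActivityMap({l: l for l in set(random_ws.labels)})
    out = map_activities(random_ws, identity)
    np.testing.assert_array_equal(out.labels, random_ws.labels)


def test_map_activities_drops_and_errors(random_ws):
    amap = ActivityMap({"walking": "walking", "sitting": "sitting"}, drop={"standing"})
    out = map_activities(random_ws, amap)
    assert "standing" not in set(out.labels)
    with pytest.raises(KeyError):
        map_activities(random_ws, ActivityMap({"walking": "walking"}))


# --- normalization --------------------------------------------------------


def test_normalizer_zscores_its_own_training_set(random_ws):
    stats = fit_normalizer(random_ws)
    out = apply_normalizer(random_ws, stats)
    flat = out.windows.reshape(-1, 6)
    np.testing.assert_allclose(flat.mean(axis=0), 0.0, atol=1e-6)
    np.testing.assert_allclose(flat.std(axis=0), 1.0, atol=1e-6)


def test_normalizer_clamps_constant_channel(random_ws):
    ws = WindowSet(
        random_ws.windows.copy(), random_ws.labels, random_ws.subject_ids, "c"
    )
    ws.windows[:, :, 2] = 4.2
    with pytest.warns(RuntimeWarning):
        stats = fit_normalizer(ws)
    out = apply_normalizer(ws, stats)
    np.testing.assert_allclose(out.windows[:, :, 2], 0.0, atol=1e-4)


def test_source_stats_do_not_center_a_shifted_target(random_ws):
    stats = fit_normalizer(random_ws)
    shifted = WindowSet(
        random_ws.windows + 3.0, random_ws.labels, random_ws.subject_ids, "shifted"
    )
    out = apply_normalizer(shifted, stats)
    assert np.all(np.abs(out.windows.reshape(-1, 6).mean(axis=0)) > 1.0)


# --- full pipeline --------------------------------------------------------


def test_pipeline_is_bit_identical_on_reruns():
    recs = generate_cohort(preset("pd-like", n_subjects=2, duration_scale=0.01), seed=9)
    a = preprocess_recordings(recs)
    b = preprocess_recordings(recs)
    np.testing.assert_array_equal(a.windows, b.windows)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_pipeline_count_conservation():
    """Total windows equal the sum of the per-run yield formula."""
    spec = preset("mhealth-like", n_subjects=2, duration_scale=0.5)
    recs = generate_cohort(spec, seed=2)
    ws = preprocess_recordings(recs)
    expected = 0
    for rec in recs:
        # 30 s runs at 50 Hz -> 5 s trims leave 1000 samples -> 6 windows
        expected += 7 * (int((30 - 10) * 50 - 150) // 150 + 1)
    assert len(ws) == expected
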