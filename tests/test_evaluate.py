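"""LOSO folds, cross-testing and binarized one-vs-rest metrics."""

import numpy as np
import pytest

from harshift.data import WindowSet
from harshift.evaluate import (
    binarize,
    binary_metrics_avg,
    cross_test,
    loso_folds,
    run_cv,
)
from harshift.models import TrainConfig
from harshift.preprocess import apply_normalizer


def _ws_with_subjects(n_subjects, per_subject=3):
    n = n_subjects * per_subject
    return WindowSet(
        np.zeros((n, 150, 6)),
        np.array(["walking"] * n, dtype=object),
        np.array([f"s{i // per_subject:02d}" for i in range(n)], dtype=object),
    )


@pytest.mark.parametrize("n_subjects", [2, 8, 10])
def test_loso_fold_count_and_partition(n_subjects):
    ws = _ws_with_subjects(n_subjects)
    plan = loso_folds(ws, seed=0)
    assert len(plan) == n_subjects
    held_out = {f.test_subject for f in plan}
    assert held_out == set(ws.subjects)
    for f in plan:
        assert f.test_subject not in f.train_subjects
        assert f.test_subject not in f.tune_subjects
        assert not set(f.train_subjects) & set(f.tune_subjects)
        assert set(f.train_subjects) | set(f.tune_subjects) | {f.test_subject} == set(ws.subjects)


def test_loso_inner_split_is_80_20():
    plan = loso_folds(_ws_with_subjects(11), seed=1)
    for f in plan:
        assert len(f.tune_subjects) == 2  # 20% of the 10 remaining subjects
        assert len(f.train_subjects) == 8


def test_loso_requires_two_subjects():
    with pytest.raises(ValueError):
        loso_folds(_ws_with_subjects(1))


def test_binarize_contracts():
    y = np.array(["cycling", "running", "walking"], dtype=object)
    np.testing.assert_array_equal(binarize(y, "walking"), [0, 0, 1])
    np.testing.assert_array_equal(binarize(y, "sitting"), [0, 0, 0])
    b = binarize(y, "walking")
    np.testing.assert_array_equal(binarize(b, 1), b)  # idempotent on binary


@pytest.mark.parametrize(
    "counts", [(654, 2843, 3042), (10, 10, 10), (1, 5, 94)]
)
def test_foreign_predictions_give_two_thirds_baseline(counts):
    """Predictions confined to outside classes -> avg binary accuracy exactly
    2/3 and avg F1 exactly 0, for any class proportions."""
    y_true = np.array(
        ["walking"] * counts[0] + ["sitting"] * counts[1] + ["standing"] * counts[2],
        dtype=object,
    )
    y_pred = np.array(["cycling", "running"] * (len(y_true) // 2 + 1), dtype=object)[: len(y_true)]
    avg_acc, per_act, avg_f1 = binary_metrics_avg(y_true, y_pred)
    assert avg_acc == pytest.approx(100 * 2 / 3, abs=1e-9)
    assert avg_f1 == 0.0


def test_perfect_predictions_score_100():
    y = np.array(["walking", "sitting", "standing"] * 5, dtype=object)
    avg_acc, _, avg_f1 = binary_metrics_avg(y, y.copy())
    assert avg_acc == 100.0
    assert avg_f1 == 100.0


def test_all_standing_predictions_match_contingency_oracle():
    """Hand-built confusion-table arithmetic on the printed PD class counts."""
    nw, nsi, nst = 654, 2843, 3042
    total = nw + nsi + nst
    y_true = np.array(["walking"] * nw + ["sitting"] * nsi + ["standing"] * nst, dtype=object)
    y_pred = np.array(["standing"] * total, dtype=object)
    avg_acc, per_act, avg_f1 = binary_metrics_avg(y_true, y_pred)
    # oracle: walking one-vs-rest -> TP=0 FP=0 FN=654 TN=5885
    acc_w = 100 * (total - nw) / total
    # sitting -> TP=0 FP=0 FN=2843
    acc_si = 100 * (total - nsi) / total
    # standing -> TP=3042 FP=3497 FN=0 TN=0
    acc_st = 100 * nst / total
    f1_st = 100 * 2 * nst / (2 * nst + (total - nst))
    assert avg_acc == pytest.approx((acc_w + acc_si + acc_st) / 3, abs=1e-9)
    assert per_act["standing"]["binary_f1"] == pytest.approx(f1_st, abs=1e-9)
    assert avg_f1 == pytest.approx(f1_st / 3, abs=1e-9)


def test_binary_metrics_rejects_bad_input():
    with pytest.raises(ValueError):
        binary_metrics_avg([], [])
    with pytest.raises(ValueError):
        binary_metrics_avg(["cycling"], ["walking"])


# --- cross-validation and cross-testing (small but real training runs) ----


@pytest.fixture(scope="module")
def cv_result(easy_cohort_ws):
    return run_cv(easy_cohort_ws, train_cfg=TrainConfig(epochs=30), seed=3)


def test_cv_reports_one_row_per_subject(easy_cohort_ws, cv_result):
    assert len(cv_result.result.per_fold) == len(easy_cohort_ws.subjects)
    assert set(cv_result.result.per_fold["test_subject"]) == set(easy_cohort_ws.subjects)


def test_cv_best_model_is_argmax(cv_result):
    per_fold = cv_result.result.per_fold
    best = per_fold.loc[per_fold["accuracy"].idxmax()]
    assert cv_result.best_fold == best["test_subject"]


def test_cv_confusion_marginals_match_label_counts(easy_cohort_ws, cv_result):
    cm = cv_result.result.confusion
    for act in easy_cohort_ws.activities:
        assert cm.loc[act].sum() == (easy_cohort_ws.labels == act).sum()
    # accuracy recomputed from the pooled matrix equals the pooled rate
    pooled_acc = 100 * np.trace(cm.to_numpy()) / cm.to_numpy().sum()
    per_fold = cv_result.result.per_fold
    recomputed = 100 * (per_fold["accuracy"] / 100 * per_fold["n_test"]).sum() / per_fold["n_test"].sum()
    assert pooled_acc == pytest.approx(recomputed, abs=1e-9)


def test_cross_test_on_identical_target_is_self_consistent(easy_cohort_ws, cv_result):
    res = cross_test(cv_result.best_model, cv_result.best_stats, easy_cohort_ws)
    direct = cv_result.best_model.predict(
        apply_normalizer(easy_cohort_ws, cv_result.best_stats)
    )
    assert res.accuracy == pytest.approx(100 * (direct == easy_cohort_ws.labels).mean())


def test_cross_test_rejects_unknown_target_labels(cv_result, random_ws):
    alien = WindowSet(
        random_ws.windows,
        np.array(["swimming"] * len(random_ws), dtype=object),
        random_ws.subject_ids,
    )
    with pytest.raises(ValueError):
        cross_test(cv_result.best_model, cv_result.best_stats, alien)


def test_cross_test_binarizes_subset_targets(easy_cohort_ws, cv_result):
    mask = np.isin(easy_cohort_ws.labels, ["walking", "standing"])
    sub = easy_cohort_ws.subset(mask)
    res = cross_test(
        cv_result.best_model,
        cv_result.best_stats,
        sub,
        binarize_activities=("walking", "standing"),
    )
    assert res.kind == "cross-test-binarized"
    assert res.avg_binary_accuracy is not None
    assert set(res.per_activity) == {"walking", "standing"}
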