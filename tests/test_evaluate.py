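"""LOOCV harness, monotone calibration and the six evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.svm import SVC

from brainmorph import (
    FeatureMatrix,
    SvmConfig,
    calibrate_scores,
    compute_metrics,
    loocv_predict,
    make_labels,
    run_task,
)
from brainmorph.evaluate import EvalError


# --------------------------------------------------------------------------
# LOOCV
# --------------------------------------------------------------------------


def test_loocv_separable_features_recover_signs():
    X = np.array([[-1.0]] * 5 + [[1.0]] * 5)
    y = np.array([0] * 5 + [1] * 5)
    scores = loocv_predict(X, y)
    assert scores.shape == (10,)
    assert (np.sign(scores) == np.where(y == 1, 1, -1)).all()


def test_loocv_returns_one_score_per_subject():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(9, 4))
    y = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0])
    assert loocv_predict(X, y).shape == (9,)


@pytest.mark.parametrize("normalize", ["none", "zscore"])
def test_loocv_matches_bruteforce_fold_loop(normalize):
    """Held-out scores equal an independent per-fold refit loop."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(6, 3)) + np.array([0, 1, 0, 1, 0, 1])[:, None]
    y = np.array([0, 1, 0, 1, 0, 1])
    scores = loocv_predict(X, y, SvmConfig(normalize=normalize))
    for i in range(6):
        train = [j for j in range(6) if j != i]
        Xtr, Xte = X[train], X[i : i + 1]
        if normalize == "zscore":
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        clf = SVC(kernel="linear", C=1.0).fit(Xtr, y[train])
        assert scores[i] == pytest.approx(float(clf.decision_function(Xte)[0]), abs=1e-9)


def test_loocv_single_class_fold_raises_with_fold_index():
    X = np.array([[0.0], [1.0], [2.0]])
    y = np.array([1, 0, 0])
    with pytest.raises(EvalError, match="fold 0"):
        loocv_predict(X, y)


def test_loocv_requires_both_classes_and_min_n():
    with pytest.raises(EvalError):
        loocv_predict(np.zeros((5, 2)), np.zeros(5, dtype=int))
    with pytest.raises(EvalError):
        loocv_predict(np.zeros((2, 2)), np.array([0, 1]))


def test_invalid_svm_config_rejected():
    with pytest.raises(EvalError, match="C"):
        SvmConfig(C=-1).validate()
    with pytest.raises(EvalError):
        SvmConfig(kernel="rbf").validate()


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------


def test_calibration_affine_example():
    np.testing.assert_allclose(
        calibrate_scores(np.array([-2.0, 0.0, 2.0])), [0.0, 0.5, 1.0]
    )


def test_calibration_identical_scores_rejected():
    with pytest.raises(EvalError, match="identical"):
        calibrate_scores(np.array([1.0, 1.0, 1.0]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.integers(min_value=-10_000, max_value=10_000),
        min_size=2,
        max_size=30,
        unique=True,
    )
)
def test_calibration_strictly_preserves_order(raw):
    # integer lattice keeps score gaps representable after affine rescaling
    raw = np.array(raw, dtype=float) / 7.0
    cal = calibrate_scores(raw)
    assert cal.min() == 0.0 and cal.max() == 1.0
    order = np.argsort(raw)
    assert np.all(np.diff(cal[order]) > 0)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


def test_perfect_scores_give_unit_metrics():
    y = np.array([0, 0, 1, 1, 1])
    scores = np.where(y == 1, 2.0, -2.0)
    rep = compute_metrics(scores, y)
    assert (rep.acc, rep.sen, rep.spe, rep.f1s, rep.auc) == (1, 1, 1, 1, 1)
    assert rep.roc[0] == (0.0, 0.0) and rep.roc[-1] == (1.0, 1.0)


def test_label_reversed_perfect_scores_give_auc_zero():
    y = np.array([0, 0, 1, 1])
    rep = compute_metrics(np.where(y == 1, -2.0, 2.0), y)
    assert rep.auc == 0.0


def test_auc_equals_mann_whitney_pair_count():
    y = np.array([1, 1, 0, 0])
    scores = np.array([0.9, 0.4, 0.6, 0.1])
    rep = compute_metrics(scores, y, threshold=0.5)
    # pair-count oracle with half credit for ties
    pos, neg = scores[y == 1], scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert rep.auc == pytest.approx(wins / (len(pos) * len(neg)))
    assert rep.auc == pytest.approx(0.75)


def test_confusion_identities_and_roc_monotone():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, size=40)
    y[:2] = [0, 1]
    scores = rng.normal(size=40) + y
    rep = compute_metrics(scores, y)
    n = len(y)
    assert rep.tp + rep.fp + rep.tn + rep.fn == n
    assert rep.acc == pytest.approx((rep.tp + rep.tn) / n)
    assert rep.sen == pytest.approx(rep.tp / (rep.tp + rep.fn))
    assert rep.spe == pytest.approx(rep.tn / (rep.tn + rep.fp))
    assert rep.f1s == pytest.approx(2 * rep.tp / (2 * rep.tp + rep.fp + rep.fn))
    misclass = np.sum((scores >= 0).astype(int) != y)
    assert rep.acc == pytest.approx(1 - misclass / n)
    fpr = np.array([p[0] for p in rep.roc])
    tpr = np.array([p[1] for p in rep.roc])
    assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


def test_metrics_require_both_classes():
    with pytest.raises(EvalError):
        compute_metrics(np.array([0.1, 0.2]), np.array([1, 1]))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    st.integers(min_value=0, max_value=2**31 - 1),
    st.floats(min_value=0.1, max_value=5.0),
    st.floats(min_value=0.0, max_value=2.0),
)
def test_auc_invariant_under_monotone_transforms(seed, a, b):
    """AUC depends only on score ranks, so any strictly increasing map preserves it."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 30))
    y = rng.integers(0, 2, size=n)
    y[:2] = [0, 1]
    scores = rng.normal(size=n)
    transformed = a * scores + b * scores**3 + 0.5 * np.arctan(scores)
    auc_raw = compute_metrics(scores, y).auc
    auc_t = compute_metrics(transformed, y).auc
    assert auc_t == pytest.approx(auc_raw, abs=1e-12)


def test_calibration_changes_no_metric():
    """Calibrated scores with the mapped threshold reproduce every metric."""
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, size=30)
    y[:2] = [0, 1]
    scores = rng.normal(size=30)
    rep_raw = compute_metrics(scores, y, threshold=0.0)
    cal = calibrate_scores(scores)
    thr = (0.0 - scores.min()) / (scores.max() - scores.min())
    rep_cal = compute_metrics(cal, y, threshold=thr)
    assert (rep_cal.tp, rep_cal.fp, rep_cal.tn, rep_cal.fn) == (
        rep_raw.tp,
        rep_raw.fp,
        rep_raw.tn,
        rep_raw.fn,
    )
    for key, value in rep_raw.metrics().items():
        assert rep_cal.metrics()[key] == pytest.approx(value, abs=1e-12)


# --------------------------------------------------------------------------
# task assembly
# --------------------------------------------------------------------------


def _toy_table_and_features(n=12, seed=4):
    import pandas as pd

    rng = np.random.default_rng(seed)
    diag = ["T2DM"] * (n // 2) + ["NT"] * (n - n // 2)
    cog = (["CI", "NC"] * n)[:n]
    table = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "diagnosis": diag,
            "cognition": cog,
        }
    )
    X = rng.normal(size=(n, 3)) + 2.0 * (np.array(diag) == "T2DM")[:, None]
    fm = FeatureMatrix(X, [f"s{i}" for i in range(n)], "VOR")
    return table, fm


def test_make_labels_positive_class_is_clinical():
    table, _ = _toy_table_and_features()
    labels, df = make_labels(table, "T2DM_vs_NT")
    assert labels.y.sum() == 6
    assert (df.loc[labels.y == 1, "diagnosis"] == "T2DM").all()
    labels_ci, _ = make_labels(table, "CI_vs_NC")
    assert labels_ci.y.sum() == 6


def test_run_task_reports_and_subgroup_filtering():
    table, fm = _toy_table_and_features()
    rep = run_task(fm, table, "T2DM_vs_NT")
    assert rep.n == 12 and rep.auc > 0.9  # planted 2-sigma shift is separable
    rep_ci = run_task(fm, table, "T2DM_vs_NT", subgroup="ci_only")
    assert rep_ci.n == 6
    assert rep_ci.subgroup == "ci_only"


def test_run_task_rejects_unknown_task_and_empty_subgroup():
    table, fm = _toy_table_and_features()
    with pytest.raises(EvalError):
        run_task(fm, table, "bogus")
    table_nc = table[table["cognition"] == "NC"].reset_index(drop=True)
    fm_nc = FeatureMatrix(
        fm.values[table["cognition"].to_numpy() == "NC"],
        [s for s, c in zip(fm.subject_ids, table["cognition"]) if c == "NC"],
        "VOR",
    )
    with pytest.raises(EvalError):
        run_task(fm_nc, table_nc, "T2DM_vs_NT", subgroup="ci_only")
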