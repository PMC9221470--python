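"""CV engine, AUC, bootstrap CI and model comparison."""

import numpy as np
import pandas as pd
import pytest

from melrad import (
    AUCSummary,
    CVScheme,
    PredictionSet,
    bootstrap_auc_ci,
    bootstrap_indices,
    build_endpoints,
    clinical_feature_frame,
    compare_models,
    mean_roc,
    pooled_auc,
    run_repeated_cv,
    train_model,
)
from melrad.evaluate import predict_scores


def brute_force_auc(scores, labels):
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# pooled AUC
# ---------------------------------------------------------------------------


def test_worked_auc_example():
    assert pooled_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_tie_and_perfect_conventions():
    assert pooled_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)
    assert pooled_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)


def test_single_class_rejected():
    with pytest.raises(ValueError):
        pooled_auc([0.1, 0.2], [1, 1])


@pytest.mark.parametrize("trial", range(30))
def test_auc_matches_pair_counting(trial):
    rng = np.random.default_rng(trial)
    n = rng.integers(10, 60)
    scores = rng.integers(0, 8, n) / 8.0  # discrete scores force ties
    labels = rng.integers(0, 2, n)
    if len(np.unique(labels)) < 2:
        labels[0], labels[1] = 0, 1
    assert pooled_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------


def test_separable_toy_problem(rng):
    X = np.vstack([rng.normal(-2, 0.1, (20, 2)), rng.normal(2, 0.1, (20, 2))])
    y = np.repeat([0, 1], 20)
    clf = train_model(X, y, seed=0)
    assert pooled_auc(predict_scores(clf, X), y) == 1.0


def test_forest_seeded_determinism(rng):
    X = rng.standard_normal((40, 3))
    y = rng.integers(0, 2, 40)
    y[:2] = [0, 1]
    s1 = predict_scores(train_model(X, y, seed=5), X)
    s2 = predict_scores(train_model(X, y, seed=5), X)
    np.testing.assert_array_equal(s1, s2)


def test_single_class_training_rejected(rng):
    with pytest.raises(ValueError, match="single class"):
        train_model(rng.standard_normal((10, 2)), np.ones(10), seed=0)


# ---------------------------------------------------------------------------
# repeated CV bookkeeping
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def cv_result(small_cohort):
    records, _, _ = small_cohort
    clinical = clinical_feature_frame(records)
    labels = build_endpoints(records)["surv_6mo"]
    scheme = CVScheme(repetitions=3, folds=5, seed=0)
    rng = np.random.default_rng(0)
    radiomic = pd.DataFrame(
        rng.standard_normal((len(clinical), 12)),
        index=clinical.index,
        columns=[f"r{j}" for j in range(12)],
    )
    return run_repeated_cv(clinical, radiomic, labels, scheme), labels


def test_every_patient_scored_once_per_repetition(cv_result):
    res, labels = cv_result
    for ps in (res.baseline, res.extended):
        assert ps.scores.shape == (3, len(labels))
        assert np.isfinite(ps.scores).all()
        assert ((ps.scores >= 0) & (ps.scores <= 1)).all()


def test_folds_partition_included_cohort(cv_result):
    res, labels = cv_result
    n = len(labels)
    for r in range(res.fold_assignments.shape[0]):
        assert sorted(np.unique(res.fold_assignments[r])) == list(range(5))
        assert res.fold_assignments.shape[1] == n


def test_models_share_folds_and_logs_recorded(cv_result):
    res, _ = cv_result
    assert res.selection_logs  # FCBF ran per fold
    assert {(l["repetition"], l["fold"]) for l in res.selection_logs} == {
        (r, k) for r in range(3) for k in range(5)
    }


# ---------------------------------------------------------------------------
# bootstrap CI
# ---------------------------------------------------------------------------


def _prediction_set(rng, n=80, reps=4, auc_signal=1.0):
    y = rng.integers(0, 2, n)
    y[:2] = [0, 1]
    scores = np.clip(
        0.5 + auc_signal * 0.2 * (y - 0.5) + 0.2 * rng.standard_normal((reps, n)), 0, 1
    )
    return PredictionSet("surv_6mo", "baseline", np.arange(n), y, scores)


def test_bootstrap_ci_reproducible(rng):
    ps = _prediction_set(rng)
    a = bootstrap_auc_ci(ps, B=200, seed=3)
    b = bootstrap_auc_ci(ps, B=200, seed=3)
    assert (a.ci_low, a.ci_high, a.point) == (b.ci_low, b.ci_high, b.point)
    assert a.ci_low <= a.point <= a.ci_high


def test_identical_repetitions_collapse(rng):
    ps = _prediction_set(rng, reps=1)
    rep = PredictionSet(ps.endpoint, ps.model, ps.patient_ids, ps.labels,
                        np.repeat(ps.scores, 5, axis=0))
    idx = bootstrap_indices(ps.labels.size, 200, seed=9)
    a = bootstrap_auc_ci(ps, indices=idx, seed=9)
    b = bootstrap_auc_ci(rep, indices=idx, seed=9)
    assert a.ci_low == pytest.approx(b.ci_low)
    assert a.ci_high == pytest.approx(b.ci_high)


def test_ci_width_shrinks_with_n():
    widths = []
    for n in (100, 400, 1600):
        rng = np.random.default_rng(n)
        ps = _prediction_set(rng, n=n, reps=3)
        s = bootstrap_auc_ci(ps, B=300, seed=1)
        widths.append(s.ci_high - s.ci_low)
    assert widths[0] > widths[1] > widths[2]
    assert widths[0] / widths[2] > 2.0  # ~ 1/sqrt(16) scaling, generous slack


# ---------------------------------------------------------------------------
# ROC and comparisons
# ---------------------------------------------------------------------------


def test_mean_roc_shapes_and_monotonicity(rng):
    ps = _prediction_set(rng)
    roc = mean_roc(ps, B=100, seed=2)
    assert roc.fpr.shape == roc.tpr_mean.shape == (101,)
    assert np.all(np.diff(roc.tpr_mean) >= -1e-12)
    assert roc.tpr_mean[-1] == pytest.approx(1.0)


def test_perfect_classifier_roc(rng):
    y = np.repeat([0, 1], 30)
    scores = np.tile(y.astype(float), (3, 1))
    ps = PredictionSet("e", "m", np.arange(60), y, scores)
    roc = mean_roc(ps, B=100, seed=0)
    assert np.all(roc.tpr_mean[1:] > 0.99)


def test_random_scores_roc_near_diagonal(rng):
    y = rng.integers(0, 2, 300)
    y[:2] = [0, 1]
    ps = PredictionSet("e", "m", np.arange(300), y, rng.random((5, 300)))
    roc = mean_roc(ps, B=100, seed=0)
    assert np.abs(roc.tpr_mean - roc.fpr).max() < 0.12
    assert np.all(roc.tpr_low <= roc.tpr_high)


def _summary(lo, hi, model="baseline", endpoint="surv_6mo"):
    return AUCSummary(endpoint, model, (lo + hi) / 2, lo, hi, 1000, 100)


def test_ci_overlap_rules():
    r = compare_models(_summary(0.55, 0.65), _summary(0.70, 0.80, "extended"))
    assert r["significantly_different"]
    assert r["baseline_predictive"] and r["extended_predictive"]
    # published-style survival CIs: overlapping, both predictive
    r = compare_models(_summary(0.545, 0.692), _summary(0.598, 0.729, "extended"))
    assert not r["significantly_different"]
    assert r["baseline_predictive"] and r["extended_predictive"]
    # lower bound below chance: not predictive
    assert not _summary(0.481, 0.629).predictive


def test_compare_requires_same_endpoint():
    with pytest.raises(ValueError):
        compare_models(_summary(0.5, 0.6), _summary(0.5, 0.6, "extended", "surv_12mo"))
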