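"""Diagnosis-specific base learner: RFE ranking oracles, LOOCV
behaviour, leakage guard, prediction closed forms, serialization."""

import numpy as np
import pandas as pd
import pytest

from pdacstack._glm import sigmoid
from pdacstack.base_learner import (
    DiagnosisSpecificClassifier,
    predict_base,
    rfe_rank,
    train_base_learner,
)
from pdacstack.cohort import assign_split
from pdacstack.evaluation import roc_auc
from pdacstack.simulate import PDAC, generate_cohort

from conftest import small_config


def test_rfe_top_feature_is_the_informative_one():
    """y depends only on one feature among 10: it is last-removed."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(120, 10))
    y = (rng.uniform(size=120) < sigmoid(3 * X[:, 4])).astype(int)
    Z = (X - X.mean(0)) / X.std(0)
    order, per_size = rfe_rank(Z, y, [f"f{i}" for i in range(10)])
    assert order[-1] == "f4"
    feats1, beta1 = per_size[1]
    assert feats1 == ["f4"]


def test_rfe_duplicate_features_tie_broken_by_name():
    rng = np.random.default_rng(1)
    x = rng.normal(size=80)
    y = (rng.uniform(size=80) < sigmoid(2 * x)).astype(int)
    Z = np.column_stack([x, x, rng.normal(size=80)])
    Z = (Z - Z.mean(0)) / Z.std(0)
    order, _ = rfe_rank(Z, y, ["dup_b", "dup_a", "noise"])
    # identical columns split the coefficient: one goes early, and the
    # lexicographically earlier name survives longer
    assert order[-1] == "dup_a"
    assert "dup_b" in order[:2]


def test_rfe_deterministic():
    rng = np.random.default_rng(2)
    Z = rng.normal(size=(40, 6))
    y = np.r_[np.zeros(20, int), np.ones(20, int)]
    a, _ = rfe_rank(Z, y)
    b, _ = rfe_rank(Z, y)
    assert a == b


def test_noise_features_size_one_matches_max_t(null_xy):
    """With pure noise and a single-feature final model, RFE picks the
    feature with the largest |t| most of the time."""
    from scipy import stats

    agree = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(150, 6))
        y = np.r_[np.zeros(75, int), np.ones(75, int)]
        Z = (X - X.mean(0)) / X.std(0)
        order, per_size = rfe_rank(Z, y)
        tvals = [
            abs(stats.ttest_ind(Z[y == 1, j], Z[y == 0, j]).statistic)
            for j in range(6)
        ]
        agree += per_size[1][0][0] == f"x{int(np.argmax(tvals))}"
    assert agree >= int(0.9 * n_seeds) - 1


def test_single_candidate_feature(tiny_cohort):
    split = assign_split(tiny_cohort, seed=0)
    disc = split.discovery(tiny_cohort)
    learner = train_base_learner(disc, "Gallstone Disease", ["CA19-9"], seed=0)
    assert learner.selected_features_ == ["CA19-9"]
    assert len(learner.cv_profile_) == 1
    assert learner.coef_.shape == (1,)


def test_planted_class_specific_features_recovered():
    """Controls of one class differ from PDAC only in two markers
    (delta = 2): both enter the selected set."""
    panel = [f"M{i}" for i in range(6)]
    cfg = small_config(
        ["Chronic Pancreatitis"],
        30,
        24,
        panel,
        effect_map={("M0", PDAC): 2.0, ("M1", PDAC): 2.0},
    )
    hits = 0
    for seed in range(5):
        coh = generate_cohort(cfg, seed=seed)
        learner = train_base_learner(
            coh, "Chronic Pancreatitis", panel, seed=seed, subset_sizes=[1, 2, 3]
        )
        hits += {"M0", "M1"} <= set(learner.selected_features_)
    assert hits >= 4


def test_predict_closed_form_and_monotonicity(tiny_cohort):
    split = assign_split(tiny_cohort, seed=0)
    disc = split.discovery(tiny_cohort)
    learner = train_base_learner(
        disc, "Chronic Pancreatitis", ["CA19-9", "M1"], seed=1, subset_sizes=[1, 2]
    )
    # a sample at the training-feature means scores logistic(intercept)
    at_means = pd.DataFrame([learner.mean_], columns=learner.selected_features_)
    p = learner.predict_proba(at_means)[0, 1]
    assert p == pytest.approx(sigmoid(learner.intercept_), abs=1e-12)
    # adding an unused column changes nothing
    with_extra = disc.feature_frame(learner.selected_features_).copy()
    base = learner.predict_proba(with_extra)[:, 1]
    with_extra["unused"] = 99.0
    assert np.array_equal(learner.predict_proba(with_extra)[:, 1], base)
    # monotone in a positive-coefficient feature
    j = int(np.argmax(np.abs(learner.coef_)))
    feat = learner.selected_features_[j]
    probe = pd.DataFrame([learner.mean_], columns=learner.selected_features_)
    lo = learner.predict_proba(probe)[0, 1]
    probe[feat] += 1.0
    hi = learner.predict_proba(probe)[0, 1]
    assert (hi > lo) == (learner.coef_[j] > 0)


def test_missing_feature_column_named(tiny_cohort):
    learner = train_base_learner(tiny_cohort, "Healthy", ["CA19-9", "M1"], seed=0,
                                 subset_sizes=[1, 2])
    bad = tiny_cohort.feature_frame(["M2"])
    with pytest.raises(KeyError, match="CA19-9|M1"):
        learner.predict_proba(bad)


def test_errors_on_absent_or_tiny_class(tiny_cohort):
    with pytest.raises(ValueError, match="absent"):
        train_base_learner(tiny_cohort, "IgG4 Disease", ["M1"], seed=0)
    healthy_ids = tiny_cohort.data.loc[
        tiny_cohort.data["diagnosis_class"] == "Healthy", "sample_id"
    ].iloc[:2]
    few = tiny_cohort.subset(
        (
            (tiny_cohort.data["label"] == "case")
            | tiny_cohort.data["sample_id"].isin(healthy_ids)
        ).to_numpy()
    )
    with pytest.raises(ValueError, match="fewer than 3"):
        train_base_learner(few, "Healthy", ["M1"], seed=0)


def test_determinism_and_serialization(tiny_cohort):
    split = assign_split(tiny_cohort, seed=0)
    disc = split.discovery(tiny_cohort)
    a = train_base_learner(disc, "Healthy", ["CA19-9", "M1", "M2"], seed=5,
                           subset_sizes=[1, 2])
    b = train_base_learner(disc, "Healthy", ["CA19-9", "M1", "M2"], seed=5,
                           subset_sizes=[1, 2])
    assert a.selected_features_ == b.selected_features_
    assert np.array_equal(a.coef_, b.coef_)
    restored = DiagnosisSpecificClassifier.from_dict(a.to_dict())
    X = disc.feature_frame(a.selected_features_)
    assert np.array_equal(restored.predict_proba(X), a.predict_proba(X))


def test_no_leakage_on_null_data(null_xy):
    """On label-independent features the pooled out-of-fold AUC stays
    near chance for every subsampling mode (the leakage guard)."""
    aucs = {"over": [], "under": [], "smote": []}
    for seed in range(8):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = np.r_[np.zeros(22, int), np.ones(18, int)]
        for mode in aucs:
            clf = DiagnosisSpecificClassifier(
                subsampling=mode, subset_sizes=[1, 2], random_state=seed
            ).fit(X, y)
            aucs[mode].append(roc_auc(clf.oof_prob_, y))
    for mode, vals in aucs.items():
        assert abs(np.mean(vals) - 0.5) < 0.12, mode


def test_cv_profile_covers_grid(null_xy):
    X, y = null_xy
    clf = DiagnosisSpecificClassifier(subset_sizes=[1, 3], random_state=0).fit(X, y)
    assert set(clf.cv_profile_) == {1, 3, 5}  # grid plus the full size
    assert clf.best_size_ in clf.cv_profile_
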