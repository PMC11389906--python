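"""Stacking layer: equivalences, monotonicity, learner elimination,
reduced signature, serialization."""

import copy

import numpy as np
import pandas as pd
import pytest

from pdacstack._glm import sigmoid
from pdacstack.base_learner import DiagnosisSpecificClassifier, train_base_learner
from pdacstack.cohort import assign_split
from pdacstack.evaluation import roc_auc
from pdacstack.simulate import PDAC, generate_cohort
from pdacstack.stack import (
    StackedDiagnosisEnsemble,
    build_reduced_signature,
    fit_stack,
    predict_stack,
    recursive_learner_elimination,
    train_ensemble,
)

from conftest import small_config


def _two_learners(cohort, seed=0):
    split = assign_split(cohort, seed=seed)
    disc = split.discovery(cohort)
    l1 = train_base_learner(disc, "Healthy", ["CA19-9", "M1"], seed=1, subset_sizes=[1, 2])
    l2 = train_base_learner(
        disc, "Chronic Pancreatitis", ["CA19-9", "M2"], seed=2, subset_sizes=[1, 2]
    )
    return disc, split.validation(cohort), l1, l2


def test_identical_learners_reproduce_single_learner_roc(tiny_cohort):
    """Two copies of one learner: the stack's ROC equals the single
    learner's (the meta-model sees one direction)."""
    disc, val, l1, _ = _two_learners(tiny_cohort)
    twin = copy.deepcopy(l1)
    twin.diagnosis_class_ = "Gallstone Disease"
    stack = fit_stack([l1, twin], disc)
    p_stack, _ = predict_stack(stack, val)
    p_single = l1.predict_proba(val.feature_frame(l1.selected_features_))[:, 1]
    assert roc_auc(p_stack, val.y) == pytest.approx(roc_auc(p_single, val.y), abs=1e-9)


def test_perfect_learner_dominates(tiny_cohort):
    """A perfectly separating learner among noise keeps discovery AUC 1."""
    disc, val, l1, l2 = _two_learners(tiny_cohort)
    perfect = copy.deepcopy(l1)
    oracle_scores = dict(zip(disc.data["sample_id"], disc.y.astype(float)))

    class Oracle(DiagnosisSpecificClassifier):
        def predict_proba(self, X):
            n = len(X)
            p = self._oracle[: n]
            return np.column_stack([1 - p, p])

    # simpler: spike the meta input by replacing one learner's
    # probabilities via monkeypatched predict on the cohort frame
    disc_y = disc.y.astype(float)
    perfect_probs = np.clip(disc_y, 0.02, 0.98)

    import pdacstack.stack as stack_mod

    stack = StackedDiagnosisEnsemble([l1, l2], "insample")
    orig = stack_mod.predict_base

    def fake_predict(learner, samples):
        if learner is l1:
            ids = samples.data["sample_id"].tolist()
            lookup = dict(zip(disc.data["sample_id"], perfect_probs))
            return np.array([lookup.get(s, 0.5) for s in ids])
        return orig(learner, samples)

    stack_mod.predict_base, saved = fake_predict, orig
    try:
        stack.fit(disc)
        p, _ = predict_stack(stack, disc)
    finally:
        stack_mod.predict_base = saved
    assert roc_auc(p, disc.y) == 1.0


def test_all_base_probs_half_yields_intercept(tiny_cohort):
    disc, _, l1, l2 = _two_learners(tiny_cohort)
    stack = fit_stack([l1, l2], disc)
    # meta input logit(0.5) = 0 for every learner -> eta = intercept
    eta = stack.meta_intercept_
    n = 3
    M = np.zeros((n, len(stack.kept_)))
    p = sigmoid(eta + M @ stack.meta_coef_)
    assert np.allclose(p, sigmoid(stack.meta_intercept_))


def test_stack_monotone_in_positive_weight_learner(tiny_cohort):
    disc, val, l1, l2 = _two_learners(tiny_cohort)
    stack = fit_stack([l1, l2], disc)
    j = int(np.argmax(stack.meta_coef_))
    base = np.full((1, len(stack.kept_)), 0.0)
    lo = sigmoid(stack.meta_intercept_ + base @ stack.meta_coef_)[0]
    base[0, j] = 1.0
    hi = sigmoid(stack.meta_intercept_ + base @ stack.meta_coef_)[0]
    assert (hi > lo) == (stack.meta_coef_[j] > 0)


def test_serialization_round_trip_bit_exact(tiny_cohort, tmp_path):
    disc, val, l1, l2 = _two_learners(tiny_cohort)
    stack = fit_stack([l1, l2], disc)
    path = tmp_path / "stack.json"
    stack.save(path)
    restored = StackedDiagnosisEnsemble.load(path)
    p1, o1 = predict_stack(stack, val)
    p2, o2 = predict_stack(restored, val)
    assert np.array_equal(p1, p2) and np.array_equal(o1, o2)


def test_fit_requires_two_learners(tiny_cohort):
    disc, _, l1, _ = _two_learners(tiny_cohort)
    with pytest.raises(ValueError, match="at least 2"):
        fit_stack([l1], disc)


def test_elimination_trace_two_learners(tiny_cohort):
    disc, _, l1, l2 = _two_learners(tiny_cohort)
    stack = fit_stack([l1, l2], disc)
    trace, best = recursive_learner_elimination(stack, disc)
    assert len(trace) == 1
    assert set(best) <= {"Healthy", "Chronic Pancreatitis"}


def test_noise_learner_eliminated_first(tiny_cohort):
    """A learner fed pure noise meta-inputs is the first removed."""
    disc, _, l1, l2 = _two_learners(tiny_cohort)
    noise = copy.deepcopy(l1)
    noise.diagnosis_class_ = "Gallstone Disease"
    rng = np.random.default_rng(0)
    # pure-noise learner: random coefficients on an uninformative marker
    noise.selected_features_ = ["M3"]
    noise.coef_ = np.array([0.01])
    noise.mean_ = np.array([0.0])
    noise.scale_ = np.array([1.0])
    stack = fit_stack([l1, l2, noise], disc)
    trace, best = recursive_learner_elimination(stack, disc)
    assert trace[0]["removed"] == "Gallstone Disease"


def test_heterogeneous_signal_keeps_full_set():
    """When every class carries its own signal, elimination keeps all
    learners (the full set is the best performer)."""
    classes = ["Healthy", "Chronic Pancreatitis", "Gallstone Disease"]
    panel = [f"M{i}" for i in range(6)]
    effect = {}
    for k, cls in enumerate(classes):
        effect[(f"M{2 * k}", cls)] = -2.2
        effect[(f"M{2 * k + 1}", cls)] = -2.2
    cfg = small_config(classes, 24, 24, panel, effect_map=effect)
    keeps = 0
    for seed in range(3):
        coh = generate_cohort(cfg, seed=seed)
        split = assign_split(coh, seed=seed)
        disc = split.discovery(coh)
        stack = train_ensemble(disc, panel, seed=seed, subset_sizes=[1, 2, 3])
        _, best = recursive_learner_elimination(stack, disc, seed=seed)
        keeps += len(best) == len(classes)
    assert keeps >= 2


def test_reduced_equals_full_when_features_identical(tiny_cohort):
    split = assign_split(tiny_cohort, seed=3)
    disc = split.discovery(tiny_cohort)
    val = split.validation(tiny_cohort)
    feats = ["CA19-9", "M1", "M2"]
    full = train_ensemble(disc, feats, seed=9, subset_sizes=[1, 2])
    reduced = build_reduced_signature(disc, features=feats, seed=9, subset_sizes=[1, 2])
    p1, _ = predict_stack(full, val)
    p2, _ = predict_stack(reduced, val)
    assert np.array_equal(p1, p2)


def test_reduced_signature_default_feature_list():
    from pdacstack.stack import REDUCED_SIGNATURE_FEATURES

    assert REDUCED_SIGNATURE_FEATURES == [
        "CA19-9", "VWF", "CPE", "CTSV", "CEACAM1", "CD160", "diabetes", "age",
    ]
    with pytest.raises(ValueError, match="non-empty"):
        build_reduced_signature(None, features=[])


def test_reduced_without_planted_markers_is_weaker(tiny_cohort):
    """Excluding the planted markers from the reduced candidate list
    cannot improve discovery AUC."""
    split = assign_split(tiny_cohort, seed=4)
    disc = split.discovery(tiny_cohort)
    full = train_ensemble(disc, ["CA19-9", "M1", "M2", "M3"], seed=2, subset_sizes=[1, 2])
    reduced = build_reduced_signature(disc, features=["M2", "M3"], seed=2, subset_sizes=[1, 2])
    p_full, _ = predict_stack(full, disc)
    p_red, _ = predict_stack(reduced, disc)
    assert roc_auc(p_red, disc.y) <= roc_auc(p_full, disc.y) + 0.05
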