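"""Logistic stacking of diagnosis-specific base learners.

The meta-learner is a logistic regression on the logits of the base
learners' PDAC probabilities (clipped away from 0/1), fit on the
discovery set.  Two meta-input conventions are supported:

* ``insample`` — base learners applied to the whole discovery set
  (the convention the base-learner performance figures use), and
* ``out_of_fold`` ("oof") — each learner's own training rows contribute
  their leave-one-out held-out probabilities instead, the leakage-safe
  alternative.

Recursive base-learner elimination greedily removes the learner whose
removal least degrades (or most improves) a validation-free metric —
pooled stratified K-fold CV AUC at the meta level — and reports the
full trace; the held-out validation arm is never consulted.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from ._glm import logistic_fit, sigmoid
from .base_learner import DiagnosisSpecificClassifier, predict_base, train_base_learner
from .evaluation import roc_auc
from .firth import fit_firth
from .simulate import CONTROL_CLASSES, CohortTable

from scipy import stats

__all__ = [
    "REDUCED_SIGNATURE_FEATURES",
    "StackedDiagnosisEnsemble",
    "fit_stack",
    "predict_stack",
    "recursive_learner_elimination",
    "build_reduced_signature",
    "train_ensemble",
]

# the reduced 8-feature signature: six serum markers plus two
# clinicodemographic covariates
REDUCED_SIGNATURE_FEATURES = [
    "CA19-9",
    "VWF",
    "CPE",
    "CTSV",
    "CEACAM1",
    "CD160",
    "diabetes",
    "age",
]

_CLIP = 1e-6


def _logit(p):
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    return np.log(p / (1.0 - p))


class StackedDiagnosisEnsemble(BaseEstimator, ClassifierMixin):
    """Ordered base learners + logistic meta-coefficients.

    Parameters
    ----------
    learners : list of fitted :class:`DiagnosisSpecificClassifier`
    prediction_mode : {"insample", "oof"}
        How meta-inputs are produced on the discovery set during
        ``fit``; recorded in provenance.
    """

    def __init__(self, learners=None, prediction_mode: str = "insample"):
        self.learners = learners
        self.prediction_mode = prediction_mode

    def _meta_matrix(self, cohort: CohortTable, training: bool) -> np.ndarray:
        cols = []
        ids = cohort.data["sample_id"].tolist()
        for lr in self.learners:
            p = predict_base(lr, cohort)
            if training and self.prediction_mode == "oof":
                oof = dict(zip(lr.sample_ids_, lr.oof_prob_))
                p = np.array([oof.get(s, pi) for s, pi in zip(ids, p)])
            cols.append(_logit(p))
        return np.column_stack(cols)

    def fit(self, discovery: CohortTable, y=None):
        if self.learners is None or len(self.learners) < 2:
            raise ValueError("stacking needs at least 2 base learners")
        if self.prediction_mode not in ("insample", "oof"):
            raise ValueError("prediction_mode must be 'insample' or 'oof'")
        y = discovery.y if y is None else np.asarray(y)
        M = self._meta_matrix(discovery, training=True)
        keep = []
        for j in range(M.shape[1]):
            if np.ptp(M[:, j]) == 0.0:
                warnings.warn(
                    f"meta-input of learner {self.learner_names[j]!r} is "
                    "constant; dropped from the stack",
                    stacklevel=2,
                )
            else:
                keep.append(j)
        self.kept_ = keep
        design = np.column_stack([np.ones(len(M)), M[:, keep]])
        fit = logistic_fit(design, y, ridge=0.0, compute_cov=True)
        self.meta_used_firth_ = False
        if fit.separated:
            try:
                beta = fit_firth(design, y.astype(float)).beta
                self.meta_used_firth_ = True
            except ValueError:
                # collinear meta-inputs (e.g. identical learners): keep a
                # ridge-stabilized fit
                beta = logistic_fit(design, y, ridge=1e-4).beta
            pi = sigmoid(design @ beta)
            w = pi * (1 - pi)
            cov = np.linalg.pinv((design.T * w) @ design)
        else:
            beta, cov = fit.beta, fit.cov
        self.meta_intercept_ = float(beta[0])
        self.meta_coef_ = beta[1:].copy()
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        z = beta / np.where(se > 0, se, np.inf)
        self.meta_pvalues_ = 2.0 * stats.norm.sf(np.abs(z[1:]))
        self.provenance_ = {
            "prediction_mode": self.prediction_mode,
            "n_discovery": len(discovery),
            "sample_ids": discovery.data["sample_id"].tolist(),
        }
        self.classes_ = np.array([0, 1])
        return self

    @property
    def learner_names(self):
        return [
            lr.diagnosis_class_ or f"learner{j}" for j, lr in enumerate(self.learners)
        ]

    def predict_proba(self, samples: CohortTable):
        M = self._meta_matrix(samples, training=False)
        eta = self.meta_intercept_ + M[:, self.kept_] @ self.meta_coef_
        p1 = sigmoid(eta)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, samples: CohortTable):
        return (self.predict_proba(samples)[:, 1] >= 0.5).astype(int)

    def coefficients_table(self) -> pd.DataFrame:
        """learner, beta, p — the shape of the published stack table."""
        rows = [("(intercept)", self.meta_intercept_, np.nan)]
        names = [self.learner_names[j] for j in self.kept_]
        for name, b, p in zip(names, self.meta_coef_, self.meta_pvalues_):
            rows.append((name, float(b), float(p)))
        return pd.DataFrame(rows, columns=["learner", "beta", "p"])

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "prediction_mode": self.prediction_mode,
            "kept": list(self.kept_),
            "meta_intercept": self.meta_intercept_,
            "meta_coef": list(map(float, self.meta_coef_)),
            "meta_pvalues": list(map(float, self.meta_pvalues_)),
            "meta_used_firth": self.meta_used_firth_,
            "provenance": self.provenance_,
            "learners": [lr.to_dict() for lr in self.learners],
        }

    def save(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "StackedDiagnosisEnsemble":
        learners = [DiagnosisSpecificClassifier.from_dict(l) for l in d["learners"]]
        obj = cls(learners=learners, prediction_mode=d["prediction_mode"])
        obj.kept_ = list(d["kept"])
        obj.meta_intercept_ = float(d["meta_intercept"])
        obj.meta_coef_ = np.asarray(d["meta_coef"], dtype=float)
        obj.meta_pvalues_ = np.asarray(d["meta_pvalues"], dtype=float)
        obj.meta_used_firth_ = bool(d["meta_used_firth"])
        obj.provenance_ = d["provenance"]
        obj.classes_ = np.array([0, 1])
        return obj

    @classmethod
    def load(cls, path) -> "StackedDiagnosisEnsemble":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def fit_stack(
    learners, discovery: CohortTable, prediction_mode: str = "insample"
) -> StackedDiagnosisEnsemble:
    return StackedDiagnosisEnsemble(learners, prediction_mode).fit(discovery)


def predict_stack(stack: StackedDiagnosisEnsemble, samples: CohortTable):
    """PDAC probability and odds per sample."""
    p = stack.predict_proba(samples)[:, 1]
    pc = np.clip(p, _CLIP, 1.0 - _CLIP)
    return p, pc / (1.0 - pc)


def _meta_cv_auc(M, y, cols, n_splits=5, seed=0):
    """Pooled stratified K-fold CV AUC of the meta-learner on columns."""
    design = np.column_stack([np.ones(len(M)), M[:, cols]])
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    oof = np.empty(len(y), dtype=float)
    for tr, te in skf.split(design, y):
        fit = logistic_fit(design[tr], y[tr], ridge=1e-4)
        oof[te] = sigmoid(design[te] @ fit.beta)
    return roc_auc(oof, y)


def recursive_learner_elimination(
    stack: StackedDiagnosisEnsemble,
    discovery: CohortTable,
    n_splits: int = 5,
    seed: int = 0,
):
    """Greedy backward elimination of base learners.

    At each step the learner whose removal maximizes the pooled CV AUC
    of the refit meta-learner is dropped.  Returns ``(trace, best)``:
    ``trace`` is a list of dicts (remaining learner names, metric after
    the step's removal, removed name) and ``best`` the learner-name
    subset with the highest metric anywhere along the trace (including
    the full set).
    """
    y = discovery.y
    M = stack._meta_matrix(discovery, training=True)
    names = stack.learner_names
    current = list(range(len(names)))
    best_metric = _meta_cv_auc(M, y, current, n_splits, seed)
    best_subset = [names[j] for j in current]
    trace = []
    while len(current) > 1:
        scored = []
        for j in current:
            remaining = [k for k in current if k != j]
            scored.append((_meta_cv_auc(M, y, remaining, n_splits, seed), j))
        metric, drop = max(scored, key=lambda t: (t[0], -t[1]))
        current = [k for k in current if k != drop]
        trace.append(
            {
                "removed": names[drop],
                "remaining": [names[k] for k in current],
                "metric": float(metric),
            }
        )
        if metric > best_metric:
            best_metric = metric
            best_subset = [names[k] for k in current]
    return trace, best_subset


def train_ensemble(
    discovery: CohortTable,
    candidates: list,
    classes=None,
    subsampling: str = "over",
    seed: int = 0,
    subset_sizes=None,
    prediction_mode: str = "insample",
) -> StackedDiagnosisEnsemble:
    """Train one base learner per control class present, then stack."""
    present = [
        c
        for c in (classes or CONTROL_CLASSES)
        if (discovery.data["diagnosis_class"] == c).any()
    ]
    learners = []
    for k, cls in enumerate(present):
        learners.append(
            train_base_learner(
                discovery,
                cls,
                candidates,
                subsampling=subsampling,
                seed=(seed * 1009 + k) % (2**31),
                subset_sizes=subset_sizes,
            )
        )
    return fit_stack(learners, discovery, prediction_mode)


def build_reduced_signature(
    discovery: CohortTable,
    features=None,
    classes=None,
    subsampling: str = "over",
    seed: int = 0,
    subset_sizes=None,
    prediction_mode: str = "insample",
) -> StackedDiagnosisEnsemble:
    """Re-run the diagnosis-specific ensemble restricted to a reduced
    candidate feature list (default: the 8-feature signature)."""
    features = REDUCED_SIGNATURE_FEATURES if features is None else list(features)
    if not features:
        raise ValueError("reduced signature needs a non-empty feature list")
    return train_ensemble(
        discovery,
        features,
        classes=classes,
        subsampling=subsampling,
        seed=seed,
        subset_sizes=subset_sizes,
        prediction_mode=prediction_mode,
    )
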