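"""Diagnosis-specific base learners.

Each base learner distinguishes the controls of one diagnosis class
from the (shared) PDAC cases of the discovery set.  Training is
leave-one-out cross-validation with everything recomputed inside each
fold — standardization from the fold's training rows, class-imbalance
resampling of the training rows only, recursive feature elimination on
the resampled fold — so no information from the held-out row leaks into
feature selection.  The feature-subset size with the best pooled
out-of-fold AUC wins, and the final model is refit on the full training
subset at that size.

RFE uses a ridge-stabilized (1e-4) logistic fit and repeatedly drops
the feature with the smallest |standardized coefficient|; ties are
broken lexicographically by feature name (the alphabetically earlier
name survives).  The final reported model is refit without the ridge
unless separation occurs, in which case it falls back to Firth
penalization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._glm import logistic_fit, sigmoid
from .evaluation import roc_auc
from .firth import fit_firth
from .resample import get_sampler
from .simulate import PDAC, CohortTable

__all__ = [
    "DEFAULT_SUBSET_SIZES",
    "rfe_rank",
    "DiagnosisSpecificClassifier",
    "train_base_learner",
    "predict_base",
]

DEFAULT_SUBSET_SIZES = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 30, 45, 60]


def _grid(n_features: int, subset_sizes=None) -> list[int]:
    base = subset_sizes if subset_sizes is not None else DEFAULT_SUBSET_SIZES
    sizes = sorted({s for s in base if 1 <= s <= n_features} | {n_features})
    return sizes


def rfe_rank(X, y, feature_names=None, ridge: float = 1e-4, subset_sizes=None):
    """Recursive feature elimination with logistic regression.

    ``X`` must be standardized.  Returns ``(order, per_size_fits)``:
    ``order`` lists features from first-dropped to last-surviving, and
    ``per_size_fits`` maps each requested subset size to
    ``(feature_names, beta)`` for the top-ranked features of that size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
    active = list(range(p))
    drop_order: list[int] = []
    while len(active) > 1:
        fit = logistic_fit(
            np.column_stack([np.ones(n), X[:, active]]), y, ridge=ridge
        )
        coefs = np.abs(fit.beta[1:])
        # smallest |coef| goes; among (numerical) ties the
        # lexicographically later name is dropped, so the earlier
        # name survives
        low = coefs.min()
        tol = 1e-9 * max(1.0, low)
        tied = [j for j in range(len(active)) if coefs[j] <= low + tol]
        worst = max(tied, key=lambda j: names[active[j]])
        drop_order.append(active.pop(worst))
    drop_order.extend(active)
    order = [names[j] for j in drop_order]
    per_size = {}
    for s in _grid(p, subset_sizes):
        top_idx = drop_order[-s:]
        fit = logistic_fit(np.column_stack([np.ones(n), X[:, top_idx]]), y, ridge=ridge)
        per_size[s] = ([names[j] for j in top_idx], fit.beta.copy())
    return order, per_size


class DiagnosisSpecificClassifier(BaseEstimator, ClassifierMixin):
    """RFE + logistic regression under LOOCV with in-fold resampling.

    Parameters
    ----------
    subsampling : {"over", "under", "smote"}
        Imbalance correction applied inside each training fold.
    subset_sizes : sequence of int, optional
        Candidate feature-count grid; defaults to
        ``{1..10, 15, 20, 30, 45, 60, p}``.
    ridge : float
        Stabilizing L2 penalty for the fits inside RFE.
    random_state : int
        Seeds the per-fold resampling draws.

    Attributes (after ``fit``)
    --------------------------
    selected_features_ : winning feature names.
    coef_, intercept_ : final logistic parameters on standardized inputs.
    mean_, scale_ : standardization statistics of the selected features,
        computed from the full training subset.
    cv_profile_ : dict size -> pooled LOOCV AUC.
    oof_prob_ : out-of-fold probability per training row at the winning
        size (the leakage-safe meta-learner input).
    used_firth_ : True when separation forced a Firth refit.
    """

    def __init__(
        self,
        subsampling: str = "over",
        subset_sizes=None,
        ridge: float = 1e-4,
        smote_k: int = 5,
        random_state: int = 0,
    ):
        self.subsampling = subsampling
        self.subset_sizes = subset_sizes
        self.ridge = ridge
        self.smote_k = smote_k
        self.random_state = random_state

    def _sampler(self, seed):
        sampler = get_sampler(self.subsampling, random_state=seed)
        if self.subsampling == "smote":
            sampler.k = self.smote_k
        return sampler

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_ = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        n, p = X.shape
        sizes = _grid(p, self.subset_sizes)
        oof = np.full((n, len(sizes)), np.nan)
        for i in range(n):
            tr = np.ones(n, dtype=bool)
            tr[i] = False
            if len(np.unique(y[tr])) < 2:
                oof[i, :] = 0.5
                continue
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Z = (X[tr] - mu) / sd
            seed = (self.random_state * 100003 + i) % (2**31)
            Zb, yb = self._sampler(seed).fit_resample(Z, y[tr])
            _, per_size = rfe_rank(
                Zb, yb, self.feature_names_, ridge=self.ridge, subset_sizes=sizes
            )
            z_i = (X[i] - mu) / sd
            for k, s in enumerate(sizes):
                feats, beta = per_size[s]
                idx = [self.feature_names_.index(f) for f in feats]
                oof[i, k] = sigmoid(beta[0] + z_i[idx] @ beta[1:])
        self.cv_profile_ = {
            s: float(roc_auc(oof[:, k], y)) for k, s in enumerate(sizes)
        }
        best_k = int(
            max(range(len(sizes)), key=lambda k: (self.cv_profile_[sizes[k]], -sizes[k]))
        )
        self.best_size_ = sizes[best_k]
        self.oof_prob_ = oof[:, best_k].copy()

        # final refit on the full training subset at the winning size
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        seed = (self.random_state * 100003 + n) % (2**31)
        Zb, yb = self._sampler(seed).fit_resample(Z, y)
        order, _ = rfe_rank(Zb, yb, self.feature_names_, ridge=self.ridge, subset_sizes=sizes)
        self.selected_features_ = sorted(
            order[-self.best_size_:], key=self.feature_names_.index
        )
        idx = [self.feature_names_.index(f) for f in self.selected_features_]
        design = np.column_stack([np.ones(len(Zb)), Zb[:, idx]])
        fit = logistic_fit(design, yb, ridge=0.0)
        self.used_firth_ = False
        if fit.separated:
            warnings.warn(
                "complete separation in final fit; switching to Firth "
                "penalization",
                stacklevel=2,
            )
            try:
                beta = fit_firth(design, yb.astype(float)).beta
                self.used_firth_ = True
            except ValueError:
                # rank-deficient resampled design: keep the ridge fit
                beta = logistic_fit(design, yb, ridge=self.ridge).beta
        else:
            beta = fit.beta
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.mean_ = mu[idx].copy()
        self.scale_ = sd[idx].copy()
        self.classes_ = np.array([0, 1])
        return self

    def _frame_to_matrix(self, X):
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.selected_features_ if f not in X.columns]
            if missing:
                raise KeyError(f"missing feature columns: {missing}")
            return X[self.selected_features_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        idx = [self.feature_names_.index(f) for f in self.selected_features_]
        return X[:, idx]

    def predict_proba(self, X):
        M = self._frame_to_matrix(X)
        Z = (M - self.mean_) / self.scale_
        p1 = sigmoid(self.intercept_ + Z @ self.coef_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "diagnosis_class": getattr(self, "diagnosis_class_", None),
            "feature_names": self.feature_names_,
            "selected_features": self.selected_features_,
            "intercept": self.intercept_,
            "coef": list(map(float, self.coef_)),
            "mean": list(map(float, self.mean_)),
            "scale": list(map(float, self.scale_)),
            "cv_profile": {str(k): v for k, v in self.cv_profile_.items()},
            "best_size": self.best_size_,
            "subsampling": self.subsampling,
            "random_state": self.random_state,
            "used_firth": self.used_firth_,
            "sample_ids": list(getattr(self, "sample_ids_", [])),
            "oof_prob": list(map(float, self.oof_prob_)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiagnosisSpecificClassifier":
        obj = cls(subsampling=d["subsampling"], random_state=d["random_state"])
        obj.feature_names_ = list(d["feature_names"])
        obj.selected_features_ = list(d["selected_features"])
        obj.intercept_ = float(d["intercept"])
        obj.coef_ = np.asarray(d["coef"], dtype=float)
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.scale_ = np.asarray(d["scale"], dtype=float)
        obj.cv_profile_ = {int(k): v for k, v in d["cv_profile"].items()}
        obj.best_size_ = int(d["best_size"])
        obj.used_firth_ = bool(d["used_firth"])
        obj.oof_prob_ = np.asarray(d["oof_prob"], dtype=float)
        obj.sample_ids_ = list(d.get("sample_ids", []))
        obj.diagnosis_class_ = d.get("diagnosis_class")
        obj.classes_ = np.array([0, 1])
        return obj


def train_base_learner(
    discovery: CohortTable,
    diagnosis_class: str | None,
    candidates: list,
    subsampling: str = "over",
    seed: int = 0,
    subset_sizes=None,
) -> DiagnosisSpecificClassifier:
    """Train one base learner: the given class's controls vs all PDACs.

    ``diagnosis_class=None`` uses *all* controls (the whole-discovery
    comparator configuration).  PDAC is coded 1 throughout.
    """
    d = discovery.data
    if diagnosis_class is None:
        mask = np.ones(len(d), dtype=bool)
    else:
        if diagnosis_class not in set(d["diagnosis_class"]):
            raise ValueError(f"class {diagnosis_class!r} absent from discovery set")
        mask = ((d["diagnosis_class"] == diagnosis_class) | (d["label"] == "case")).to_numpy()
    subset = discovery.subset(mask)
    y = subset.y
    if (y == 0).sum() < 3:
        raise ValueError(
            f"class {diagnosis_class!r} has fewer than 3 control samples in discovery"
        )
    if (y == 1).sum() < 1:
        raise ValueError("no PDAC cases in discovery")
    X = subset.feature_frame(candidates)
    clf = DiagnosisSpecificClassifier(
        subsampling=subsampling, subset_sizes=subset_sizes, random_state=seed
    )
    clf.fit(X, y)
    clf.diagnosis_class_ = diagnosis_class
    clf.sample_ids_ = subset.data["sample_id"].tolist()
    clf.candidates_ = list(candidates)
    return clf


def predict_base(learner: DiagnosisSpecificClassifier, samples: CohortTable) -> np.ndarray:
    """PDAC probability for any samples, regardless of diagnosis class."""
    X = samples.feature_frame(learner.selected_features_)
    return learner.predict_proba(X)[:, 1]
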