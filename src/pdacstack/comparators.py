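"""Non-ensemble baselines trained on the whole discovery set.

The whole-cohort RFE-glm comparator reuses the base-learner machinery
verbatim but pools *all* controls against the cases — one model instead
of sixteen, so no stacking.  The tree baselines (random forest,
gradient-boosted trees) delegate fitting to scikit-learn and tune by
random hyperparameter search scored with pooled cross-validated AUC and
in-fold resampling, on exactly the same candidate features and splits
as the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .base_learner import DiagnosisSpecificClassifier, train_base_learner
from .evaluation import roc_auc
from .resample import get_sampler
from .simulate import CohortTable

__all__ = [
    "train_rfe_glm_whole",
    "TreeComparator",
    "train_tree_comparators",
    "DEFAULT_TREE_GRIDS",
]


def train_rfe_glm_whole(
    discovery: CohortTable,
    candidates: list,
    subsampling: str = "over",
    seed: int = 0,
    subset_sizes=None,
) -> DiagnosisSpecificClassifier:
    """RFE + logistic on all discovery controls vs all cases."""
    return train_base_learner(
        discovery,
        None,
        candidates,
        subsampling=subsampling,
        seed=seed,
        subset_sizes=subset_sizes,
    )


DEFAULT_TREE_GRIDS = {
    "random_forest": {
        "n_estimators": [100, 200, 500],
        "max_depth": [None, 2, 3, 5, 8],
        "max_features": ["sqrt", "log2", 0.5, 1.0],
        "min_samples_leaf": [1, 2, 4, 8],
    },
    "gradient_boosted_trees": {
        "n_estimators": [50, 100, 200, 500],
        "max_depth": [1, 2, 3, 5],
        "learning_rate": [0.01, 0.05, 0.1, 0.3],
        "subsample": [0.5, 0.8, 1.0],
    },
}

_FAMILIES = {
    "random_forest": RandomForestClassifier,
    "gradient_boosted_trees": GradientBoostingClassifier,
}


@dataclass
class TreeComparator:
    model_family: str
    model: object
    best_params: dict
    best_auc: float
    search_trace: list = field(default_factory=list)
    features: list = field(default_factory=list)

    def predict_proba_cohort(self, cohort: CohortTable):
        X = cohort.feature_frame(self.features).to_numpy()
        return self.model.predict_proba(X)[:, 1]


def _cv_auc(model_cls, params, X, y, sampler_mode, seed, cv):
    if cv == "loo":
        splitter = LeaveOneOut()
    else:
        splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    for k, (tr, te) in enumerate(splitter.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            oof[te] = 0.5
            continue
        sampler = get_sampler(sampler_mode, random_state=(seed * 97 + k) % (2**31))
        Xb, yb = sampler.fit_resample(X[tr], y[tr])
        model = model_cls(random_state=seed, **params)
        model.fit(Xb, yb)
        oof[te] = model.predict_proba(X[te])[:, 1]
    return roc_auc(oof, y)


def train_tree_comparators(
    discovery: CohortTable,
    model_family: str = "random_forest",
    candidates: list | None = None,
    n_param_draws: int = 1000,
    subsampling: str = "over",
    seed: int = 0,
    cv="loo",
    grids: dict | None = None,
) -> TreeComparator:
    """Random hyperparameter search for a tree baseline.

    ``cv='loo'`` honours leave-one-out (the default); an integer
    downgrades to stratified K-fold for speed.  The search trace has
    exactly ``n_param_draws`` entries and the best configuration is
    refit on the full (resampled) discovery set.
    """
    if n_param_draws < 1:
        raise ValueError("n_param_draws must be >= 1")
    if model_family not in _FAMILIES:
        raise ValueError(f"unknown model family {model_family!r}")
    grid = (grids or DEFAULT_TREE_GRIDS)[model_family]
    model_cls = _FAMILIES[model_family]
    if candidates is None:
        candidates = list(discovery.marker_names)
    X = discovery.feature_frame(candidates).to_numpy()
    y = discovery.y
    rng = np.random.default_rng(seed)
    trace = []
    best = None
    for draw in range(n_param_draws):
        params = {k: v[rng.integers(len(v))] for k, v in grid.items()}
        auc = _cv_auc(model_cls, params, X, y, subsampling, seed, cv)
        trace.append({"params": params, "cv_auc": float(auc)})
        if best is None or auc > best[0]:
            best = (auc, params)
    sampler = get_sampler(subsampling, random_state=seed)
    Xb, yb = sampler.fit_resample(X, y)
    final = model_cls(random_state=seed, **best[1])
    final.fit(Xb, yb)
    return TreeComparator(
        model_family=model_family,
        model=final,
        best_params=best[1],
        best_auc=float(best[0]),
        search_trace=trace,
        features=list(candidates),
    )
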