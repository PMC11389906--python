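"""Model-agnostic permutation importance per base learner, scaled to
[0, 100] within each learner and averaged across learners.

Importance of a feature is the mean drop in AUC over independent
permutations of that feature's column; features a learner never
selected get exactly 0 without computation.  Per-learner importances
are max-normalized to 100 and the cross-learner aggregate is their
plain mean (zeros included), so a feature selected everywhere with top
importance aggregates to 100.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .base_learner import DiagnosisSpecificClassifier, predict_base
from .evaluation import roc_auc
from .simulate import CohortTable

__all__ = ["permutation_importance", "aggregate_importance", "importance_long_table"]


def permutation_importance(
    learner: DiagnosisSpecificClassifier,
    data: CohortTable,
    features: list | None = None,
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Raw AUC-drop importance for each feature in ``features``.

    ``features`` defaults to the learner's selected set; any extra
    names get importance 0.
    """
    if features is None:
        features = list(learner.selected_features_)
    y = data.y
    if len(np.unique(y)) < 2:
        raise ValueError("importance metric undefined on single-class data")
    X = data.feature_frame(
        [f for f in features if f in learner.selected_features_]
    )
    base_auc = roc_auc(predict_base(learner, data), y)
    out = pd.Series(0.0, index=list(features))
    for f in features:
        if f not in learner.selected_features_:
            continue
        # per-feature stream keyed by the name, so the importance vector
        # is invariant to the order features are listed in
        rng = np.random.default_rng([seed, zlib.crc32(f.encode())])
        drops = np.empty(n_repeats)
        Xp = X.copy()
        for r in range(n_repeats):
            Xp[f] = rng.permutation(X[f].to_numpy())
            p = learner.predict_proba(Xp)[:, 1]
            drops[r] = base_auc - roc_auc(p, y)
        Xp[f] = X[f]
        out[f] = float(drops.mean())
    return out


def aggregate_importance(
    learners: list,
    data: CohortTable,
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature x learner matrix of scaled importances plus aggregate.

    Per learner, raw importances are scaled so the maximum is 100
    (when any importance is positive); the ``aggregate`` column is the
    mean over learners with absent features counted as 0.  Rows are
    sorted by descending aggregate, ties broken lexicographically.
    """
    if not learners:
        raise ValueError("need at least one learner")
    all_features = sorted({f for lr in learners for f in lr.selected_features_})
    cols = {}
    for j, lr in enumerate(learners):
        raw = permutation_importance(
            lr, data, features=all_features, n_repeats=n_repeats,
            seed=(seed * 31 + j) % (2**31),
        )
        raw = raw.clip(lower=0.0)
        top = raw.max()
        scaled = raw * (100.0 / top) if top > 0 else raw
        cols[lr.diagnosis_class_ or f"learner{j}"] = scaled
    table = pd.DataFrame(cols, index=all_features)
    table["aggregate"] = table.mean(axis=1)
    table = table.sort_values(
        by=["aggregate"], ascending=False, kind="mergesort"
    )
    # lexicographic tie-break within equal aggregates
    table = table.iloc[
        np.lexsort((table.index.to_numpy(), -table["aggregate"].to_numpy()))
    ]
    return table


def importance_long_table(table: pd.DataFrame) -> pd.DataFrame:
    """Long (feature, learner, scaled_importance) layout for export."""
    long = (
        table.drop(columns="aggregate")
        .reset_index(names="feature")
        .melt(id_vars="feature", var_name="learner", value_name="scaled_importance")
    )
    return long
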