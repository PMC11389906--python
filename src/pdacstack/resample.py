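"""Class-imbalance corrections applied strictly inside training folds.

Three strategies, all returning exactly balanced classes:

* random oversampling of the minority class (with replacement),
* random undersampling of the majority class (without replacement),
* SMOTE: synthetic minority points interpolated uniformly along the
  segment to one of the k nearest minority neighbours, with distances
  measured on standardized features.

The samplers expose the imbalanced-learn ``fit_resample`` interface and
are deterministic given ``random_state``.  They must only ever see the
training slice of a fold; the leakage guard for that discipline lives
in the base-learner tests, not here.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "RandomOverSampler",
    "RandomUnderSampler",
    "SmoteSampler",
    "oversample_minority",
    "undersample_majority",
    "smote",
    "get_sampler",
]


def _split_classes(y):
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to resample")
    if len(classes) > 2:
        raise ValueError("only binary problems are supported")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    if counts[0] == counts[1]:
        minority, majority = classes[0], classes[1]
    return minority, majority


class RandomOverSampler(BaseEstimator):
    """Duplicate minority rows (sampled with replacement) until balance."""

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        minority, majority = _split_classes(y)
        idx_min = np.flatnonzero(y == minority)
        idx_maj = np.flatnonzero(y == majority)
        deficit = len(idx_maj) - len(idx_min)
        if deficit == 0:
            return X.copy(), y.copy()
        rng = np.random.default_rng(self.random_state)
        extra = rng.choice(idx_min, size=deficit, replace=True)
        keep = np.concatenate([np.arange(len(y)), extra])
        return X[keep], y[keep]


class RandomUnderSampler(BaseEstimator):
    """Subsample the majority class without replacement to minority size."""

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        minority, majority = _split_classes(y)
        idx_min = np.flatnonzero(y == minority)
        idx_maj = np.flatnonzero(y == majority)
        if len(idx_maj) == len(idx_min):
            return X.copy(), y.copy()
        rng = np.random.default_rng(self.random_state)
        keep_maj = rng.choice(idx_maj, size=len(idx_min), replace=False)
        keep = np.sort(np.concatenate([idx_min, keep_maj]))
        return X[keep], y[keep]


class SmoteSampler(BaseEstimator):
    """SMOTE with k nearest minority neighbours on standardized features.

    Each synthetic point is ``x_i + u * (x_nn - x_i)`` with
    ``u ~ Uniform(0, 1)`` in the original feature space; only the
    neighbour search is standardized.  ``k`` is capped at
    ``minority_count - 1``; with a single minority row SMOTE degrades to
    plain oversampling (with a warning).
    """

    def __init__(self, k: int = 5, random_state: int = 0):
        self.k = k
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        minority, majority = _split_classes(y)
        idx_min = np.flatnonzero(y == minority)
        idx_maj = np.flatnonzero(y == majority)
        deficit = len(idx_maj) - len(idx_min)
        if deficit == 0:
            return X.copy(), y.copy()
        if len(idx_min) < 2:
            warnings.warn(
                "SMOTE needs at least 2 minority samples; falling back to "
                "random oversampling",
                stacklevel=2,
            )
            return RandomOverSampler(self.random_state).fit_resample(X, y)
        rng = np.random.default_rng(self.random_state)
        Xm = X[idx_min]
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Xm - mu) / sd
        d = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        k = min(self.k, len(idx_min) - 1)
        nn = np.argsort(d, axis=1)[:, :k]
        base = rng.integers(0, len(idx_min), size=deficit)
        pick = rng.integers(0, k, size=deficit)
        u = rng.uniform(0.0, 1.0, size=deficit)
        partners = nn[base, pick]
        synthetic = Xm[base] + u[:, None] * (Xm[partners] - Xm[base])
        X_out = np.vstack([X, synthetic])
        y_out = np.concatenate([y, np.full(deficit, minority, dtype=y.dtype)])
        return X_out, y_out


def oversample_minority(X, y, seed: int = 0):
    return RandomOverSampler(seed).fit_resample(X, y)


def undersample_majority(X, y, seed: int = 0):
    return RandomUnderSampler(seed).fit_resample(X, y)


def smote(X, y, k: int = 5, seed: int = 0):
    return SmoteSampler(k=k, random_state=seed).fit_resample(X, y)


_SAMPLERS = {
    "over": RandomOverSampler,
    "under": RandomUnderSampler,
    "smote": SmoteSampler,
}


def get_sampler(mode: str, random_state: int = 0):
    """Sampler factory for pipeline configs; modes: over, under, smote."""
    if mode not in _SAMPLERS:
        raise ValueError(f"unknown subsampling mode {mode!r}; choose from {sorted(_SAMPLERS)}")
    return _SAMPLERS[mode](random_state=random_state)
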