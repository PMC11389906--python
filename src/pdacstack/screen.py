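"""Per-feature association with PDAC and single-predictor performance.

Each feature gets a Firth-penalized logistic fit on the discovery set
(odds ratio, profile CI, penalized-LRT p-value) plus the ROC
performance of the single-feature logistic model trained on discovery
and scored — without refitting — on discovery and validation.  Symptom
associations use the same Firth machinery, restricted to the
symptomatic source cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._glm import sigmoid
from .evaluation import RocSummary, roc_summary
from .firth import FirthFit, fit_firth
from .simulate import CohortTable

__all__ = ["ScreenRow", "screen_features", "youden_cutoff", "symptom_association"]


@dataclass
class ScreenRow:
    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    discovery: RocSummary | None
    validation: RocSummary | None
    youden_threshold: float
    constant: bool = False


def youden_cutoff(scores, labels):
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between adjacent observed
    scores (positive call: score >= threshold), so the returned cutoff
    sits between the two groups it separates.  Returns ``(threshold, J)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(np.unique(labels))) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0]), 0.0
    # midpoints preferred on ties; the extremes (call everything, or
    # nothing, positive; J = 0) are genuine candidates too
    midpoints = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.r_[midpoints, uniq[0] - 1.0, uniq[-1] + 1.0]
    case = scores[labels == 1]
    ctrl = scores[labels == 0]
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        j = (case >= t).mean() + (ctrl < t).mean() - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = t, j
    return float(best_t), float(best_j)


def _single_feature_fit(x, y):
    design = np.column_stack([np.ones(len(x)), x])
    return fit_firth(design, y.astype(float))


def screen_features(
    discovery: CohortTable,
    features: list,
    validation: CohortTable | None = None,
    n_boot: int = 500,
    seed: int = 0,
    ci: bool = True,
) -> list[ScreenRow]:
    """Firth fit + single-feature model performance per feature.

    Constant features are flagged with p = 1 by convention.  Rows come
    back sorted by p-value.  Validation performance uses the
    discovery-fit model's scores; a monotone single-feature model means
    the AUC equals that of the raw feature values, but the fitted model
    is applied for consistency with multi-stage pipelines.
    """
    y = discovery.y
    X = discovery.feature_frame(features)
    rows = []
    for f in features:
        x = X[f].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            rows.append(
                ScreenRow(f, 1.0, np.nan, np.nan, 1.0, None, None, float(x[0]), True)
            )
            continue
        fit = _single_feature_fit(x, y)
        lo, hi = fit.profile_ci(1) if ci else (np.nan, np.nan)
        p = fit.lrt_pvalue(1)
        scores_d = sigmoid(fit.beta[0] + fit.beta[1] * x)
        disc = roc_summary(scores_d, y, n_boot=n_boot, seed=seed)
        val = None
        if validation is not None:
            xv = validation.feature_frame([f])[f].to_numpy(dtype=float)
            scores_v = sigmoid(fit.beta[0] + fit.beta[1] * xv)
            val = roc_summary(scores_v, validation.y, n_boot=n_boot, seed=seed)
        thr, _ = youden_cutoff(x, y)
        rows.append(
            ScreenRow(
                feature=f,
                odds_ratio=float(np.exp(fit.beta[1])),
                ci_low=lo,
                ci_high=hi,
                pvalue=p,
                discovery=disc,
                validation=val,
                youden_threshold=thr,
            )
        )
    rows.sort(key=lambda r: (r.pvalue, r.feature))
    return rows


def screen_table(rows: list[ScreenRow]) -> pd.DataFrame:
    """Flatten screen rows to the screen.tsv schema, with an optional
    Benjamini-Hochberg column (reported, never used for selection)."""
    recs = []
    for r in rows:
        recs.append(
            {
                "feature": r.feature,
                "OR": r.odds_ratio,
                "CI_low": r.ci_low,
                "CI_high": r.ci_high,
                "p": r.pvalue,
                "youden_threshold": r.youden_threshold,
                "auc_discovery": r.discovery.auc if r.discovery else np.nan,
                "auc_validation": r.validation.auc if r.validation else np.nan,
                "constant": r.constant,
            }
        )
    df = pd.DataFrame(recs)
    p = df["p"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    bh = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = m - rank_from_end
        running = min(running, p[idx] * m / k)
        bh[idx] = running
    df["p_bh"] = bh
    return df


def symptom_association(cohort: CohortTable) -> dict[str, FirthFit]:
    """Per-symptom Firth fit vs PDAC status, symptomatic source only.

    Screening-source samples carry no symptom information and are
    excluded.  Symptoms absent (all-zero or missing) are skipped.
    """
    sympt = cohort.subset((cohort.data["source_cohort"] == "symptomatic").to_numpy())
    y = sympt.y
    out = {}
    for s in sympt.symptom_names:
        x = sympt.data[s].to_numpy(dtype=float)
        if not np.isfinite(x).all() or x.sum() == 0:
            import warnings

            warnings.warn(f"symptom {s!r} absent or incomplete; skipped", stacklevel=2)
            continue
        out[s] = _single_feature_fit(x, y)
    return out
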