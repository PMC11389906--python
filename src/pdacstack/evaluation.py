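"""ROC metrics, fixed-specificity operating points, and bootstrap inference.

AUC is computed as the Mann-Whitney U statistic (ties credited 1/2)
normalized by ``n_cases * n_controls``.  Sensitivity/PPV/NPV are
reported at 90% specificity with the threshold restricted to observed
score values (no interpolation), and uncertainty comes from stratified
bootstrap: cases and controls resampled separately with replacement,
percentile intervals.  AUC (or sensitivity) comparisons between two
paired score vectors use the one-sided bootstrap z-test convention of
the pROC package: the observed difference standardized by the bootstrap
SD of the difference, referred to the normal tail.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "RocSummary",
    "AucComparison",
    "roc_auc",
    "roc_curve_points",
    "metrics_at_specificity",
    "stratified_bootstrap_ci",
    "compare_auc_bootstrap",
    "roc_summary",
    "evaluate_symptom_subset",
    "qcancer_analysis",
]


def _check_two_classes(labels):
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be 1-D")
    uniq = set(np.unique(labels))
    if not uniq <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(uniq) < 2:
        raise ValueError("both classes must be present")
    return labels.astype(int)


def roc_auc(scores, labels) -> float:
    """Rank-based AUC; exactly the tie-corrected pair-counting statistic."""
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve_points(scores, labels):
    """(threshold, sensitivity, specificity) at every observed score.

    Positive call is ``score >= threshold``.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.unique(scores)
    case = scores[labels == 1]
    ctrl = scores[labels == 0]
    sens = np.array([(case >= t).mean() for t in thresholds])
    spec = np.array([(ctrl < t).mean() for t in thresholds])
    return thresholds, sens, spec


def metrics_at_specificity(scores, labels, spec: float = 0.90):
    """Sensitivity, PPV, NPV at the smallest observed threshold with
    specificity >= ``spec``.

    If no observed score attains the required specificity the threshold
    is placed above the maximum score: sensitivity 0, PPV undefined
    (NaN), NPV equal to the control fraction.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    case = scores[labels == 1]
    ctrl = scores[labels == 0]
    thresholds = np.unique(scores)
    chosen = None
    for t in thresholds:
        if (ctrl < t).mean() >= spec:
            chosen = float(t)
            break
    if chosen is None:
        n1, n0 = len(case), len(ctrl)
        return 0.0, float("nan"), n0 / (n0 + n1), float(np.max(scores)) + 1.0
    tp = float((case >= chosen).sum())
    fp = float((ctrl >= chosen).sum())
    fn = float((case < chosen).sum())
    tn = float((ctrl < chosen).sum())
    sens = tp / (tp + fn)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    return sens, ppv, npv, chosen


def stratified_bootstrap_ci(
    metric,
    scores,
    labels,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
):
    """Percentile CI with cases and controls resampled separately.

    ``metric(scores, labels) -> float``.  Resamples on which the metric
    is undefined (raises or returns NaN) are redrawn; the redraw count
    is returned alongside the interval.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(labels == 1)
    idx0 = np.flatnonzero(labels == 0)
    vals = np.full(n_boot, np.nan)
    redraws = 0
    for b in range(n_boot):
        for _attempt in range(20):
            take = np.concatenate(
                [rng.choice(idx1, len(idx1)), rng.choice(idx0, len(idx0))]
            )
            try:
                v = metric(scores[take], labels[take])
            except ValueError:
                v = float("nan")
            if np.isfinite(v):
                vals[b] = v
                break
            redraws += 1
    finite = vals[np.isfinite(vals)]
    if len(finite) < n_boot // 2:
        # metric undefined on essentially every resample: no interval
        return float("nan"), float("nan"), redraws
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(finite, [alpha, 1.0 - alpha])
    return float(lo), float(hi), redraws


@dataclass
class RocSummary:
    """AUC and the 90%-specificity operating point, with bootstrap CIs."""

    auc: float
    auc_ci: tuple
    sens: float
    sens_ci: tuple
    ppv: float
    ppv_ci: tuple
    npv: float
    npv_ci: tuple
    threshold: float
    n_cases: int
    n_controls: int
    spec: float = 0.90
    n_boot: int = 2000
    level: float = 0.95
    seed: int = 0
    stable: bool = True

    def to_dict(self):
        return asdict(self)


def roc_summary(
    scores,
    labels,
    spec: float = 0.90,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> RocSummary:
    """Full ROC summary: AUC and sens/PPV/NPV at fixed specificity,
    each with a stratified-bootstrap percentile CI.

    The operating threshold is re-derived on every bootstrap resample,
    so the intervals reflect threshold-selection variability as well.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    auc = roc_auc(scores, labels)
    sens, ppv, npv, thr = metrics_at_specificity(scores, labels, spec)

    def m_sens(s, l):
        return metrics_at_specificity(s, l, spec)[0]

    def m_ppv(s, l):
        return metrics_at_specificity(s, l, spec)[1]

    def m_npv(s, l):
        return metrics_at_specificity(s, l, spec)[2]

    stable = n1 >= 2 and n0 >= 2
    if n_boot == 0:
        auc_ci = sens_ci = ppv_ci = npv_ci = (float("nan"), float("nan"))
    elif stable:
        auc_ci = stratified_bootstrap_ci(roc_auc, scores, labels, n_boot, level, seed)[:2]
        sens_ci = stratified_bootstrap_ci(m_sens, scores, labels, n_boot, level, seed)[:2]
        ppv_ci = stratified_bootstrap_ci(m_ppv, scores, labels, n_boot, level, seed)[:2]
        npv_ci = stratified_bootstrap_ci(m_npv, scores, labels, n_boot, level, seed)[:2]
    else:
        auc_ci = sens_ci = ppv_ci = npv_ci = (float("nan"), float("nan"))
    return RocSummary(
        auc=auc,
        auc_ci=auc_ci,
        sens=sens,
        sens_ci=sens_ci,
        ppv=ppv,
        ppv_ci=ppv_ci,
        npv=npv,
        npv_ci=npv_ci,
        threshold=thr,
        n_cases=n1,
        n_controls=n0,
        spec=spec,
        n_boot=n_boot,
        level=level,
        seed=seed,
        stable=stable,
    )


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    delta: float
    pvalue: float
    n_boot: int
    seed: int
    paired: bool = True
    metric: str = "auc"

    def to_dict(self):
        return asdict(self)


def compare_auc_bootstrap(
    scores_a,
    scores_b,
    labels,
    n_boot: int = 10000,
    seed: int = 0,
    metric: str = "auc",
    spec: float = 0.90,
) -> AucComparison:
    """One-sided paired bootstrap test of H1: metric(a) > metric(b).

    Stratified paired resampling; the bootstrap SD of the difference
    standardizes the observed difference, and the p-value is the upper
    normal tail (half of the two-sided normal p, as in pROC's
    ``roc.test(..., method='bootstrap')``).  ``metric`` may be ``auc``
    or ``sens`` (sensitivity at ``spec``).
    """
    labels = _check_two_classes(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if len(scores_a) != len(scores_b) or len(scores_a) != len(labels):
        raise ValueError("paired comparison requires equal-length score vectors")

    if metric == "auc":
        stat = roc_auc
    elif metric == "sens":
        def stat(s, l):
            return metrics_at_specificity(s, l, spec)[0]
    else:
        raise ValueError(f"unknown metric {metric!r}")

    obs = stat(scores_a, labels) - stat(scores_b, labels)
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(labels == 1)
    idx0 = np.flatnonzero(labels == 0)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([rng.choice(idx1, len(idx1)), rng.choice(idx0, len(idx0))])
        deltas[b] = stat(scores_a[take], labels[take]) - stat(scores_b[take], labels[take])
    sd = float(deltas.std(ddof=1))
    if sd == 0.0:
        p = 0.5 if obs == 0.0 else (0.0 if obs > 0 else 1.0)
    else:
        p = float(stats.norm.sf(obs / sd))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return AucComparison(
        auc_a=float(stat(scores_a, labels)),
        auc_b=float(stat(scores_b, labels)),
        delta=float(obs),
        pvalue=p,
        n_boot=n_boot,
        seed=seed,
        metric=metric,
    )


def evaluate_symptom_subset(
    probabilities,
    labels,
    symptom_flags,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocSummary:
    """ROC summary on the subset of samples carrying a symptom.

    Probabilities must come from an already-trained model; discovery and
    validation probabilities are concatenated upstream, and no refitting
    happens here.  Subsets with fewer than 2 cases or 2 controls are
    flagged unstable and returned without CIs.
    """
    flags = np.asarray(symptom_flags).astype(bool)
    probabilities = np.asarray(probabilities, dtype=float)[flags]
    labels = np.asarray(labels)[flags]
    if len(set(np.unique(labels))) < 2:
        raise ValueError("symptom subset contains a single class")
    return roc_summary(probabilities, labels, n_boot=n_boot, seed=seed)


def qcancer_analysis(
    probabilities,
    labels,
    qcancer,
    thresholds=(2.0, 2.5, 3.0),
    n_boot: int = 2000,
    seed: int = 0,
):
    """Model-vs-QCancer evaluation on QCancer-scored samples.

    For all scored samples and for each score threshold, summarizes
    both the model probabilities and the raw QCancer score as PDAC
    predictors, and reports the Pearson correlation (with t-test
    p-value) between the QCancer score and the model's log-odds.
    """
    q = np.asarray(qcancer, dtype=float)
    scored = np.isfinite(q)
    if not scored.any():
        raise ValueError("no samples carry a QCancer score")
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    p = np.clip(probabilities[scored], 1e-9, 1 - 1e-9)
    log_odds = np.log(p / (1 - p))
    r, r_p = stats.pearsonr(q[scored], log_odds)
    out = {"correlation": {"r": float(r), "p": float(r_p), "n": int(scored.sum())}}
    subsets = {"all": scored}
    for t in thresholds:
        subsets[f">{t:g}"] = scored & (q > t)
    for name, mask in subsets.items():
        entry = {}
        for which, s in (("model", probabilities), ("qcancer", q)):
            sub_l = labels[mask]
            if len(np.unique(sub_l)) < 2:
                entry[which] = None
                continue
            entry[which] = roc_summary(s[mask], sub_l, n_boot=n_boot, seed=seed)
        entry["n"] = int(mask.sum())
        out[name] = entry
    return out
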