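"""Cross-sectional classification performance at fixed follow-up horizons.

Under right censoring, "has the patient developed the outcome by year t?" is
only defined for patients observed long enough: a patient with an event at or
before the horizon is a case, a patient followed event-free through the
horizon is a control, and a patient censored event-free before the horizon is
excluded from that horizon's analysis.  On the resulting case/control sets
the module computes ROC curves with the Hanley-McNeil significance test,
Youden-optimal cutoffs with the full confusion-matrix metrics, and the
rank-based group comparisons used for biomarker box plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "HorizonLabels",
    "RocResult",
    "CutoffMetrics",
    "BoxplotSummary",
    "label_at_horizon",
    "roc_curve",
    "youden_optimal",
    "youden_index",
    "confusion_at_cutoff",
    "mannwhitney_u",
    "pearson_r",
    "boxplot_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class HorizonLabels:
    """Case/control/excluded status of every patient at one horizon."""

    horizon_years: float
    labels: np.ndarray  # strings "case" | "control" | "excluded"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(np.unique(self.labels)) - {"case", "control", "excluded"}
        if bad:
            raise ValueError(f"invalid labels: {bad}")

    @property
    def n_case(self) -> int:
        return int(np.sum(self.labels == "case"))

    @property
    def n_control(self) -> int:
        return int(np.sum(self.labels == "control"))

    @property
    def n_excluded(self) -> int:
        return int(np.sum(self.labels == "excluded"))


def label_at_horizon(times, events, horizon_years: float) -> HorizonLabels:
    """Status-at-horizon labelling under right censoring.

    Event with time <= horizon -> case (boundary inclusive); event-free
    follow-up through the horizon (time >= horizon, including later events)
    -> control; censored event-free before the horizon -> excluded.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if len(times) != len(events):
        raise ValueError("times and events must align")
    if horizon_years <= 0:
        raise ValueError("horizon must be > 0")
    labels = np.where(
        (events == 1) & (times <= horizon_years),
        "case",
        np.where(times >= horizon_years, "control", "excluded"),
    ).astype(object)
    return HorizonLabels(horizon_years, labels)


@dataclass
class RocResult:
    """ROC sweep over the unique observed scores (rule: score >= threshold
    predicts case), with trapezoidal AUC and Hanley-McNeil p against 0.5."""

    thresholds: np.ndarray  # descending unique scores
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_p: float
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    n_case: int
    n_control: int


def _hanley_mcneil_p(auc: float, n_case: int, n_control: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_case - 1) * (q1 - auc * auc)
        + (n_control - 1) * (q2 - auc * auc)
    ) / (n_case * n_control)
    if var <= 0:
        return 1.0 if auc == 0.5 else 0.0
    z = (auc - 0.5) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def roc_curve(scores, labels: HorizonLabels) -> RocResult:
    """ROC of a score against horizon case/control labels.

    Excluded patients are dropped.  The trapezoidal AUC is asserted against
    the tie-corrected rank statistic U/(n_case*n_control) as an internal
    identity before being returned.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(labels.labels):
        raise ValueError("scores must align with labels")
    use = labels.labels != "excluded"
    s = scores[use]
    y = (labels.labels[use] == "case").astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one case and one control")
    thresholds = np.unique(s)[::-1]
    pred = s[None, :] >= thresholds[:, None]
    tp = (pred & (y == 1)).sum(axis=1)
    fp = (pred & (y == 0)).sum(axis=1)
    fn = n1 - tp
    tn = n0 - fp
    se = tp / n1
    sp = tn / n0
    fpr = 1 - sp
    # trapezoid over (0,0) .. per-threshold points .. (1,1)
    xs = np.concatenate([[0.0], fpr, [1.0]])
    ys = np.concatenate([[0.0], se, [1.0]])
    auc = float(np.trapezoid(ys, xs))
    # tie-corrected rank AUC: (concordant + 0.5 * tied) / (n1 * n0)
    ranks = stats.rankdata(s)
    u = float(ranks[y == 1].sum() - n1 * (n1 + 1) / 2)
    auc_rank = u / (n1 * n0)
    if abs(auc - auc_rank) > 1e-9:
        raise AssertionError(
            f"trapezoidal AUC {auc} != rank AUC {auc_rank}; internal inconsistency"
        )
    return RocResult(
        thresholds=thresholds,
        sensitivity=se,
        specificity=sp,
        auc=auc,
        auc_p=_hanley_mcneil_p(auc, n1, n0),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_case=n1,
        n_control=n0,
    )


@dataclass
class CutoffMetrics:
    """Operating characteristics at one cutoff (rule: score >= cutoff)."""

    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None

    def __post_init__(self):
        if abs(self.youden_j - (self.sensitivity + self.specificity - 1)) > 1e-12:
            raise ValueError("youden_j must equal sensitivity + specificity - 1")


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic, J = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def _metrics_from_counts(cutoff, tp, fp, tn, fn) -> CutoffMetrics:
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    npv = tn / (tn + fn) if (tn + fn) > 0 else None
    if ppv is None or npv is None:
        logger.warning("zero-denominator predictive value at cutoff %s reported as absent", cutoff)
    return CutoffMetrics(float(cutoff), youden_index(se, sp), float(se), float(sp), ppv, npv)


def youden_optimal(roc: RocResult) -> CutoffMetrics:
    """The cutoff maximizing J = Se + Sp - 1; ties resolved to the lowest
    qualifying cutoff so one reusable threshold emerges from a fixed score
    distribution."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = j.max()
    idx = np.flatnonzero(j >= best - 1e-12)
    pick = idx[np.argmin(roc.thresholds[idx])]
    return _metrics_from_counts(
        roc.thresholds[pick], roc.tp[pick], roc.fp[pick], roc.tn[pick], roc.fn[pick]
    )


def confusion_at_cutoff(scores, labels: HorizonLabels, cutoff: float) -> CutoffMetrics:
    """Confusion-matrix metrics of ``score >= cutoff`` on the labelled
    case/control sets; zero-denominator predictive values are absent."""
    scores = np.asarray(scores, dtype=float)
    use = labels.labels != "excluded"
    s = scores[use]
    y = (labels.labels[use] == "case").astype(int)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("need at least one case and one control")
    pred = s >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return _metrics_from_counts(cutoff, tp, fp, tn, fn)


# exact Mann-Whitney null enumeration is used when the product of the group
# sizes is at most this and the pooled sample has no ties
_MWU_EXACT_LIMIT = 400


def mannwhitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of group a against group b.

    Exact null enumeration for small untied samples (n_a * n_b <= 400),
    tie-corrected normal approximation otherwise.  Returns (U of group a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= _MWU_EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def boxplot_summary(values) -> BoxplotSummary:
    """Tukey box-plot numbers: median, linear-interpolation quartiles,
    whiskers at the most extreme points within 1.5 IQR, outliers beyond."""
    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise ValueError("need at least 5 values")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotSummary(
        float(med), float(q1), float(q3), float(inside.min()), float(inside.max()), np.sort(outliers)
    )
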