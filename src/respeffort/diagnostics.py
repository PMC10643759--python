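"""Effort classification and diagnostic-accuracy statistics.

Effort is classed low / intermediate / high against the pre-defined
reference bands: Pmus < 5 / 5-10 / > 10 cmH2O, or PTPmus/min < 50 /
50-200 / > 200 cmH2O.s/min (boundary values fall in the intermediate
band).  The accuracy of an airway-pressure index for detecting a class is
summarized by the ROC curve: AUC with a DeLong 95% CI, paired DeLong
comparison between indices, the Youden-index cutoff, the resulting
confusion matrix with exact binomial CIs on sensitivity/specificity/
PPV/NPV, stratified tenfold cross-validation of the cutoff, and
nonparametric 10th/90th-percentile reference intervals with a bootstrap CI
and the fraction of observations in the grey zone.

The AUC uses the Mann-Whitney construction (ties count half); its variance
and the paired test use DeLong's structural components.  ``direction`` is
``"greater"`` when larger index values mark the positive class (high
effort) and ``"lesser"`` when smaller values do (low effort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (DataError, DegenerateLabels, GroupingError,
                     ParameterError, SampleTooSmall)

__all__ = ["EFFORT_BANDS", "EffortClass", "DiagnosticResult",
           "ReferenceInterval", "classify_effort", "roc_auc",
           "compare_auc_delong", "youden_cutoff", "confusion_stats",
           "cross_validate_tenfold", "reference_interval",
           "variance_explained"]

# (low upper bound, high lower bound); boundary values are intermediate
EFFORT_BANDS = {"pmus": (5.0, 10.0), "ptp_min": (50.0, 200.0)}


@dataclass(frozen=True)
class EffortClass:
    criterion: str   # "pmus" | "ptp_min"
    label: str       # "low" | "intermediate" | "high"


def classify_effort(value, criterion: str = "pmus") -> EffortClass:
    """Class label for a reference effort value (or EffortMeasures).

    Strict inequalities define low and high, so values exactly on a band
    edge (5, 10, 50, 200) are intermediate.
    """
    if criterion not in EFFORT_BANDS:
        raise ParameterError(f"unknown criterion {criterion!r}")
    v = getattr(value, "pmus_max" if criterion == "pmus" else "ptp_min", value)
    if v is None or not np.isfinite(v):
        raise DataError(f"no {criterion} value to classify")
    lo, hi = EFFORT_BANDS[criterion]
    label = "low" if v < lo else ("high" if v > hi else "intermediate")
    return EffortClass(criterion=criterion, label=label)


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def _check_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ParameterError("scores and labels must be 1-D and equal length")
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise DegenerateLabels("both classes must be present")
    return scores, labels


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores, labels, direction="greater"):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    scores, labels = _check_binary(scores, labels)
    if direction == "lesser":
        scores = -scores
    elif direction != "greater":
        raise ParameterError(f"direction must be greater|lesser, got {direction!r}")
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = x.size, y.size
    tz = _midrank(np.concatenate([x, y]))
    tx = _midrank(x)
    ty = _midrank(y)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n                  # per positive
    v01 = 1.0 - (tz[m:] - ty) / m            # per negative
    return auc, v10, v01


@dataclass
class DiagnosticResult:
    """ROC summary of one index against one binary reference."""

    auc: float
    auc_ci: tuple[float, float]
    auc_se: float
    direction: str
    cutoff: float | None = None
    youden_j: float | None = None
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    sensitivity: float | None = None
    sensitivity_ci: tuple | None = None
    specificity: float | None = None
    specificity_ci: tuple | None = None
    ppv: float | None = None
    ppv_ci: tuple | None = None
    npv: float | None = None
    npv_ci: tuple | None = None
    per_fold_cutoffs: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def roc_auc(scores, labels, direction: str = "greater",
            alpha: float = 0.05) -> DiagnosticResult:
    """AUC with DeLong standard error and normal-approximation CI."""
    auc, v10, v01 = _delong_components(scores, labels, direction)
    m, n = v10.size, v01.size
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = stats.norm.ppf(1 - alpha / 2)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return DiagnosticResult(auc=float(auc), auc_ci=ci, auc_se=se,
                            direction=direction)


def compare_auc_delong(scores_a, scores_b, labels,
                       direction: str = "greater") -> tuple[float, float]:
    """Paired DeLong test between two correlated AUCs on the same labels.

    Returns ``(z, p)``; the covariance of the two AUCs comes from the
    covariance of their structural components over the shared cases.
    """
    auc_a, v10a, v01a = _delong_components(scores_a, labels, direction)
    auc_b, v10b, v01b = _delong_components(scores_b, labels, direction)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 1e-15:
        return 0.0, 1.0
    z = float((auc_a - auc_b) / np.sqrt(var_diff))
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p


# ---------------------------------------------------------------------------
# cutoffs and confusion statistics
# ---------------------------------------------------------------------------

def _predict(scores: np.ndarray, cutoff: float, direction: str) -> np.ndarray:
    return scores >= cutoff if direction == "greater" else scores <= cutoff


def youden_cutoff(scores, labels, direction: str = "greater"
                  ) -> tuple[float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between adjacent distinct scores
    (plus open ends); ties in J are broken toward higher specificity
    (the more extreme cutoff).
    """
    scores, labels = _check_binary(scores, labels)
    uniq = np.unique(scores)
    mids = (uniq[1:] + uniq[:-1]) / 2.0
    step = (uniq[-1] - uniq[0]) / 2.0 or 1.0
    # midpoints realize every achievable confusion matrix under the >=
    # rule; the open ends realize the all-negative / all-positive calls
    cands = np.concatenate([[uniq[0] - step], mids, [uniq[-1] + step]])
    best_j, best_c = -np.inf, cands[0]
    order = np.sort(cands)
    if direction == "greater":
        order = order[::-1]   # scan from most-specific end; ties keep first
    for c in order:
        pred = _predict(scores, c, direction)
        tp = int(np.sum(pred & (labels == 1)))
        fn = int(np.sum(~pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        fp = int(np.sum(pred & (labels == 0)))
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c), float(best_j)


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def confusion_stats(scores, labels, cutoff: float,
                    direction: str = "greater", alpha: float = 0.05,
                    result: DiagnosticResult | None = None) -> DiagnosticResult:
    """Confusion matrix and proportions with exact (Clopper-Pearson) CIs.

    A proportion whose denominator is empty is reported as ``None`` rather
    than zero.  When ``result`` is given its ROC fields are kept and the
    confusion fields filled in.
    """
    scores, labels = _check_binary(scores, labels)
    if not np.isfinite(cutoff):
        raise ParameterError("cutoff must be finite")
    pred = _predict(scores, cutoff, direction)
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    out = result or DiagnosticResult(auc=np.nan, auc_ci=(np.nan, np.nan),
                                     auc_se=np.nan, direction=direction)
    out.cutoff = float(cutoff)
    out.tp, out.fp, out.tn, out.fn = tp, fp, tn, fn

    def prop(k, n):
        if n == 0:
            return None, None
        return k / n, _clopper_pearson(k, n, alpha)

    out.sensitivity, out.sensitivity_ci = prop(tp, tp + fn)
    out.specificity, out.specificity_ci = prop(tn, tn + fp)
    out.ppv, out.ppv_ci = prop(tp, tp + fp)
    out.npv, out.npv_ci = prop(tn, tn + fn)
    return out


def cross_validate_tenfold(scores, labels, direction: str = "greater",
                           seed: int = 0, n_splits: int = 10) -> dict:
    """Stratified k-fold stability check of the Youden cutoff.

    Per fold the cutoff is fitted on the training split and applied to the
    held-out split; test predictions are pooled into one confusion matrix.
    Folds whose training or test split loses a class are flagged and
    excluded from pooling.
    """
    from sklearn.model_selection import StratifiedKFold

    scores, labels = _check_binary(scores, labels)
    if scores.size < n_splits:
        raise DataError(f"need at least {n_splits} observations")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    cutoffs, excluded = [], []
    tp = fp = tn = fn = 0
    for k, (tr, te) in enumerate(skf.split(scores.reshape(-1, 1), labels)):
        if len(set(labels[tr])) < 2 or len(set(labels[te])) < 2:
            excluded.append(k)
            continue
        c, _ = youden_cutoff(scores[tr], labels[tr], direction)
        cutoffs.append(c)
        pred = _predict(scores[te], c, direction)
        tp += int(np.sum(pred & (labels[te] == 1)))
        fp += int(np.sum(pred & (labels[te] == 0)))
        tn += int(np.sum(~pred & (labels[te] == 0)))
        fn += int(np.sum(~pred & (labels[te] == 1)))
    pooled = {
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
        "ppv": tp / (tp + fp) if (tp + fp) else None,
        "npv": tn / (tn + fn) if (tn + fn) else None,
    }
    return {"fold_cutoffs": cutoffs, "excluded_folds": excluded,
            "pooled": pooled, "counts": (tp, fp, tn, fn)}


# ---------------------------------------------------------------------------
# reference intervals and association strength
# ---------------------------------------------------------------------------

@dataclass
class ReferenceInterval:
    lower: float
    upper: float
    lower_ci: tuple[float, float]
    upper_ci: tuple[float, float]
    grey_zone_fraction: float
    percentiles: tuple[float, float] = (10.0, 90.0)


def reference_interval(values, seed: int = 0, *, n_boot: int = 2000,
                       percentiles: tuple[float, float] = (10.0, 90.0),
                       alpha: float = 0.05) -> ReferenceInterval:
    """Nonparametric reference interval with bootstrap CIs on each limit.

    Limits are the 10th and 90th percentiles (linear interpolation); their
    CIs come from a seeded bootstrap.  ``grey_zone_fraction`` is the share
    of the sample lying outside [lower, upper] — by the percentile
    definition about 0.2 of the sample itself.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 20:
        raise SampleTooSmall(f"need >= 20 observations, got {values.size}")
    lo_p, hi_p = percentiles
    lower, upper = np.percentile(values, [lo_p, hi_p])
    rng = np.random.default_rng(seed)
    boots = np.percentile(
        rng.choice(values, size=(n_boot, values.size), replace=True),
        [lo_p, hi_p], axis=1)
    lci = tuple(np.percentile(boots[0], [100 * alpha / 2, 100 * (1 - alpha / 2)]))
    uci = tuple(np.percentile(boots[1], [100 * alpha / 2, 100 * (1 - alpha / 2)]))
    grey = float(np.mean((values < lower) | (values > upper)))
    return ReferenceInterval(lower=float(lower), upper=float(upper),
                             lower_ci=(float(lci[0]), float(lci[1])),
                             upper_ci=(float(uci[0]), float(uci[1])),
                             grey_zone_fraction=grey, percentiles=percentiles)


def variance_explained(x, y, patient_ids) -> tuple[float, float]:
    """Between- and within-patient R-squared of y on x.

    Between: least-squares R^2 on the patient means.  Within: R^2 on the
    pooled observations after subtracting each patient's mean from both
    variables (the analysis-of-covariance decomposition used to summarize
    association under repeated measures).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = np.asarray(patient_ids)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, ids = x[ok], y[ok], ids[ok]
    groups = np.unique(ids)
    if groups.size < 2:
        raise GroupingError("need at least two patients")
    counts = np.array([np.sum(ids == g) for g in groups])
    if np.any(counts < 2):
        raise GroupingError("every patient needs at least two observations")
    mx = np.array([x[ids == g].mean() for g in groups])
    my = np.array([y[ids == g].mean() for g in groups])
    # center within patients
    xc = x.copy()
    yc = y.copy()
    for g in groups:
        sel = ids == g
        xc[sel] -= x[sel].mean()
        yc[sel] -= y[sel].mean()

    def r2(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            raise GroupingError("degenerate (constant) variable in R^2")
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    return r2(mx, my), r2(xc, yc)
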