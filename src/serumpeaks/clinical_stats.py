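"""Validation-layer statistics: ROC/AUC with confidence interval, Youden
optimal cutoff, marker combination by logistic regression, group-comparison
utilities, and Kaplan-Meier survival analysis with ROC-derived
dichotomization.

The ROC curve is the empirical curve over all distinct score thresholds; the
AUC is computed by the Mann-Whitney identity (ties count 0.5), which equals
the trapezoid rule on the empirical curve. The 95% confidence interval uses
the Hanley-McNeil analytic standard error. The reported Youden cutoff is a
score-space value: candidate cutoffs are the midpoints between consecutive
distinct scores, and among tied-J candidates the one closest to the median
score is reported (the midpoint of the two closest if equidistant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .exceptions import ParameterError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    """Empirical ROC curve with AUC, CI and Youden-optimal operating point."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci_95: tuple
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    positive_high: bool = True

    def __post_init__(self):
        if not 0 <= self.auc <= 1:
            raise ValidationError(f"AUC {self.auc} outside [0, 1]")
        lo, hi = self.auc_ci_95
        if not (lo - 1e-12 <= self.auc <= hi + 1e-12):
            raise ValidationError("confidence interval does not contain the AUC")
        if np.any(np.diff(self.tpr) < -1e-12) or np.any(np.diff(self.fpr) < -1e-12):
            raise ValidationError("tpr/fpr must be non-decreasing along the sweep")

    @property
    def youden(self) -> float:
        return self.sens_at_cutoff + self.spec_at_cutoff - 1.0

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_95": [float(self.auc_ci_95[0]), float(self.auc_ci_95[1])],
            "youden_cutoff": float(self.youden_cutoff),
            "sensitivity_pct": round(100 * self.sens_at_cutoff, 1),
            "specificity_pct": round(100 * self.spec_at_cutoff, 1),
            "positive_high": self.positive_high,
        }


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int) -> tuple:
    """Hanley & McNeil (1982) analytic 95% CI for an empirical AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    return (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))


def roc_analysis(
    scores, labels, positive_high: bool = True
) -> RocResult:
    """Empirical ROC analysis of a continuous score against binary labels.

    ``positive_high=False`` treats *low* scores as indicating the positive
    class (e.g. a marker down-regulated in disease); the reported cutoff
    stays in original score units, with positives predicted at or below it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ParameterError("scores and labels must be equal-length 1-D")
    if not np.all(np.isfinite(scores)):
        raise ParameterError("scores must be finite")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes must be present")
    if np.ptp(scores) == 0:
        raise ParameterError("scores are constant; ROC analysis is undefined")

    s = scores if positive_high else -scores

    # AUC via the Mann-Whitney identity (= trapezoid on the empirical curve)
    ranks = sps.rankdata(s)
    u = float(ranks[labels == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    # empirical curve: predict positive when s >= t, t over distinct scores
    distinct = np.unique(s)[::-1]
    thresholds = np.concatenate([[np.inf], distinct])
    tpr = np.array([(s[labels == 1] >= t).mean() for t in thresholds])
    fpr = np.array([(s[labels == 0] >= t).mean() for t in thresholds])

    # Youden cutoff: midpoints between consecutive distinct values
    asc = distinct[::-1]
    if len(asc) == 1:  # unreachable (constant scores rejected above)
        candidates = np.array([asc[0]])
    else:
        candidates = (asc[:-1] + asc[1:]) / 2.0
    sens_c = np.array([(s[labels == 1] > c).mean() for c in candidates])
    spec_c = np.array([(s[labels == 0] <= c).mean() for c in candidates])
    j = sens_c + spec_c - 1.0
    best = np.flatnonzero(np.isclose(j, j.max(), atol=1e-12))
    if len(best) == 1:
        cut = candidates[best[0]]
        k = best[0]
    else:
        med = np.median(s)
        dist = np.abs(candidates[best] - med)
        closest = best[np.flatnonzero(np.isclose(dist, dist.min()))]
        cut = float(np.mean(candidates[closest]))
        k = closest[0]
    sens, spec = float(sens_c[k]), float(spec_c[k])

    if not positive_high:
        thresholds = -thresholds
        cut = -cut
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=float(auc),
        auc_ci_95=_hanley_mcneil_ci(auc, n_pos, n_neg),
        youden_cutoff=float(cut),
        sens_at_cutoff=sens,
        spec_at_cutoff=spec,
        positive_high=positive_high,
    )


# ---------------------------------------------------------------------------
# Marker combination
# ---------------------------------------------------------------------------


def combine_markers(
    features: pd.DataFrame, labels, binary_cols: list | None = None
) -> tuple[pd.Series, RocResult]:
    """Combine markers into one score by additive logistic regression.

    Continuous features are z-scored; binary features (auto-detected as
    taking at most two distinct values, or named in ``binary_cols``) enter
    as-is. Rows with any missing value are dropped (logged). On perfect
    separation the fit falls back to a ridge-penalized logistic model (the
    penalty is logged), never to failure. The combined score is the fitted
    linear predictor; its ROC is computed with :func:`roc_analysis`.
    """
    if features.empty:
        raise ParameterError("feature table is empty")
    labels = pd.Series(np.asarray(labels).astype(int), index=features.index)
    keep = features.notna().all(axis=1)
    if (~keep).any():
        logger.info("dropping %d rows with missing feature values", int((~keep).sum()))
    X = features.loc[keep].copy()
    y = labels.loc[keep]
    if X.empty:
        raise ParameterError("no complete rows to fit on")

    if binary_cols is None:
        binary_cols = [c for c in X.columns if X[c].nunique() <= 2]
    cols = []
    for c in X.columns:
        if X[c].nunique() <= 1:
            logger.warning("feature %r is constant across samples; dropped", c)
            continue
        if c in binary_cols:
            cols.append(X[c].astype(float))
        else:
            v = X[c].astype(float)
            cols.append((v - v.mean()) / v.std(ddof=0))
    if not cols:
        raise ParameterError("no informative features remain after dropping constants")
    design = pd.concat(cols, axis=1)

    import statsmodels.api as sm

    Xd = sm.add_constant(design.to_numpy(), has_constant="add")
    beta = None
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y.to_numpy(), Xd).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(fit.params)) and fit.mle_retvals.get("converged", False):
            beta = fit.params
    except Exception:
        beta = None
    if beta is None:
        from sklearn.linear_model import LogisticRegression

        logger.warning(
            "logistic MLE failed (perfect separation or non-convergence); "
            "falling back to ridge-penalized fit (C=1.0)"
        )
        lr = LogisticRegression(C=1.0, max_iter=1000)
        lr.fit(design.to_numpy(), y.to_numpy())
        beta = np.concatenate([lr.intercept_, lr.coef_.ravel()])

    score = pd.Series(Xd @ beta, index=design.index, name="combined_score")
    roc = roc_analysis(score.to_numpy(), y.to_numpy(), positive_high=True)
    return score, roc


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def group_compare(values, group_labels, design: str = "t_test") -> tuple[float, float]:
    """Two-sided group comparison: Student t, Welch t, or one-way ANOVA.

    Boundary handling: groups whose values are all identical *and* equal
    across groups give (0, p=1); zero within-group variance everywhere with
    unequal means is an error (the statistic diverges).
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    levels = pd.unique(group_labels)
    samples = [values[group_labels == g] for g in levels]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ParameterError("need >= 2 groups with >= 2 values each")
    if design in ("t_test", "welch") and len(samples) != 2:
        raise ParameterError(f"{design} requires exactly 2 groups, got {len(samples)}")

    if all(np.ptp(s) == 0 for s in samples):
        means = [s[0] for s in samples]
        if np.ptp(means) == 0:
            return 0.0, 1.0  # identical constant groups: no evidence
        raise ParameterError(
            "zero within-group variance in all groups with unequal means"
        )
    if design == "t_test":
        res = sps.ttest_ind(samples[0], samples[1], equal_var=True)
    elif design == "welch":
        res = sps.ttest_ind(samples[0], samples[1], equal_var=False)
    elif design == "anova":
        res = sps.f_oneway(*samples)
    else:
        raise ParameterError(f"unknown design {design!r}")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalRecord:
    """One subject's follow-up with a continuous marker value."""

    time: float
    event: int
    expression: float
    group: str | None = None  # "high" | "low" once dichotomized

    def __post_init__(self):
        if self.time <= 0:
            raise ValidationError("survival time must be > 0")
        if self.event not in (0, 1):
            raise ValidationError("event must be 0 (censored) or 1 (death)")


def dichotomize_by_outcome_roc(expression, outcome) -> tuple[float, np.ndarray]:
    """Split subjects into high/low marker groups at the Youden-optimal cutoff.

    The cutoff maximizes Youden's J for predicting the binary outcome from
    the expression value; the orientation (high-positive or low-positive) is
    chosen to put the AUC at or above 0.5. Returns the cutoff and an array
    of ``"high"``/``"low"`` labels (``expression > cutoff`` is high).
    """
    expression = np.asarray(expression, dtype=float)
    outcome = np.asarray(outcome).astype(int)
    auc_high = roc_analysis(expression, outcome, positive_high=True).auc
    res = roc_analysis(expression, outcome, positive_high=auc_high >= 0.5)
    cutoff = res.youden_cutoff
    groups = np.where(expression > cutoff, "high", "low")
    return float(cutoff), groups


def km_logrank(records: pd.DataFrame) -> tuple[dict, float, float]:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    ``records`` needs columns ``time``, ``event``, ``group`` (two levels).
    Returns ``(curves, chi2, p)`` where ``curves[group]`` is the product-
    limit estimate as a DataFrame indexed by time. Ties use the standard
    hypergeometric variance; p is two-sided from chi-square with 1 df.
    """
    for col in ("time", "event", "group"):
        if col not in records.columns:
            raise ParameterError(f"records table lacks required column {col!r}")
    if (records["time"] <= 0).any():
        raise ValidationError("survival times must be > 0")
    levels = pd.unique(records["group"])
    if len(levels) != 2:
        raise ParameterError(f"log-rank test needs exactly 2 groups, got {len(levels)}")
    if int(records["event"].sum()) == 0:
        raise ParameterError("no events observed; log-rank test is undefined")
    a = records[records["group"] == levels[0]]
    b = records[records["group"] == levels[1]]
    curves = {}
    for name, sub in ((levels[0], a), (levels[1], b)):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(name))
        curves[name] = kmf.survival_function_
    res = logrank_test(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return curves, float(res.test_statistic), float(res.p_value)
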