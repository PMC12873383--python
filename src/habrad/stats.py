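"""Evaluation statistics: ROC/AUC with DeLong variance, the paired DeLong
test, confusion metrics, decision-curve analysis, ICC and chi-square.

The AUC is the Mann-Whitney concordance (ties count 1/2); its variance and
the covariance between two correlated AUCs come from DeLong's structural
components: for each positive subject the mean concordance against all
negatives (V10), and vice versa (V01).  Net benefit at threshold
probability pt is TP/n - (FP/n) * pt / (1 - pt).  The ICC is the two-way
random-effects, absolute-agreement, single-measure form ICC(2,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    variance: float
    ci95: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


def _structural_components(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    # psi(x, y): 1 if x > y, 0.5 if tied, 0 otherwise
    psi = (pos[:, None] > neg[None, :]).astype(np.float64)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01


def roc_auc(scores, labels, logit_ci: bool = False) -> ROCResult:
    """AUC with DeLong variance and 95% CI, plus the full ROC curve."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    v10, v01 = _structural_components(scores, labels)
    m, n = len(v10), len(v01)
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = np.sqrt(var)
    if logit_ci and 0 < auc < 1 and se > 0:
        logit = np.log(auc / (1 - auc))
        se_l = se / (auc * (1 - auc))
        lo = 1 / (1 + np.exp(-(logit - 1.96 * se_l)))
        hi = 1 / (1 + np.exp(-(logit + 1.96 * se_l)))
    else:
        lo, hi = auc - 1.96 * se, auc + 1.96 * se
    ci = (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))

    order = np.argsort(-scores, kind="stable")
    y = np.asarray(labels)[order]
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), len(y) - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / m]
    fpr = np.r_[0.0, fps / n]
    thr = np.r_[np.inf, scores[order][distinct]]
    return ROCResult(auc, var, ci, fpr, tpr, thr, m, n)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired DeLong comparison of two correlated AUCs.

    Returns ``(auc_a - auc_b, z, two-sided p)``.  Identical score vectors
    give (0, 0, 1); zero variance with a nonzero difference is degenerate
    and signalled with a warning (p = 0).
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must cover the same subjects")
    va10, va01 = _structural_components(scores_a, labels)
    vb10, vb01 = _structural_components(scores_b, labels)
    m, n = len(va10), len(va01)
    diff = float(va10.mean() - vb10.mean())
    if m > 1:
        s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        if diff == 0:
            return 0.0, 0.0, 1.0
        warnings.warn("degenerate DeLong variance with unequal AUCs",
                      RuntimeWarning)
        return diff, float(np.sign(diff) * np.inf), 0.0
    z = diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return diff, float(z), float(p)


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float


def confusion_metrics(predicted, labels) -> ConfusionSummary:
    predicted = np.asarray(predicted).astype(np.int64)
    labels = np.asarray(labels).astype(np.int64)
    tp = int(np.sum((predicted == 1) & (labels == 1)))
    fp = int(np.sum((predicted == 1) & (labels == 0)))
    fn = int(np.sum((predicted == 0) & (labels == 1)))
    tn = int(np.sum((predicted == 0) & (labels == 0)))
    n = tp + fp + fn + tn
    return ConfusionSummary(
        tp, fp, fn, tn,
        accuracy=(tp + tn) / n if n else 0.0,
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
    )


# ---------------------------------------------------------------------------
# decision-curve analysis
# ---------------------------------------------------------------------------

@dataclass
class DCACurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    n: int


def decision_curve(probabilities, labels,
                   thresholds: np.ndarray | None = None) -> DCACurve:
    """Net benefit of the model vs treat-all / treat-none references.

    At each threshold pt subjects with probability >= pt are classified
    positive; net benefit = TP/n - (FP/n) * pt/(1-pt).
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels).astype(np.int64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prevalence = y.mean()
    pos = p[:, None] >= thresholds[None, :]
    tp = (pos & (y == 1)[:, None]).sum(axis=0) / n
    fp = (pos & (y == 0)[:, None]).sum(axis=0) / n
    w = thresholds / (1 - thresholds)
    nb = tp - fp * w
    treat_all = prevalence - (1 - prevalence) * w
    return DCACurve(thresholds, nb, treat_all, np.zeros_like(nb), n)


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------

def icc_absolute_agreement(measurements: np.ndarray) -> float:
    """Two-way random-effects, single-measure, absolute-agreement ICC.

    ``measurements`` is subjects x raters (or sessions).  Computed from the
    ANOVA mean squares: (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    X = np.asarray(measurements, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 3 subjects and >= 2 raters")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_total = ((X - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("zero total variance: ICC undefined")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def demographics_chisquare(table_2x2, yates: bool = True
                           ) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1.

    With ``yates`` the continuity correction subtracts 0.5 from each
    |O - E| (floored at 0) before squaring.
    """
    obs = np.asarray(table_2x2, dtype=np.float64)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin")
    expected = row @ col / total
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return stat, p


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Everything the pipeline reports for one model configuration."""

    k: int
    train_roc: ROCResult
    validation_roc: ROCResult
    train_confusion: ConfusionSummary
    validation_confusion: ConfusionSummary
    validation_dca: DCACurve
    silhouette: float | None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def roc_d(r: ROCResult):
            return {"auc": r.auc, "variance": r.variance, "ci95": list(r.ci95),
                    "n_pos": r.n_pos, "n_neg": r.n_neg}

        def conf_d(c: ConfusionSummary):
            return {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
                    "accuracy": c.accuracy, "sensitivity": c.sensitivity,
                    "specificity": c.specificity}

        return {
            "k": self.k,
            "train_roc": roc_d(self.train_roc),
            "validation_roc": roc_d(self.validation_roc),
            "train_confusion": conf_d(self.train_confusion),
            "validation_confusion": conf_d(self.validation_confusion),
            "silhouette": self.silhouette,
            "extras": self.extras,
        }
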