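"""Diagnostic validation of screening scores against the binary outcome.

Confusion-matrix metrics (sensitivity, specificity, PPV, NPV), ROC curves
with the tie-corrected rank AUC and DeLong 95% confidence intervals, Pearson
correlation with Fisher-z intervals, simple least-squares fits, and the
uncorrected 2x2 Pearson chi-square used for group comparisons of binary
exposure items.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import DiagnosticReport, ValidationError


# ---------------------------------------------------------------------------
# confusion metrics

def confusion_metrics(predicted, outcome) -> DiagnosticReport:
    """Diagnostic report from binary predictions vs binary outcome.

    sens = TP/(TP+FN), spec = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN).
    A zero denominator yields NaN with the metric name recorded in
    ``undefined`` — never a silent 0.
    """
    p = np.asarray(predicted, dtype=int)
    y = np.asarray(outcome, dtype=int)
    if p.shape != y.shape:
        raise ValidationError(f"length mismatch: {p.shape} vs {y.shape}")
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome must contain both classes")
    tp = int(((p == 1) & (y == 1)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return DiagnosticReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class RocCurve:
    """ROC curve with AUC, DeLong 95% CI and the AUC-vs-0.5 normal test.

    ``points`` holds one row per distinct score threshold for each of the two
    point conventions ("gt": positive iff score > t; "ge": positive iff
    score >= t).
    """

    auc: float
    ci95: tuple[float, float]
    p_value: float
    n_pos: int
    n_neg: int
    points: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "ci95": list(self.ci95), "p_value": self.p_value,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }


def auc_mann_whitney(scores, outcome) -> float:
    """Tie-corrected rank AUC: [#(pos > neg) + 1/2 #(pos = neg)] / (n1 n0)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("outcome must contain both classes")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of the AUC via midrank structural components."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    # V10_i = P(neg < pos_i) + 1/2 P(neg = pos_i); V01_j symmetric
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, outcome) -> RocCurve:
    """ROC curve and AUC with DeLong 95% CI.

    The AUC is the tie-corrected rank statistic; the trapezoidal area of the
    ROC curve agrees with it to numerical precision (asserted in tests).
    The p-value is the two-sided normal test of AUC = 0.5 with the DeLong
    variance.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    auc = auc_mann_whitney(s, y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    var = _delong_variance(s, y)
    se = math.sqrt(var)
    zcrit = stats.norm.ppf(0.975)
    lo = max(0.0, auc - zcrit * se)
    hi = min(1.0, auc + zcrit * se)
    if se > 0:
        p = 2 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 0.0 if auc != 0.5 else 1.0

    thresholds = np.unique(s)
    rows = []
    for convention in ("gt", "ge"):
        # add sentinels so the curve spans (0,0) .. (1,1)
        tgrid = (
            np.concatenate([thresholds, [np.inf]]) if convention == "gt"
            else np.concatenate([[-np.inf], thresholds, [np.inf]])
        )
        for t in tgrid:
            pred = (s > t) if convention == "gt" else (s >= t)
            sens = pred[y == 1].mean()
            fpr = pred[y == 0].mean()
            rows.append({"convention": convention, "threshold": t,
                         "sensitivity": sens, "fpr": fpr})
    points = pd.DataFrame(rows)
    return RocCurve(auc=auc, ci95=(lo, hi), p_value=float(p),
                    n_pos=n_pos, n_neg=n_neg, points=points)


def roc_trapezoid_area(curve: RocCurve, convention: str = "gt") -> float:
    """Trapezoidal area under the (FPR, sensitivity) curve."""
    pts = curve.points[curve.points["convention"] == convention]
    pts = pts.sort_values(["fpr", "sensitivity"])
    x = np.concatenate([[0.0], pts["fpr"].to_numpy(), [1.0]])
    yv = np.concatenate([[0.0], pts["sensitivity"].to_numpy(), [1.0]])
    return float(np.trapezoid(yv, x))


# ---------------------------------------------------------------------------
# correlation / regression

def pearson_ci(x, y, alpha: float = 0.05) -> dict:
    """Pearson r with a Fisher-z confidence interval (z +- z_crit/sqrt(n-3))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValidationError("need n >= 4 for a Fisher-z interval")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(r)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit / math.sqrt(n - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    return {"r": float(r), "ci95": (float(lo), float(hi)), "p": float(p), "n": n}


def ols_simple(x, y) -> dict:
    """Simple least-squares line y = a + b x; r^2 equals squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValidationError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValidationError("constant predictor")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope), "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue ** 2), "p": float(fit.pvalue),
        "stderr": float(fit.stderr),
    }


# ---------------------------------------------------------------------------
# 2x2 chi-square

def chisq_2x2(a: int, b: int, c: int, d: int, *, correction: bool = False) -> dict:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], df = 1.

    Uncorrected by default (Yates continuity correction behind the flag):
    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    cells = np.array([[a, b], [c, d]], dtype=float)
    if (cells < 0).any() or np.any(np.modf(cells)[0] != 0):
        raise ValidationError("cell counts must be non-negative integers")
    margins = np.concatenate([cells.sum(axis=0), cells.sum(axis=1)])
    if (margins == 0).any():
        raise ValidationError("chi-square undefined with a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(cells, correction=correction)
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}


# ---------------------------------------------------------------------------
# full report

def evaluate_screening(
    scores: pd.Series,
    outcome: pd.Series,
    richness: pd.Series | None = None,
    cutoff: int | None = None,
) -> DiagnosticReport:
    """Complete diagnostic report for a screening score.

    Applies the model's "positive iff score > cutoff" rule (when a cutoff is
    given), computes confusion metrics, the ROC AUC with DeLong CI, and — if
    richness values are supplied — the Pearson correlation between score and
    richness with its Fisher-z interval.
    """
    outcome = outcome.reindex(scores.index)
    if outcome.isna().any():
        raise ValidationError("outcome missing for some scored subjects")
    curve = roc_auc(scores.to_numpy(), outcome.to_numpy())
    if cutoff is not None:
        pred = (scores.to_numpy() > cutoff).astype(int)
        report = confusion_metrics(pred, outcome.to_numpy())
    else:
        report = confusion_metrics(
            (scores.to_numpy() > np.median(scores)).astype(int), outcome.to_numpy()
        )
    report.auc = curve.auc
    report.auc_ci95 = curve.ci95
    report.auc_p = curve.p_value
    if richness is not None:
        corr = pearson_ci(scores.to_numpy(), richness.reindex(scores.index).to_numpy())
        report.pearson_r = corr["r"]
        report.pearson_ci95 = corr["ci95"]
    return report
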