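"""Method-comparison statistics for eGFR validation.

Everything here operates on complete pairs of estimated and measured GFR
(both in ml/min/1.73 m²). Conventions:

* error = eGFR − mGFR, so positive bias means systematic overestimation;
* bias = mean error, precision = sample SD of the error (n−1 denominator);
* P15/P30/P50 accuracy = percentage of patients with |error|/mGFR within
  the tolerance;
* limits of agreement = bias ± 1.96 × precision (Bland–Altman);
* ROC AUC treats low measured GFR (default < 60 ml/min/1.73 m², the KDIGO
  CKD threshold) as the positive class and scores patients by −eGFR so
  that an informative estimator yields AUC ≥ 0.5.

Pairwise equation comparisons follow clinical method-comparison practice:
a paired t test on signed per-patient error differences for bias, and a
McNemar test on within-tolerance discordance for accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "ValidationMetrics",
    "PairedComparison",
    "CorrelationResult",
    "McNemarResult",
    "error_vector",
    "bias_precision",
    "accuracy_within",
    "limits_of_agreement",
    "pearson_correlation",
    "roc_auc",
    "roc_points",
    "sensitivity_at_threshold",
    "youden_threshold",
    "paired_bias_test",
    "mcnemar_accuracy_test",
    "validate_equation",
]

#: Exact discordant-pair count below which the McNemar p-value is computed
#: from the binomial distribution rather than the chi-square approximation.
MCNEMAR_EXACT_LIMIT = 25


@dataclass
class CorrelationResult:
    """Pearson correlation with the univariate regression line."""

    r: float
    slope: float
    intercept: float
    p_value: float


@dataclass
class McNemarResult:
    statistic: float
    p_value: float
    b: int  # first within tolerance, second not
    c: int  # second within tolerance, first not
    degenerate: bool = False


@dataclass
class ValidationMetrics:
    """One equation's full validation panel against measured GFR."""

    equation: str
    n: int
    bias: float
    precision: float
    p15: float
    p30: float
    p50: float
    pearson_r: float
    slope: float
    intercept: float
    loa_lower: float
    loa_upper: float
    roc_auc: float
    sensitivity: float
    youden_cutoff: Optional[float] = None
    youden_sensitivity: Optional[float] = None


@dataclass
class PairedComparison:
    equation_a: str
    equation_b: str
    n: int
    bias_t_statistic: float
    bias_p_value: float
    mcnemar_statistic: float
    mcnemar_p_value: float
    mcnemar_degenerate: bool = False


def error_vector(egfr, mgfr) -> np.ndarray:
    """Per-patient differences eGFR − mGFR (positive = overestimation)."""
    egfr = np.asarray(egfr, dtype=float)
    mgfr = np.asarray(mgfr, dtype=float)
    if egfr.shape != mgfr.shape:
        raise ValueError(f"length mismatch: {egfr.shape} vs {mgfr.shape}")
    if egfr.size < 1:
        raise ValueError("need at least one pair")
    if np.any(np.isnan(egfr)) or np.any(np.isnan(mgfr)):
        raise ValueError("complete pairs only; drop missing values first")
    return egfr - mgfr


def bias_precision(errors) -> tuple[float, float]:
    """Mean (bias) and sample SD with n−1 denominator (precision)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("precision needs at least two errors")
    return float(np.mean(errors)), float(np.std(errors, ddof=1))


def accuracy_within(egfr, mgfr, tolerance: float) -> float:
    """Percentage of pairs with |eGFR − mGFR| / mGFR ≤ tolerance."""
    egfr = np.asarray(egfr, dtype=float)
    mgfr = np.asarray(mgfr, dtype=float)
    if np.any(mgfr <= 0):
        raise ValueError("measured GFR must be positive for relative accuracy")
    err = error_vector(egfr, mgfr)
    within = np.abs(err) / mgfr <= tolerance
    return float(100.0 * np.count_nonzero(within) / within.size)


def within_tolerance(egfr, mgfr, tolerance: float) -> np.ndarray:
    """Boolean per-patient within-tolerance indicator (P30-style)."""
    egfr = np.asarray(egfr, dtype=float)
    mgfr = np.asarray(mgfr, dtype=float)
    if np.any(mgfr <= 0):
        raise ValueError("measured GFR must be positive for relative accuracy")
    return np.abs(error_vector(egfr, mgfr)) / mgfr <= tolerance


def limits_of_agreement(bias: float, precision: float) -> tuple[float, float]:
    """Bland–Altman 95 % limits: (bias − 1.96·SD, bias + 1.96·SD)."""
    if precision < 0:
        raise ValueError("precision must be non-negative")
    half = 1.96 * precision
    return bias - half, bias + half


def pearson_correlation(egfr, mgfr) -> CorrelationResult:
    """Pearson r plus the univariate regression of eGFR on mGFR."""
    egfr = np.asarray(egfr, dtype=float)
    mgfr = np.asarray(mgfr, dtype=float)
    if egfr.shape != mgfr.shape or egfr.size < 3:
        raise ValueError("need at least three complete pairs")
    if np.std(egfr) == 0 or np.std(mgfr) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.linregress(mgfr, egfr)
    return CorrelationResult(
        r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
    )


def roc_auc(scores, positive, lower_indicates_positive: bool = True) -> float:
    """Mann–Whitney ROC area, ties counted ½.

    With ``lower_indicates_positive`` (the default for eGFR scoring low GFR
    disease) the score is negated before ranking so an informative
    estimator yields AUC ≥ 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if scores.shape != positive.shape:
        raise ValueError("scores and labels must align")
    if positive.all() or not positive.any():
        raise ValueError("need at least one positive and one negative label")
    oriented = -scores if lower_indicates_positive else scores
    return float(roc_auc_score(positive, oriented))


def roc_points(scores, positive, lower_indicates_positive: bool = True):
    """(FPR, TPR, threshold) arrays for the ROC step function."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if positive.all() or not positive.any():
        raise ValueError("need at least one positive and one negative label")
    oriented = -scores if lower_indicates_positive else scores
    fpr, tpr, thr = roc_curve(positive, oriented)
    if lower_indicates_positive:
        thr = -thr
    return fpr, tpr, thr


def sensitivity_at_threshold(egfr, mgfr, threshold: float = 60.0) -> float:
    """Fraction of true low-GFR patients (mGFR < threshold) flagged by
    eGFR < threshold."""
    egfr = np.asarray(egfr, dtype=float)
    mgfr = np.asarray(mgfr, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cases = mgfr < threshold
    if not cases.any():
        raise ValueError("no true positive cases below threshold")
    return float(np.count_nonzero(egfr[cases] < threshold) / np.count_nonzero(cases))


def youden_threshold(egfr, mgfr, threshold: float = 60.0):
    """Operating point maximising sensitivity + specificity − 1.

    Returns (eGFR cutoff, sensitivity at that cutoff) for classifying
    mGFR < threshold; emitted for reference alongside the fixed clinical
    cutoff.
    """
    positive = np.asarray(mgfr, dtype=float) < threshold
    fpr, tpr, thr = roc_points(egfr, positive)
    j = tpr - fpr
    best = int(np.argmax(j))
    return float(thr[best]), float(tpr[best])


def paired_bias_test(errors_a, errors_b) -> tuple[float, float]:
    """Paired t test on signed per-patient error differences.

    Tests whether two equations' biases differ on the same patients:
    one-sample t on (error_a − error_b), two-sided p with n−1 df.
    Identical error vectors give (0, 1); zero-variance differences with a
    nonzero mean are degenerate and raise.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length error vectors with n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.mean(d) == 0:
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero-mean difference: t undefined")
    res = stats.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue)


def mcnemar_accuracy_test(within_a, within_b) -> McNemarResult:
    """McNemar test on within-tolerance discordance between two equations.

    Discordant counts b (a within, b not) and c (a not, b within);
    statistic = (|b − c| − 1)² / (b + c) with continuity correction.
    p-value is the exact binomial when b + c < 25, otherwise the
    chi-square tail. No discordance is degenerate: p = 1.
    """
    wa = np.asarray(within_a, dtype=bool)
    wb = np.asarray(within_b, dtype=bool)
    if wa.shape != wb.shape:
        raise ValueError("need equal-length indicator vectors")
    b = int(np.count_nonzero(wa & ~wb))
    c = int(np.count_nonzero(~wa & wb))
    if b + c == 0:
        return McNemarResult(statistic=float("nan"), p_value=1.0, b=b, c=c, degenerate=True)
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    both = int(np.count_nonzero(wa & wb))
    neither = int(np.count_nonzero(~wa & ~wb))
    table = [[both, b], [c, neither]]
    exact = (b + c) < MCNEMAR_EXACT_LIMIT
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return McNemarResult(statistic=float(statistic), p_value=float(res.pvalue), b=b, c=c)


def validate_equation(
    egfr,
    mgfr,
    equation: str = "",
    gfr_threshold: float = 60.0,
    tolerances: Sequence[float] = (0.15, 0.30, 0.50),
) -> ValidationMetrics:
    """Full validation panel for one equation against measured GFR.

    ``egfr`` and ``mgfr`` must be complete pairs. The ROC/sensitivity block
    dichotomises at ``gfr_threshold`` (positive class mGFR below it); if the
    cohort has a single class there, AUC and sensitivity are NaN.
    """
    egfr = np.asarray(egfr, dtype=float)
    mgfr = np.asarray(mgfr, dtype=float)
    errors = error_vector(egfr, mgfr)
    bias, precision = bias_precision(errors)
    lo, hi = limits_of_agreement(bias, precision)
    p15, p30, p50 = (accuracy_within(egfr, mgfr, t) for t in tolerances)
    corr = pearson_correlation(egfr, mgfr)
    positive = mgfr < gfr_threshold
    if positive.any() and not positive.all():
        auc = roc_auc(egfr, positive)
        sens = sensitivity_at_threshold(egfr, mgfr, gfr_threshold)
        ycut, ysens = youden_threshold(egfr, mgfr, gfr_threshold)
    else:
        auc = sens = ycut = ysens = float("nan")
    return ValidationMetrics(
        equation=equation,
        n=int(egfr.size),
        bias=bias,
        precision=precision,
        p15=p15,
        p30=p30,
        p50=p50,
        pearson_r=corr.r,
        slope=corr.slope,
        intercept=corr.intercept,
        loa_lower=lo,
        loa_upper=hi,
        roc_auc=auc,
        sensitivity=sens,
        youden_cutoff=ycut,
        youden_sensitivity=ysens,
    )
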