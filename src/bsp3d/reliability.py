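"""Reliability and agreement statistics for repeated measurements.

Covers the repeatability toolkit for repeated scans and method comparison:
coefficient of variation (sample SD / mean × 100), intraclass correlation
coefficients from the two-way subjects × repetitions ANOVA decomposition
(absolute-agreement ICC(2,1) and consistency ICC(3,1)), Bland–Altman bias
and 95% limits of agreement (bias ± 1.96 SD of paired differences), and
one-way ANOVA F-tests in independent-groups and repeated-measures forms.

Qualitative labels follow common cut-offs: CV >15% not acceptable, 15–10%
acceptable, 10–5% good, <5% very good; ICC <0.5 poor, 0.5–0.75 moderate,
0.75–0.9 good, >0.9 excellent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    """Raised for degenerate or mismatched inputs."""


@dataclass
class RepeatedMeasures:
    """n subjects × k repetitions of one measurand (complete matrix)."""

    values: np.ndarray
    subjects: list[str] | None = None
    repetitions: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StatsError("values must be a 2-D (subjects x repetitions) matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise StatsError("need at least 2 subjects and 2 repetitions")
        if not np.all(np.isfinite(self.values)):
            raise StatsError("missing or non-finite cells are not supported")


@dataclass
class ICCResult:
    value: float
    variant: str
    ms_rows: float
    ms_cols: float
    ms_error: float

    @property
    def label(self) -> str:
        return icc_label(self.value)


@dataclass
class AgreementResult:
    """Bland–Altman bias and limits of agreement (bias ± 1.96 SD)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class AnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float


def cv_label(cv_percent: float) -> str:
    if cv_percent > 15:
        return "not acceptable"
    if cv_percent > 10:
        return "acceptable"
    if cv_percent > 5:
        return "good"
    return "very good"


def icc_label(value: float) -> str:
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def coefficient_of_variation(values) -> float:
    """Sample-SD / mean × 100, in percent.

    Note the normalized-variability convention: SD over mean (some sources
    print the inverted ratio; the reported quantities are SD/mean).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise StatsError("need a flat series of at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise StatsError("coefficient of variation undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / abs(mean))


def _mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way subjects × repetitions decomposition."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_error = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_error, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(data: RepeatedMeasures, variant: str = "icc_2_1_agreement") -> ICCResult:
    """Single-measure intraclass correlation.

    ``icc_2_1_agreement``: (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)
    ``icc_3_1_consistency``: (MSR − MSE) / (MSR + (k−1)MSE)
    A zero-variance matrix (all cells equal) is defined as ICC = 1 with a
    warning.
    """
    if variant not in ("icc_2_1_agreement", "icc_3_1_consistency"):
        raise StatsError(f"unknown ICC variant {variant!r}")
    values = data.values
    n, k = values.shape
    msr, msc, mse = _mean_squares(values)
    if np.ptp(values) == 0:
        logger.warning("zero-variance matrix; ICC defined as 1")
        return ICCResult(1.0, variant, msr, msc, mse)
    if variant == "icc_2_1_agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    value = (msr - mse) / denom if denom != 0 else 1.0
    return ICCResult(float(value), variant, msr, msc, mse)


def bland_altman(estimates, reference) -> AgreementResult:
    """Bias and 95% limits of agreement of ``estimates − reference``.

    A positive bias means the estimating method overestimates relative to
    the reference; negative means it underestimates.
    """
    estimates = np.asarray(estimates, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if estimates.shape != reference.shape or estimates.ndim != 1:
        raise StatsError("paired series must have equal length")
    if len(estimates) < 2:
        raise StatsError("need at least 2 pairs")
    diff = estimates - reference
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=len(diff),
    )


def anova_oneway(groups, repeated: bool = False) -> AnovaResult:
    """One-way ANOVA F-test.

    ``repeated=False``: independent groups, standard between/within F.
    ``repeated=True``: within-subject conditions (rows of an implicit
    subjects × conditions matrix; all groups must have equal length); the F
    is the conditions mean square over the subject × condition residual mean
    square, unadjusted for sphericity.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("need at least 2 groups/conditions")
    if any(len(a) < 2 for a in arrays):
        raise StatsError("need at least 2 observations per group")
    if not repeated:
        f, p = stats.f_oneway(*arrays)
        df_num = len(arrays) - 1
        df_den = sum(len(a) for a in arrays) - len(arrays)
        return AnovaResult(float(f), df_num, df_den, float(p))
    if len({len(a) for a in arrays}) != 1:
        raise StatsError("repeated-measures conditions must have equal length")
    values = np.column_stack(arrays)  # subjects x conditions
    n, k = values.shape
    _, msc, mse = _mean_squares(values)
    df_num = k - 1
    df_den = (n - 1) * (k - 1)
    if mse == 0:
        f = 0.0 if msc == 0 else np.inf
    else:
        f = msc / mse
    p = float(stats.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
    return AnovaResult(float(f), df_num, df_den, p)
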