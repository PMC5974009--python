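"""Method-comparison statistics for paired LV function measurements.

Given the same index (EDV, ESV, SV or EF) measured on each subject by two
methods, this module computes the full agreement battery used to validate a
new measurement system against a reference: Pearson correlation with a
two-sided p-value, ordinary least-squares regression of method B on method
A, Bland-Altman bias and limits of agreement, the coefficient of variation
of the paired differences, and a categorical agreement classification
(excellent if r > 0.80 or CoV < 10%; good if r > 0.6; poor otherwise).

Differences are taken as x - y with x the system under test and y the
reference, so a positive bias means the new system reads higher.

Whole volume-time curves are compared per subject by the Pearson
correlation between the two curves, summarized by the median and
interquartile range (Q3 - Q1) across subjects, together with the per-subject
difference in time to minimal volume (percentage points of the cycle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "CurvePair",
    "CurveAgreement",
    "pearson",
    "linear_regression",
    "bland_altman",
    "cov",
    "classify_agreement",
    "compare_measurements",
    "curve_agreement",
]


@dataclass(eq=False)
class PairedMeasurements:
    """One index measured by two methods on the same subjects (same units)."""

    subject_ids: tuple[str, ...]
    x: np.ndarray  # method under test
    y: np.ndarray  # reference method

    def __post_init__(self) -> None:
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.subject_ids) == len(self.x) == len(self.y)):
            raise ValueError("subject_ids, x and y must have equal length")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValueError("missing or non-finite values are not allowed")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class AgreementResult:
    """Full agreement battery for one index and one method pair."""

    r: float
    p_value: float
    slope: float
    intercept: float
    r_squared: float
    bias: float
    loa_low: float
    loa_high: float
    cov_pct: float
    classification: str


def _require(pm: PairedMeasurements, n_min: int) -> None:
    if pm.n < n_min:
        raise ValueError(f"need at least {n_min} paired measurements, got {pm.n}")


def pearson(pm: PairedMeasurements) -> tuple[float, float]:
    """Product-moment correlation r and its two-sided p-value.

    p follows the exact t-distribution of t = r sqrt((n-2)/(1-r^2)) on
    n - 2 degrees of freedom under the null of no correlation.
    """
    _require(pm, 3)
    if np.ptp(pm.x) == 0 or np.ptp(pm.y) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    res = stats.pearsonr(pm.x, pm.y)
    return float(res.statistic), float(res.pvalue)


def linear_regression(pm: PairedMeasurements) -> tuple[float, float, float]:
    """OLS fit y = slope * x + intercept; returns (slope, intercept, R^2).

    For a constant y the fit is flat and R^2 is defined as 0.
    """
    _require(pm, 3)
    if np.ptp(pm.x) == 0:
        raise ValueError("regression undefined: zero variance in x")
    if np.ptp(pm.y) == 0:
        return 0.0, float(pm.y[0]), 0.0
    res = stats.linregress(pm.x, pm.y)
    return float(res.slope), float(res.intercept), float(res.rvalue) ** 2


def bland_altman(pm: PairedMeasurements, k: float = 1.96) -> tuple[float, float, float]:
    """Bland-Altman bias and limits of agreement.

    d = x - y elementwise; bias = mean(d); limits = bias -/+ k SD(d) with the
    sample (n - 1) standard deviation.  k defaults to 1.96, the 95% normal
    quantile.
    """
    _require(pm, 2)
    d = pm.x - pm.y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - k * sd, bias + k * sd


def cov(pm: PairedMeasurements, denominator: str = "pooled") -> float:
    """Coefficient of variation of the paired differences, in percent.

    Numerator: SD (n - 1) of x - y.  Denominator: the pooled mean of all
    measurements of both methods (default) or the mean of method A
    (``denominator='method_a'``).
    """
    _require(pm, 2)
    sd = float(np.std(pm.x - pm.y, ddof=1))
    if denominator == "pooled":
        mean = float(np.mean(np.concatenate([pm.x, pm.y])))
    elif denominator == "method_a":
        mean = float(np.mean(pm.x))
    else:
        raise ValueError(f"denominator must be 'pooled' or 'method_a', got {denominator!r}")
    if mean == 0:
        raise ValueError("CoV undefined: zero mean")
    return 100.0 * sd / mean


def classify_agreement(r: float, cov_pct: float) -> str:
    """Categorical agreement: excellent (r > 0.80 or CoV < 10%), good (r > 0.6), poor."""
    if r > 0.80 or cov_pct < 10.0:
        return "excellent"
    if r > 0.6:
        return "good"
    return "poor"


def compare_measurements(
    pm: PairedMeasurements, k: float = 1.96, cov_denominator: str = "pooled"
) -> AgreementResult:
    """Run the full battery on one paired index."""
    r, p = pearson(pm)
    slope, intercept, r2 = linear_regression(pm)
    bias, lo, hi = bland_altman(pm, k=k)
    c = cov(pm, denominator=cov_denominator)
    return AgreementResult(
        r=r,
        p_value=p,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        cov_pct=c,
        classification=classify_agreement(r, c),
    )


@dataclass(eq=False)
class CurvePair:
    """One subject's global volume curve measured by two methods.

    ``time_to_min_pct_a``/``_b`` are the per-method times of minimal volume
    as percentages of the cycle (computed upstream from each method's own
    timing).
    """

    subject_id: str
    volumes_a: np.ndarray
    volumes_b: np.ndarray
    time_to_min_pct_a: float
    time_to_min_pct_b: float

    def __post_init__(self) -> None:
        self.volumes_a = np.asarray(self.volumes_a, dtype=float)
        self.volumes_b = np.asarray(self.volumes_b, dtype=float)


@dataclass(eq=False)
class CurveAgreement:
    """Cohort summary of per-subject curve correlations and timing differences."""

    subject_ids: tuple[str, ...]
    correlations: np.ndarray
    median_r: float
    iqr_r: float
    time_to_min_diff_pct: np.ndarray  # |a - b| per subject, percentage points
    time_to_min_mean: float
    time_to_min_sd: float


def curve_agreement(pairs: list[CurvePair]) -> CurveAgreement:
    """Compare global volume curves subject by subject.

    Each pair must have equal phase counts (resample upstream otherwise).
    Median and IQR use linear-interpolation quantiles.
    """
    if not pairs:
        raise ValueError("need at least one curve pair")
    rs = []
    for p in pairs:
        if p.volumes_a.shape != p.volumes_b.shape:
            raise ValueError(
                f"subject {p.subject_id}: curves have different phase counts "
                f"({len(p.volumes_a)} vs {len(p.volumes_b)})"
            )
        rs.append(float(stats.pearsonr(p.volumes_a, p.volumes_b).statistic))
    rs = np.array(rs)
    diffs = np.array([abs(p.time_to_min_pct_a - p.time_to_min_pct_b) for p in pairs])
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    return CurveAgreement(
        subject_ids=tuple(p.subject_id for p in pairs),
        correlations=rs,
        median_r=float(np.median(rs)),
        iqr_r=float(np.percentile(rs, 75) - np.percentile(rs, 25)),
        time_to_min_diff_pct=diffs,
        time_to_min_mean=float(np.mean(diffs)),
        time_to_min_sd=sd,
    )
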