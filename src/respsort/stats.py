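"""Method-comparison statistics: Bland-Altman, two-way mixed ICC, CoV.

All standard deviations use the n-1 denominator.  The ICC is the
single-measure two-way mixed-model coefficient computed from the two-way
ANOVA mean squares; both the absolute-agreement (default, the variant SPSS
reports as "two-way mixed, absolute agreement") and consistency definitions
are available, with 95% confidence intervals from the F-distribution
(McGraw & Wong).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BlandAltmanResult",
    "ICCResult",
    "bland_altman",
    "icc_two_way_mixed",
    "coefficient_of_variation",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    definition: str
    n_subjects: int
    n_conditions: int


def bland_altman(a, b) -> BlandAltmanResult:
    """Bias, SD of differences, and 95% limits of agreement (bias +- 1.96 SD).

    Differences are ``a - b`` pairwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("insufficient pairs: inputs must be equal-length 1D arrays")
    if len(a) < 2:
        raise ValueError("insufficient pairs: need n >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd,
                             loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                             n=len(a))


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of the complete two-way layout."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_two_way_mixed(ratings, definition: str = "absolute",
                      alpha: float = 0.05) -> ICCResult:
    """Single-measure two-way mixed ICC with a 95% CI.

    ``ratings`` is a complete subjects x conditions matrix.  The
    ``consistency`` definition is (MS_R - MS_E) / (MS_R + (k-1) MS_E); the
    ``absolute`` definition additionally charges the condition (column)
    variance.  Confidence bounds follow McGraw & Wong's F-based formulas.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("insufficient pairs: need a >= 2 x 2 complete matrix")
    if np.any(~np.isfinite(x)):
        raise ValueError("insufficient pairs: matrix must be complete")
    n, k = x.shape
    if float(x.std()) == 0:
        raise ValueError("degenerate ratings: zero total variance")
    msr, msc, mse = _anova_mean_squares(x)

    if definition == "consistency":
        denom = msr + (k - 1) * mse
        if denom == 0:
            raise ValueError("degenerate ratings: zero variance")
        icc = (msr - mse) / denom
        if mse == 0:
            return ICCResult(1.0, 1.0, 1.0, definition, n, k)
        f = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * sps.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    elif definition == "absolute":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        if denom == 0:
            raise ValueError("degenerate ratings: zero variance")
        icc = (msr - mse) / denom
        if mse == 0 and msc == 0:
            return ICCResult(1.0, 1.0, 1.0, definition, n, k)
        # McGraw & Wong CI for ICC(A,1)
        a_ = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b_ = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isfinite(a_) and (a_ * msc + b_ * mse) > 0:
            v = (a_ * msc + b_ * mse) ** 2 / (
                (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1)))
        else:
            v = (n - 1) * (k - 1)
        f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr)
    else:
        raise ValueError("definition must be 'absolute' or 'consistency'")
    lo = float(np.clip(lo, -1.0, 1.0))
    hi = float(np.clip(hi, -1.0, 1.0))
    return ICCResult(float(icc), lo, hi, definition, n, k)


def coefficient_of_variation(a, b, method: str = "within-subject") -> float:
    """Coefficient of variation (%) between paired measurements.

    ``within-subject`` (default): SD of the paired differences divided by
    sqrt(2), relative to the grand mean.  ``simple``: SD of the differences
    relative to the grand mean.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("insufficient pairs: need equal-length 1D arrays, n >= 2")
    grand = float(np.mean(np.r_[a, b]))
    if grand <= 0:
        raise ValueError("invalid scale: grand mean must be positive")
    sd = float((a - b).std(ddof=1))
    if method == "within-subject":
        return sd / np.sqrt(2.0) / grand * 100.0
    if method == "simple":
        return sd / grand * 100.0
    raise ValueError("method must be 'within-subject' or 'simple'")
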