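"""Method-agreement statistics: calibration regression and Bland–Altman.

These are the validation tools of the quantification chain: ordinary
least-squares regression of image-derived gold mass against the elemental
assay (slope, R²), and Bland–Altman agreement (bias = mean difference,
95 % limits of agreement = bias ± 1.96 × sample SD of the differences).

The agreement report mirrors the in-vivo analysis convention: points falling
outside the limits of agreement are flagged as outliers and the regression is
re-fitted without them; both fits are always reported rather than choosing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "AgreementReport",
    "linreg",
    "bland_altman",
    "agreement_report",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class AgreementReport:
    """Joint regression + agreement summary with outlier-excluded re-fit."""

    regression: RegressionResult
    bland_altman: BlandAltmanResult
    outliers: tuple
    regression_excluding_outliers: RegressionResult


def linreg(x, y) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x`` with R² = 1 − SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be matching 1-D arrays with n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the regression is undefined")
    res = sps.linregress(x, y)
    fitted = res.intercept + res.slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # flat response carries no explained variance: R² = 0 when SS_tot = 0
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RegressionResult(float(res.slope), float(res.intercept), r2, x.size)


def bland_altman(a, b) -> BlandAltmanResult:
    """Agreement of two measurements: differences d = a − b.

    bias = mean(d); SD with the n−1 denominator; limits = bias ± 1.96·SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, a.size)


def agreement_report(estimates, references) -> AgreementReport:
    """Full report: OLS fit, Bland–Altman, and the outlier-excluded re-fit.

    Outliers are pairs whose difference falls outside the limits of
    agreement.  When exclusion leaves fewer than two points (or a constant
    reference) the original fit is reported for both entries.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    reg = linreg(ref, est)
    ba = bland_altman(est, ref)
    d = est - ref
    out = np.flatnonzero((d < ba.loa_low) | (d > ba.loa_high))
    keep = np.setdiff1d(np.arange(est.size), out)
    if keep.size >= 2 and np.ptp(ref[keep]) > 0:
        reg_ex = linreg(ref[keep], est[keep])
    else:
        reg_ex = reg
    return AgreementReport(reg, ba, tuple(int(i) for i in out), reg_ex)
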