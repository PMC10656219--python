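"""Bland-Altman agreement and calibration regression for paired kcal.

The Bland-Altman analysis summarises per-meal differences
(estimated - weighed) by their mean and 95% limits of agreement
(mean +/- 1.96 SD), and tests for *proportional bias* -- a systematic
trend of the difference with meal size -- by regressing the difference
on the pair mean (the conventional x-axis of the Bland-Altman plot).

The calibration regression fits estimated = a + b * weighed by ordinary
least squares; a slope above 1 means estimates grow faster than the
served energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import statsmodels.api as sm

Pairs = Sequence[Tuple[float, float]]  # (weighed, estimated)


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_slope: float
    bias_intercept: float
    bias_p: float
    bias_r2: float
    loa_multiplier: float = 1.96


@dataclass(frozen=True)
class CalibrationResult:
    n: int
    slope: float
    intercept: float
    r2: float
    slope_p: float


def bland_altman(pairs: Pairs, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Mean difference, limits of agreement, and proportional-bias test.

    Requires n >= 3.  When the pair means are constant the bias
    regression is undefined and reported as ``nan`` while the mean
    difference and limits of agreement are still returned.
    """
    w = np.asarray([p[0] for p in pairs], float)
    e = np.asarray([p[1] for p in pairs], float)
    n = len(w)
    if n < 3:
        raise ValueError("bland_altman requires at least 3 pairs")
    diff = e - w
    mean = (e + w) / 2.0
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))

    if np.ptp(mean) == 0:
        slope = intercept = p = r2 = math.nan
    else:
        # errstate: a zero-variance difference series makes R^2 0/0
        with np.errstate(divide="ignore", invalid="ignore"):
            fit = sm.OLS(diff, sm.add_constant(mean)).fit()
            intercept, slope = (float(v) for v in fit.params)
            p = float(fit.pvalues[1])
            r2 = float(fit.rsquared)
    return BlandAltmanResult(
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - loa_multiplier * sd_diff,
        loa_high=mean_diff + loa_multiplier * sd_diff,
        bias_slope=slope,
        bias_intercept=intercept,
        bias_p=p,
        bias_r2=r2,
        loa_multiplier=loa_multiplier,
    )


def calibration_ols(pairs: Pairs) -> CalibrationResult:
    """OLS fit of estimated on weighed kcal with slope test and R^2."""
    w = np.asarray([p[0] for p in pairs], float)
    e = np.asarray([p[1] for p in pairs], float)
    if len(w) < 3:
        raise ValueError("calibration_ols requires at least 3 pairs")
    if np.ptp(w) == 0:
        raise ValueError("calibration_ols: weighed values are constant")
    fit = sm.OLS(e, sm.add_constant(w)).fit()
    intercept, slope = (float(v) for v in fit.params)
    return CalibrationResult(
        n=len(w),
        slope=slope,
        intercept=intercept,
        r2=float(fit.rsquared),
        slope_p=float(fit.pvalues[1]),
    )
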