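"""Standard-curve quantification and before/after consumption differencing.

The enzymatic D-gluconic acid assay reads absorbance at 340 nm before (A1)
and after (A2) the coupled reaction; A2 - A1 is linear in analyte
concentration over the calibration range.  A fitted line converts unknown
supernatant readings back to g/L (inverse prediction).  Substrate or amino
acid consumption is the signed before-minus-after concentration difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats as sstats

logger = logging.getLogger(__name__)

#: Calibration grid used for the D-gluconic acid kit, g/L.
GLUCONIC_STANDARDS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class StandardCurve:
    """OLS line relating delta-absorbance (A2 - A1) to concentration."""

    slope: float  # delta-absorbance per (g/L)
    intercept: float
    r_squared: float
    conc_range: tuple  # (min, max) calibration concentration, g/L


@dataclass(frozen=True)
class Concentration:
    """An inverse-predicted concentration, flagged when extrapolated."""

    value: float  # g/L
    extrapolated: bool


@dataclass(frozen=True)
class ConsumptionResult:
    analyte: str
    before: float
    after: float
    delta: float  # before - after
    flag: str  # "consumed" | "produced" | ""


def fit_standard_curve(concs, delta_abs) -> StandardCurve:
    """Fit delta-absorbance vs concentration by ordinary least squares.

    Requires >= 3 distinct calibration concentrations; the intercept is
    estimated, not forced through zero.  A fit with r^2 < 0.98 is logged
    as a warning (suspect calibration).
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(delta_abs, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 calibration points")
    if np.unique(x).size < 2:
        raise ValueError("calibration concentrations are all identical (singular fit)")
    res = sstats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 < 0.98:
        logger.warning("standard curve r^2 = %.4f < 0.98; calibration is suspect", r2)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=r2, conc_range=(float(x.min()), float(x.max())))


def interpolate_concentration(curve: StandardCurve, delta_abs: float) -> Concentration:
    """Invert the standard curve: ``(delta_abs - intercept) / slope``.

    The result is flagged extrapolated when it falls outside the
    calibration concentration range.
    """
    if curve.slope == 0:
        raise ValueError("cannot invert a zero-slope standard curve")
    conc = (float(delta_abs) - curve.intercept) / curve.slope
    lo, hi = curve.conc_range
    extrapolated = not (lo <= conc <= hi)
    if extrapolated:
        logger.warning("inverse prediction %.4g g/L outside calibration range [%g, %g]",
                       conc, lo, hi)
    return Concentration(value=conc, extrapolated=extrapolated)


def compute_consumption(before: float, after: float, analyte: str = "") -> ConsumptionResult:
    """Signed consumption: positive delta means the analyte was consumed,
    negative means net production.  No clamping."""
    if before < 0 or after < 0:
        raise ValueError("concentrations must be >= 0")
    delta = before - after
    flag = "consumed" if delta > 0 else ("produced" if delta < 0 else "")
    return ConsumptionResult(analyte=analyte, before=float(before),
                             after=float(after), delta=float(delta), flag=flag)
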