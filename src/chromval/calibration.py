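"""Calibration: OLS fitting, split curves, backcalculation, linearity criteria.

The quantification strategy is the one this validation follows: a single
unweighted least-squares line over the full nine-level range, plus two
"adjusted" curves obtained by splitting the range at a shared level
(5 ug/mL by default) into a low-concentration and a high-concentration
curve of at least five levels each. Splitting is the remedy for the
heteroscedasticity of detector areas across a ~1750-fold concentration
range; weighting is deliberately out of scope.

Linearity is judged by three criteria: correlation (r, r^2), the relative
standard deviation of the slope RSD(%) = s_m / m * 100 (< 5%), and the
zero-in-intercept-confidence-interval criterion at 95%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError

__all__ = [
    "CalibrationCurve",
    "AccordanceRecord",
    "LinearityAssessment",
    "fit_ols",
    "fit_table",
    "split_curves",
    "split_table",
    "backcalculate",
    "accordance",
    "slope_rsd",
    "assess_linearity",
    "slope_confidence_interval",
    "select_curve",
]

DEFAULT_SPLIT_LEVEL = 5.0


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted calibration line with its dispersion statistics."""

    slope: float  # area per (ug/mL)
    intercept: float  # area
    slope_sd: float  # standard error of the slope
    intercept_sd: float  # standard error of the intercept
    r: float  # Pearson correlation
    r2: float  # determination coefficient
    range_low: float  # ug/mL
    range_high: float  # ug/mL
    n_points: int  # observations used in the fit
    n_levels: int  # distinct concentration levels
    residual_sd: float  # RMS residual, area units

    @property
    def meets_level_guideline(self) -> bool:
        """ICH-style guideline: at least five concentration levels."""
        return self.n_levels >= 5

    def predict(self, concentration):
        """Noise-free area at a concentration (vectorized)."""
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept


@dataclass(frozen=True)
class AccordanceRecord:
    """One backcalculated standard: obtained vs nominal, in percent."""

    nominal: float
    obtained: float
    accordance: float  # obtained / nominal * 100


@dataclass(frozen=True)
class LinearityAssessment:
    """Linearity decision-rule outcome for one curve."""

    slope_rsd: float  # percent
    intercept_ci: tuple[float, float]  # area units
    zero_in_ci: bool
    slope_rsd_pass: bool
    r_pass: bool

    @property
    def passed(self) -> bool:
        return self.zero_in_ci and self.slope_rsd_pass and self.r_pass


def _as_xy(concentrations, areas) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and areas must be equal-length 1-D vectors")
    return x, y


def fit_ols(concentrations, areas) -> CalibrationCurve:
    """Ordinary least-squares calibration line.

    Requires at least three distinct concentration levels. Standard errors
    of slope and intercept come from the classical OLS formulas; r is the
    Pearson correlation of (c, area) and r^2 its square.
    """
    x, y = _as_xy(concentrations, areas)
    levels = np.unique(x)
    if levels.size < 3:
        raise DegenerateDesignError(
            f"need >= 3 distinct concentration levels, got {levels.size}"
        )
    res = stats.linregress(x, y)
    n = x.size
    resid = y - (res.slope * x + res.intercept)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_sd=float(res.stderr),
        intercept_sd=float(res.intercept_stderr),
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        range_low=float(levels[0]),
        range_high=float(levels[-1]),
        n_points=int(n),
        n_levels=int(levels.size),
        residual_sd=residual_sd,
    )


def fit_table(table: pd.DataFrame) -> CalibrationCurve:
    """Fit on a peak-area observation table (all replicate points, not level means)."""
    return fit_ols(table["concentration_ug_per_ml"], table["area"])


def _split_masks(x: np.ndarray, split: float) -> tuple[np.ndarray, np.ndarray]:
    at_split = np.isclose(x, split)
    if not at_split.any():
        raise DegenerateDesignError(
            f"split level {split} ug/mL is not among the standards"
        )
    low = (x < split) | at_split
    high = (x > split) | at_split
    for mask, side in ((low, "low"), (high, "high")):
        if np.unique(x[mask]).size < 5:
            raise DegenerateDesignError(
                f"{side} side of the split at {split} ug/mL has fewer than 5 levels"
            )
    return low, high


def split_curves(
    concentrations, areas, split_concentration: float = DEFAULT_SPLIT_LEVEL
) -> tuple[CalibrationCurve, CalibrationCurve]:
    """Split one calibration design into low- and high-range curves.

    The split level belongs to both curves, so each adjusted range stays
    anchored at the shared standard. Each side must contain at least five
    distinct levels.
    """
    x, y = _as_xy(concentrations, areas)
    low, high = _split_masks(x, split_concentration)
    return fit_ols(x[low], y[low]), fit_ols(x[high], y[high])


def split_table(
    table: pd.DataFrame, split_concentration: float = DEFAULT_SPLIT_LEVEL
) -> tuple[CalibrationCurve, CalibrationCurve]:
    return split_curves(
        table["concentration_ug_per_ml"], table["area"], split_concentration
    )


def backcalculate(curve: CalibrationCurve, area):
    """Invert the calibration line: c = (area - b) / m.

    The result may legitimately be negative for areas below the fitted
    intercept (low standards under a full-range curve).
    """
    if curve.slope == 0:
        raise DegenerateDesignError("cannot backcalculate with a zero slope")
    out = (np.asarray(area, dtype=float) - curve.intercept) / curve.slope
    return float(out) if out.ndim == 0 else out


def accordance(nominal: float, obtained: float) -> float:
    """Backcalculation accordance, percent: obtained / nominal * 100."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be > 0")
    return obtained / nominal * 100.0


def slope_rsd(curve: CalibrationCurve) -> float:
    """Relative standard deviation of the slope, percent: s_m / m * 100."""
    if curve.slope == 0:
        raise DegenerateDesignError("slope RSD undefined for zero slope")
    return curve.slope_sd / curve.slope * 100.0


def assess_linearity(
    curve: CalibrationCurve,
    confidence: float = 0.95,
    max_slope_rsd: float = 5.0,
    min_r: float = 0.99,
) -> LinearityAssessment:
    """Apply the linearity decision rules to a fitted curve.

    The intercept confidence interval is the Student-t OLS interval
    b +/- t(confidence, n-2) * SE(b). A tiny numerical pad (1e-7 relative)
    keeps an exactly collinear fit, whose interval degenerates to a point
    up to float error, on the correct side of the zero-inclusion rule.
    """
    if curve.n_points < 3:
        raise DegenerateDesignError("linearity assessment needs >= 3 points")
    tq = stats.t.ppf(0.5 + confidence / 2.0, curve.n_points - 2)
    half = tq * curve.intercept_sd
    ci = (curve.intercept - half, curve.intercept + half)
    pad = 1e-7 * max(1.0, abs(curve.intercept))
    zero_in = (ci[0] - pad) <= 0.0 <= (ci[1] + pad)
    rsd = slope_rsd(curve)
    return LinearityAssessment(
        slope_rsd=rsd,
        intercept_ci=ci,
        zero_in_ci=bool(zero_in),
        slope_rsd_pass=bool(rsd < max_slope_rsd),
        r_pass=bool(curve.r >= min_r),
    )


def slope_confidence_interval(
    concentrations, areas, confidence: float = 0.95, robust: bool = True
) -> tuple[float, float]:
    """Confidence interval for the slope, for parameter-recovery checks.

    With ``robust=True`` (default) the interval uses heteroskedasticity-
    consistent (HC3) standard errors. Detector noise is largely
    proportional to signal, so over a wide calibration range the classical
    homoscedastic OLS interval materially undercovers the true slope; the
    robust interval is the appropriate recovery diagnostic. The classical
    s_m reported by :func:`fit_ols` is unchanged by this choice — it is the
    conventional linearity statistic, not a coverage tool.
    """
    import statsmodels.api as sm

    x, y = _as_xy(concentrations, areas)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit(cov_type="HC3" if robust else "nonrobust")
    lo, hi = fit.conf_int(1.0 - confidence)[1]
    return float(lo), float(hi)


def select_curve(
    low: CalibrationCurve,
    high: CalibrationCurve,
    concentration: float,
    split_concentration: float = DEFAULT_SPLIT_LEVEL,
) -> CalibrationCurve:
    """Pick the adjusted curve whose range suits an expected concentration.

    Concentrations at or below the split level use the low-range curve
    (the split standard belongs to both ranges; the low curve is the
    convention here because detection/quantification limits live there).
    """
    return low if concentration <= split_concentration else high
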