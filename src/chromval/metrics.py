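"""Validation statistics: sensitivity, precision, accuracy, robustness, stability.

Implements the ICH-style figures of merit on peak-area observation tables:

* LOD = 3.3 * delta / s and LOQ = 10 * delta / s, with delta the standard
  deviation of blank responses and s the calibration slope;
* repeatability (intraday) and intermediate precision (interday) as
  RSD(%) = s / mean * 100, on backcalculated concentrations by default;
* accuracy as obtained / nominal * 100 against an 85-115% band;
* robustness as the perturbed-to-optimized peak-area ratio plus the
  retention-time difference;
* stability as mean(day x) / mean(day 0) * 100 per storage condition;
* selectivity as one-to-one analyte assignment with all adjacent
  resolutions above a threshold (default Rs >= 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, backcalculate
from .peaks import AssignmentResult, DetectedPeak

__all__ = [
    "SensitivityResult",
    "PrecisionResult",
    "AccuracyResult",
    "StabilityResult",
    "RobustnessComparison",
    "SelectivityResult",
    "PeakSummary",
    "lod_loq",
    "precision",
    "accuracy",
    "stability",
    "robustness_compare",
    "selectivity_check",
]

LOQ_LOD_RATIO = 10.0 / 3.3


@dataclass(frozen=True)
class SensitivityResult:
    blank_sd: float  # delta, area units
    slope: float  # area per (ug/mL)
    lod: float  # ug/mL
    loq: float  # ug/mL


@dataclass(frozen=True)
class PrecisionResult:
    level: float  # ug/mL
    intraday_rsd: float | None  # percent
    interday_rsd: float | None  # percent
    passed: bool


@dataclass(frozen=True)
class AccuracyResult:
    level: float  # ug/mL (the real value)
    obtained_mean: float  # ug/mL
    accuracy: float  # percent
    passed: bool


@dataclass(frozen=True)
class StabilityResult:
    condition: str
    level: float  # ug/mL
    day: int
    stability: float  # percent


@dataclass(frozen=True)
class RobustnessComparison:
    parameter: str
    optimized_area: float
    perturbed_area: float
    area_percent: float  # perturbed / optimized * 100
    rt_difference: float  # minutes, perturbed - optimized


@dataclass(frozen=True)
class PeakSummary:
    """Minimal peak record for robustness comparisons."""

    area: float
    retention_time: float


@dataclass(frozen=True)
class SelectivityResult:
    passed: bool
    messages: list[str] = field(default_factory=list)
    matched: dict[str, float] = field(default_factory=dict)  # analyte -> apex time
    resolutions: list[tuple[tuple[str, str], float]] = field(default_factory=list)


def lod_loq(blank_areas, curve_slope: float) -> SensitivityResult:
    """Detection and quantification limits from blank variability.

    delta is the sample SD of the blank responses (ten blanks in
    triplicate in the reference design); the slope should come from the
    curve covering the low-concentration range, where the limits live.
    LOQ is derived as LOD * 10/3.3 so the ratio is exact by construction.
    """
    blanks = np.asarray(blank_areas, dtype=float)
    if blanks.size < 2:
        raise ValueError("need >= 2 blank observations")
    if curve_slope <= 0:
        raise ValueError("calibration slope must be > 0")
    delta = float(np.std(blanks, ddof=1))
    lod = 3.3 * delta / curve_slope
    return SensitivityResult(
        blank_sd=delta, slope=float(curve_slope), lod=lod, loq=lod * LOQ_LOD_RATIO
    )


def _rsd(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(np.std(values, ddof=1) / mean * 100.0)


def _level_rows(table: pd.DataFrame, level: float) -> pd.DataFrame:
    rows = table[np.isclose(table["concentration_ug_per_ml"], level)]
    if rows.empty:
        raise ValueError(f"level {level} ug/mL absent from the table")
    return rows


def precision(
    table: pd.DataFrame,
    level: float,
    mode: str = "both",
    curve: CalibrationCurve | None = None,
    rsd_threshold: float = 15.0,
) -> PrecisionResult:
    """Intraday and/or interday RSD at one concentration level.

    Statistics are computed on backcalculated concentrations when a curve
    is given (the conventional presentation, since the precision table is
    indexed by concentration), otherwise directly on areas; the two agree
    exactly only for a zero-intercept line, hence the explicit choice.

    Intraday (repeatability): the RSD within each day, averaged over days.
    Interday (intermediate precision): the RSD of all replicate values
    pooled across days — the conservative reading, since day-to-day shifts
    then inflate rather than average out.
    """
    if mode not in ("intraday", "interday", "both"):
        raise ValueError("mode must be 'intraday', 'interday' or 'both'")
    rows = _level_rows(table, level).copy()
    if len(rows) < 3:
        raise ValueError("need >= 3 observations at the level")
    rows["value"] = (
        backcalculate(curve, rows["area"].to_numpy()) if curve else rows["area"].to_numpy()
    )

    intraday = interday = None
    if mode in ("intraday", "both"):
        per_day = [
            _rsd(g["value"].to_numpy())
            for _, g in rows.groupby("day")
            if len(g) >= 2
        ]
        if not per_day:
            raise ValueError("intraday RSD needs >= 2 replicates within a day")
        intraday = float(np.mean(per_day))
    if mode in ("interday", "both"):
        if rows["day"].nunique() < 2:
            raise ValueError("interday RSD needs observations on >= 2 days")
        interday = _rsd(rows["value"].to_numpy())

    computed = [v for v in (intraday, interday) if v is not None]
    return PrecisionResult(
        level=float(level),
        intraday_rsd=intraday,
        interday_rsd=interday,
        passed=bool(all(v <= rsd_threshold for v in computed)),
    )


def accuracy(
    table: pd.DataFrame,
    level: float,
    curve: CalibrationCurve,
    band: tuple[float, float] = (85.0, 115.0),
) -> AccuracyResult:
    """Accuracy(%) = experimental / real * 100 at one level.

    The experimental value is the mean backcalculated concentration of the
    level's replicates under the supplied curve (pick the adjusted curve
    whose range covers the level).
    """
    if level <= 0:
        raise ValueError("accuracy level must be > 0")
    rows = _level_rows(table, level)
    obtained = float(np.mean(backcalculate(curve, rows["area"].to_numpy())))
    acc = obtained / level * 100.0
    return AccuracyResult(
        level=float(level),
        obtained_mean=obtained,
        accuracy=acc,
        passed=bool(band[0] <= acc <= band[1]),
    )


def stability(
    day0_values, dayx_values, day: int, condition: str = "", level: float = float("nan")
) -> StabilityResult:
    """Stability(%) = mean response at day x / mean response at day 0 * 100.

    Day 0 compared with itself is exactly 100 by definition.
    """
    v0 = np.asarray(day0_values, dtype=float)
    vx = np.asarray(dayx_values, dtype=float)
    if v0.size == 0 or vx.size == 0:
        raise ValueError("both day-0 and day-x value sets must be non-empty")
    if v0.mean() == 0:
        raise ValueError("day-0 mean response is zero")
    pct = 100.0 if day == 0 else float(vx.mean() / v0.mean() * 100.0)
    return StabilityResult(condition=condition, level=level, day=int(day), stability=pct)


def _area_rt(summary) -> tuple[float, float]:
    if isinstance(summary, DetectedPeak):
        return summary.area, summary.apex_time
    return summary.area, summary.retention_time


def robustness_compare(
    optimized, perturbed, parameter: str = ""
) -> RobustnessComparison:
    """Compare a perturbed run's quercetin peak against the optimized method.

    Accepts :class:`PeakSummary` or :class:`~chromval.peaks.DetectedPeak`
    objects; reports the perturbed area as a percentage of the optimized
    area and the retention-time difference (perturbed - optimized).
    """
    a0, rt0 = _area_rt(optimized)
    a1, rt1 = _area_rt(perturbed)
    if a0 == 0:
        raise ValueError("optimized peak area is zero")
    return RobustnessComparison(
        parameter=parameter,
        optimized_area=float(a0),
        perturbed_area=float(a1),
        area_percent=float(a1 / a0 * 100.0),
        rt_difference=float(rt1 - rt0),
    )


def selectivity_check(
    assignment: AssignmentResult,
    required: set[str] | list[str],
    min_resolution: float = 1.5,
) -> SelectivityResult:
    """Selectivity verdict: every required analyte matched once, Rs adequate.

    Fails (with a narrative) when a required analyte is unmatched, when an
    analyte is matched by more than one peak, or when any adjacent pair of
    assigned peaks resolves below ``min_resolution``.
    """
    messages: list[str] = []
    required = set(required)

    counts: dict[str, int] = {}
    for p in assignment.peaks:
        if p.assigned_analyte is not None:
            counts[p.assigned_analyte] = counts.get(p.assigned_analyte, 0) + 1
    for name in sorted(required):
        n = counts.get(name, 0)
        if n == 0:
            messages.append(f"{name}: no peak assigned")
        elif n > 1:
            messages.append(
                f"{name}: ambiguous, {n} peaks claim the same analyte"
            )
    for pair, rs in assignment.resolutions:
        if rs < min_resolution:
            messages.append(
                f"resolution {pair[0]}/{pair[1]} = {rs:.2f} below {min_resolution}"
            )
    matched = {
        name: peak.apex_time
        for name, peak in assignment.assignments.items()
        if name in required
    }
    return SelectivityResult(
        passed=not messages,
        messages=messages,
        matched=matched,
        resolutions=list(assignment.resolutions),
    )
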