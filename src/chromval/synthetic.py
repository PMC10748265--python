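"""Synthetic chromatograms and peak-area tables for validation studies.

The generator emulates the data a reversed-phase HPLC-DAD assay of
quercetin produces: exponentially modified Gaussian (EMG) peaks at the
method's retention times (rutin 2.5 min, quercetin 3.6 min, kaempferol
5.4 min) over a 10-minute run, and peak-area observations that follow a
linear detector response ``area = slope * c + intercept`` perturbed by
additive (blank-level) and proportional (injection-level) Gaussian noise,
laid out as replicate x day tables. Storage drift (evaporation up,
degradation down) and deliberate robustness perturbations (mobile-phase
pH, flow rate) act multiplicatively on areas.

Every stochastic operation takes an explicit seed; there is no hidden
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .errors import PeakWindowError
from .peaks import ChromatogramTrace

__all__ = [
    "PeakModel",
    "ResponseModel",
    "StabilityScenario",
    "RobustnessPerturbation",
    "STANDARD_LEVELS",
    "RETENTION_TIMES",
    "STORAGE_CONDITIONS",
    "emg_kernel",
    "simulate_trace",
    "simulate_area_table",
    "apply_stability",
    "apply_perturbation",
]

#: The nine-point calibration design of the validated method (ug/mL).
STANDARD_LEVELS: tuple[float, ...] = (0.14, 0.35, 0.57, 2.8, 5.0, 65.0, 125.0, 185.0, 245.0)

#: Nominal retention times (min) of the three flavonoids the method separates.
RETENTION_TIMES: dict[str, float] = {"rutin": 2.5, "quercetin": 3.6, "kaempferol": 5.4}

#: Closed set of storage conditions for stability studies.
STORAGE_CONDITIONS: tuple[str, ...] = ("minus20C", "plus4C", "roomT")

# tau below this fraction of sigma is treated as a pure Gaussian: the EMG
# pdf is numerically unstable for vanishing tailing constants.
_TAU_GAUSSIAN_CUTOFF = 1e-6


@dataclass(frozen=True)
class PeakModel:
    """One chromatographic peak to synthesize.

    The kernel is an EMG (Gaussian of width ``sigma`` convolved with an
    exponential of time constant ``tau``; ``tau = 0`` gives a symmetric
    Gaussian), positioned so that its *apex* sits at ``retention_time`` and
    scaled so that its integral over the run equals ``area`` exactly.
    """

    analyte_name: str
    retention_time: float  # minutes
    area: float  # detector-units * min
    sigma: float = 0.05  # Gaussian width, minutes
    tau: float = 0.02  # exponential tailing constant, minutes

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"peak '{self.analyte_name}': sigma must be > 0")
        if self.tau < 0:
            raise ValueError(f"peak '{self.analyte_name}': tau must be >= 0")
        if self.area <= 0:
            raise ValueError(f"peak '{self.analyte_name}': area must be > 0")


@dataclass(frozen=True)
class ResponseModel:
    """Linear detector response with its noise structure.

    slope : detector response per (ug/mL); default from the validated
        quercetin calibration.
    intercept : area at zero concentration. Defaults to 0: a blank carries
        no analyte absorbance at the quercetin retention time (a real
        fitted calibration intercept can still be nonzero through slight
        curvature of the data, but that is a fitting artifact, not a
        property of the detector).
    sigma_additive : SD of the blank-level additive noise, area units. The
        default reproduces the method's detection limit of roughly
        0.05 ug/mL through LOD = 3.3 * sigma / slope.
    cv_proportional : relative SD of the injection-to-injection
        proportional noise; the default puts repeatability RSDs in the
        handful-of-percent range typical of this assay.
    """

    slope: float = 15485.0
    intercept: float = 0.0
    sigma_additive: float = 212.7
    cv_proportional: float = 0.04

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.sigma_additive < 0:
            raise ValueError("sigma_additive must be >= 0")
        if not 0 <= self.cv_proportional < 1:
            raise ValueError("cv_proportional must lie in [0, 1)")

    def expected(self, concentration):
        """Noise-free area at a concentration (vectorized)."""
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept


@dataclass(frozen=True)
class StabilityScenario:
    """Storage condition with a geometric per-day concentration drift.

    Positive rates model apparent concentration gain (solvent evaporation),
    negative rates analyte degradation.
    """

    condition: str
    daily_drift_rate: float

    def __post_init__(self) -> None:
        if self.condition not in STORAGE_CONDITIONS:
            raise ValueError(
                f"condition must be one of {STORAGE_CONDITIONS}, got {self.condition!r}"
            )
        if abs(self.daily_drift_rate) >= 0.2:
            raise ValueError("|daily_drift_rate| must be < 0.2 per day")


@dataclass(frozen=True)
class RobustnessPerturbation:
    """Net effect of a deliberate method change on the quercetin peak."""

    name: str  # e.g. "pH_shift" or "flow_shift"
    area_scale: float  # multiplier on peak area
    retention_shift: float = 0.0  # minutes, added to retention time

    def __post_init__(self) -> None:
        if self.area_scale <= 0:
            raise ValueError("area_scale must be > 0")


@lru_cache(maxsize=256)
def _emg_mode_offset(sigma: float, tau: float) -> float:
    """Apex position of a unit EMG relative to its Gaussian center."""
    k = tau / sigma
    res = minimize_scalar(
        lambda t: -stats.exponnorm.pdf(t, k, loc=0.0, scale=sigma),
        bounds=(-sigma, tau + 2.0 * sigma),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def emg_kernel(
    t: np.ndarray, retention_time: float, sigma: float, tau: float, area: float
) -> np.ndarray:
    """EMG peak evaluated at times ``t``.

    Parameterized through the normalized EMG density, so the kernel
    integrates to ``area`` by construction (the amplitude is derived, never
    supplied), and shifted so the apex falls at ``retention_time``.
    """
    t = np.asarray(t, dtype=float)
    if tau < _TAU_GAUSSIAN_CUTOFF * sigma or tau < 1e-12:
        return area * stats.norm.pdf(t, loc=retention_time, scale=sigma)
    mu = retention_time - _emg_mode_offset(sigma, tau)
    return area * stats.exponnorm.pdf(t, tau / sigma, loc=mu, scale=sigma)


def simulate_trace(
    peaks: list[PeakModel],
    run_length: float = 10.0,
    sampling_rate: float = 100.0,
    baseline_drift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelength_nm: float = 368.0,
) -> ChromatogramTrace:
    """Synthesize a chromatogram: EMG peaks + linear baseline + white noise.

    ``run_length`` is in minutes (default the method's 10-minute run),
    ``sampling_rate`` in points per minute (>= 50), ``baseline_drift`` in
    detector units per minute. Identical seed and parameters give a
    bit-identical trace.
    """
    if sampling_rate < 50:
        raise ValueError("sampling_rate must be >= 50 points/min")
    for p in peaks:
        if not (0.0 < p.retention_time and p.retention_time + 5.0 * (p.sigma + p.tau) < run_length):
            raise PeakWindowError(
                f"peak '{p.analyte_name}' at {p.retention_time} min does not fit "
                f"a {run_length}-min run (needs 5*(sigma+tau) of clearance)"
            )
    n = int(round(run_length * sampling_rate))
    times = np.arange(n + 1, dtype=float) / sampling_rate
    signal = np.zeros_like(times)
    for p in peaks:
        signal += emg_kernel(times, p.retention_time, p.sigma, p.tau, p.area)
    signal += baseline_drift * times
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=times.size)
    annotations = {p.analyte_name: p.retention_time for p in peaks} or None
    return ChromatogramTrace(times, signal, wavelength_nm=wavelength_nm, annotations=annotations)


def simulate_area_table(
    levels: list[float],
    response: ResponseModel | None = None,
    replicates: int = 3,
    days: int = 1,
    seed: int = 0,
    analyte: str = "quercetin",
    condition: str = "fresh",
) -> pd.DataFrame:
    """Simulate a replicate x day peak-area table at the given levels.

    Each observation is ``slope*c + intercept`` plus independent additive
    N(0, sigma_additive) and proportional N(0, cv * signal) noise. Rows are
    ordered (day, replicate, level); zero-concentration rows are valid
    blanks. Row count = len(levels) * replicates * days.
    """
    if len(levels) == 0:
        raise ValueError("levels must be a non-empty list of concentrations")
    levels_arr = np.asarray(levels, dtype=float)
    if np.any(levels_arr < 0):
        raise ValueError("concentrations must be >= 0")
    if replicates < 1 or days < 1:
        raise ValueError("replicates and days must be >= 1")
    response = response or ResponseModel()

    day_idx, rep_idx, lvl_idx = np.meshgrid(
        np.arange(1, days + 1),
        np.arange(1, replicates + 1),
        np.arange(levels_arr.size),
        indexing="ij",
    )
    conc = levels_arr[lvl_idx.ravel()]
    expected = response.expected(conc)
    rng = np.random.default_rng(seed)
    areas = (
        expected
        + rng.normal(0.0, 1.0, conc.size) * response.sigma_additive
        + rng.normal(0.0, 1.0, conc.size) * response.cv_proportional * np.abs(expected)
    )
    return pd.DataFrame(
        {
            "analyte": analyte,
            "concentration_ug_per_ml": conc,
            "replicate": rep_idx.ravel(),
            "day": day_idx.ravel(),
            "condition": condition,
            "area": areas,
        }
    )


def apply_stability(
    table: pd.DataFrame, scenario: StabilityScenario, day: int
) -> pd.DataFrame:
    """Rescale areas for ``day`` days of storage under ``scenario``.

    Areas are multiplied by ``(1 + daily_drift_rate)**day`` (geometric
    single-rate drift); day 0 returns the table unchanged.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    if day == 0:
        return table.copy()
    out = table.copy()
    out["area"] = out["area"] * (1.0 + scenario.daily_drift_rate) ** day
    out["condition"] = scenario.condition
    return out


def apply_perturbation(obj, perturbation: RobustnessPerturbation):
    """Apply a robustness perturbation to peak models or an area table.

    Peak models get their area scaled by ``area_scale`` and retention time
    shifted by ``retention_shift``; an area table has its ``area`` column
    scaled (retention has no meaning there).
    """
    if isinstance(obj, pd.DataFrame):
        out = obj.copy()
        out["area"] = out["area"] * perturbation.area_scale
        return out
    if isinstance(obj, PeakModel):
        return replace(
            obj,
            area=obj.area * perturbation.area_scale,
            retention_time=obj.retention_time + perturbation.retention_shift,
        )
    return [apply_perturbation(p, perturbation) for p in obj]
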