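"""Validation orchestration and report rendering.

``run_validation`` executes the full workflow — calibration and split
curves, linearity criteria, backcalculation accordance, LOD/LOQ,
precision, accuracy, selectivity, robustness, stability — on a single
configuration, producing a :class:`ValidationReport` shaped like the
conventional validation write-up, with pass/fail flags against the
configured thresholds. Sections whose inputs are absent are skipped and
flagged as not assessed; the calibration section is mandatory because
everything downstream consumes its curves.

Inputs can be externally measured peak-area tables (CSV paths) for the
calibration, blank, precision, and accuracy sections, or a simulation
scenario (the default) that generates them with
:mod:`chromval.synthetic`. The selectivity, robustness, and stability
sections are driven by the simulation scenario. Every run is
deterministic given the configured seed, and the report records seed,
configuration hash, and software version.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as cio
from ._utils import round_half_up
from .calibration import (
    CalibrationCurve,
    LinearityAssessment,
    accordance,
    assess_linearity,
    backcalculate,
    fit_table,
    select_curve,
    split_table,
)
from .errors import ChromValError
from .metrics import (
    AccuracyResult,
    PrecisionResult,
    RobustnessComparison,
    SelectivityResult,
    SensitivityResult,
    StabilityResult,
    accuracy,
    lod_loq,
    precision,
    robustness_compare,
    selectivity_check,
    stability,
)
from .peaks import assign_and_resolve, detect_peaks
from .synthetic import (
    PeakModel,
    ResponseModel,
    RobustnessPerturbation,
    StabilityScenario,
    apply_perturbation,
    apply_stability,
    simulate_area_table,
    simulate_trace,
)

__version__ = "0.1.0"

__all__ = [
    "ValidationThresholds",
    "ValidationReport",
    "default_config",
    "run_validation",
    "render_report",
    "parse_report",
]


@dataclass(frozen=True)
class ValidationThresholds:
    """Acceptance bands for the validation decision rules."""

    max_rsd_percent: float = 15.0
    accuracy_low: float = 85.0
    accuracy_high: float = 115.0
    max_slope_rsd: float = 5.0
    min_r: float = 0.99
    min_r2: float = 0.995
    min_resolution: float = 1.5
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.accuracy_low < self.accuracy_high):
            raise ValueError("accuracy band must satisfy 0 < low < high")
        for name in ("max_rsd_percent", "max_slope_rsd", "min_r", "min_r2",
                     "min_resolution", "confidence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict | None) -> "ValidationThresholds":
        return cls(**(d or {}))


def default_config(seed: int = 0) -> dict:
    """The default simulation scenario: the full validation design.

    Levels and replicate structures follow the reference design: nine
    calibration standards in triplicate over three days, ten blanks in
    triplicate, five precision levels with fifteen measurements each, six
    accuracy levels in triplicate, a three-flavonoid selectivity mix at
    0.245 ug/mL, two robustness perturbations, and a 0/5/7-day stability
    grid over three storage conditions.
    """
    return {
        "seed": seed,
        "analyte": "quercetin",
        "thresholds": {},
        "response": {"slope": 15485.0, "intercept": 0.0,
                     "sigma_additive": 212.7, "cv_proportional": 0.04},
        "peak_shape": {"sigma": 0.05, "tau": 0.02},
        "trace": {"run_length": 10.0, "sampling_rate": 100.0,
                  "baseline_drift": 0.0, "noise_sd": 50.0, "min_height": 500.0},
        "calibration": {"levels": [0.14, 0.35, 0.57, 2.8, 5.0, 65.0, 125.0,
                                   185.0, 245.0],
                        "replicates": 3, "days": 3, "split_level": 5.0},
        "blanks": {"n_samples": 10, "replicates": 3},
        "precision": {"levels": [0.35, 0.57, 5.0, 125.0, 185.0],
                      "replicates": 3, "days": 5},
        "accuracy": {"levels": [0.35, 0.49, 0.57, 49.0, 125.0, 196.0],
                     "replicates": 3},
        "selectivity": {"concentration": 0.245, "tolerance": 0.3,
                        "retention_times": {"rutin": 2.5, "quercetin": 3.6,
                                            "kaempferol": 5.4}},
        "robustness": {"concentration": 150.0,
                       "perturbations": [
                           {"name": "pH_shift", "area_scale": 0.9229,
                            "retention_shift": 0.0},
                           {"name": "flow_shift", "area_scale": 0.7035,
                            "retention_shift": -1.3}]},
        "stability": {"levels": [0.57, 5.0, 125.0], "days": [5, 7],
                      "replicates": 3,
                      "scenarios": {"minus20C": 0.02, "plus4C": 0.015,
                                    "roomT": -0.05}},
    }


@dataclass
class ValidationReport:
    """The full validation result bundle with pass/fail flags."""

    curves: dict[str, CalibrationCurve]
    linearity: dict[str, LinearityAssessment]
    accordance: list[dict]
    sensitivity: SensitivityResult | None
    precision: list[PrecisionResult]
    accuracy: list[AccuracyResult]
    selectivity: SelectivityResult | None
    robustness: list[RobustnessComparison]
    stability: list[StabilityResult]
    not_assessed: list[str]
    overall_pass: bool
    meta: dict = field(default_factory=dict)

    # ---- lossless machine serialization -------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            if isinstance(obj, list):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "curves": {k: enc(v) for k, v in self.curves.items()},
            "linearity": {k: enc(v) for k, v in self.linearity.items()},
            "accordance": enc(self.accordance),
            "sensitivity": enc(self.sensitivity),
            "precision": enc(self.precision),
            "accuracy": enc(self.accuracy),
            "selectivity": enc(self.selectivity),
            "robustness": enc(self.robustness),
            "stability": enc(self.stability),
            "not_assessed": list(self.not_assessed),
            "overall_pass": self.overall_pass,
            "meta": enc(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        def sel(x):
            if x is None:
                return None
            return SelectivityResult(
                passed=x["passed"],
                messages=list(x["messages"]),
                matched=dict(x["matched"]),
                resolutions=[(tuple(pair), rs) for pair, rs in x["resolutions"]],
            )

        def lin(x):
            return LinearityAssessment(
                slope_rsd=x["slope_rsd"],
                intercept_ci=tuple(x["intercept_ci"]),
                zero_in_ci=x["zero_in_ci"],
                slope_rsd_pass=x["slope_rsd_pass"],
                r_pass=x["r_pass"],
            )

        return cls(
            curves={k: CalibrationCurve(**v) for k, v in d["curves"].items()},
            linearity={k: lin(v) for k, v in d["linearity"].items()},
            accordance=[dict(r) for r in d["accordance"]],
            sensitivity=(SensitivityResult(**d["sensitivity"])
                         if d["sensitivity"] is not None else None),
            precision=[PrecisionResult(**r) for r in d["precision"]],
            accuracy=[AccuracyResult(**r) for r in d["accuracy"]],
            selectivity=sel(d["selectivity"]),
            robustness=[RobustnessComparison(**r) for r in d["robustness"]],
            stability=[StabilityResult(**r) for r in d["stability"]],
            not_assessed=list(d["not_assessed"]),
            overall_pass=d["overall_pass"],
            meta=dict(d["meta"]),
        )


def _config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _section_table(section: dict | None, builder):
    """External table if the section names one, else the simulated table."""
    if section is None:
        return None
    if "table" in section:
        return cio.read_area_table(section["table"])
    return builder(section)


def run_validation(config: dict) -> ValidationReport:
    """Execute the complete validation workflow for one configuration.

    ``config`` follows the layout of :func:`default_config`; omitting a
    section (or setting it to None) marks it as not assessed. The overall
    verdict aggregates the sections that carry an acceptance band
    (linearity, precision, accuracy, selectivity); sensitivity,
    robustness, and stability are informational.
    """
    config = copy.deepcopy(config)
    seed = int(config.get("seed", 0))
    thresholds = ValidationThresholds.from_dict(config.get("thresholds"))
    analyte = config.get("analyte", "quercetin")
    response = ResponseModel(**config.get("response", {}))
    shape = config.get("peak_shape", {"sigma": 0.05, "tau": 0.02})
    trace_cfg = config.get("trace", {})
    not_assessed: list[str] = []
    gates: list[bool] = []

    # ---- calibration (mandatory) --------------------------------------
    cal_cfg = config.get("calibration")
    if cal_cfg is None:
        raise ChromValError("no calibration data: the workflow needs a curve")
    cal_table = _section_table(
        cal_cfg,
        lambda c: simulate_area_table(
            c["levels"], response, c.get("replicates", 3), c.get("days", 3),
            seed=seed + 1, analyte=analyte,
        ),
    )
    split_level = cal_cfg.get("split_level", 5.0)
    full = fit_table(cal_table)
    low, high = split_table(cal_table, split_level)
    curves = {"nonadjusted": full, "adjusted_low": low, "adjusted_high": high}
    linearity = {
        name: assess_linearity(curve, thresholds.confidence,
                               thresholds.max_slope_rsd, thresholds.min_r)
        for name, curve in curves.items()
    }
    gates.append(all(a.passed for a in linearity.values()))

    accord_rows: list[dict] = []
    level_means = (
        cal_table.groupby("concentration_ug_per_ml")["area"].mean().sort_index()
    )
    for name, curve in curves.items():
        for level, mean_area in level_means.items():
            if level <= 0 or not (curve.range_low <= level <= curve.range_high):
                continue
            obtained = backcalculate(curve, mean_area)
            accord_rows.append({
                "curve": name, "nominal": float(level),
                "obtained": float(obtained),
                "accordance": accordance(level, obtained),
            })

    # ---- sensitivity ---------------------------------------------------
    blank_cfg = config.get("blanks")
    sensitivity = None
    if blank_cfg is None:
        not_assessed.append("sensitivity")
    else:
        blank_table = _section_table(
            blank_cfg,
            lambda c: simulate_area_table(
                [0.0] * c.get("n_samples", 10), response,
                c.get("replicates", 3), 1, seed=seed + 2, analyte=analyte,
            ),
        )
        # the low-range curve covers where the limits live
        sensitivity = lod_loq(blank_table["area"].to_numpy(), low.slope)

    # ---- precision -----------------------------------------------------
    prec_cfg = config.get("precision")
    precision_rows: list[PrecisionResult] = []
    if prec_cfg is None:
        not_assessed.append("precision")
    else:
        prec_table = _section_table(
            prec_cfg,
            lambda c: simulate_area_table(
                c["levels"], response, c.get("replicates", 3),
                c.get("days", 5), seed=seed + 3, analyte=analyte,
            ),
        )
        for level in sorted(prec_table["concentration_ug_per_ml"].unique()):
            curve = select_curve(low, high, level, split_level)
            precision_rows.append(
                precision(prec_table, level, "both", curve,
                          thresholds.max_rsd_percent)
            )
        gates.append(all(r.passed for r in precision_rows))

    # ---- accuracy ------------------------------------------------------
    acc_cfg = config.get("accuracy")
    accuracy_rows: list[AccuracyResult] = []
    if acc_cfg is None:
        not_assessed.append("accuracy")
    else:
        acc_table = _section_table(
            acc_cfg,
            lambda c: simulate_area_table(
                c["levels"], response, c.get("replicates", 3), 1,
                seed=seed + 4, analyte=analyte,
            ),
        )
        for level in sorted(acc_table["concentration_ug_per_ml"].unique()):
            curve = select_curve(low, high, level, split_level)
            accuracy_rows.append(
                accuracy(acc_table, level, curve,
                         (thresholds.accuracy_low, thresholds.accuracy_high))
            )
        gates.append(all(r.passed for r in accuracy_rows))

    # ---- selectivity ---------------------------------------------------
    sel_cfg = config.get("selectivity")
    selectivity = None
    if sel_cfg is None:
        not_assessed.append("selectivity")
    else:
        conc = sel_cfg.get("concentration", 0.245)
        rts = sel_cfg.get("retention_times",
                          {"rutin": 2.5, "quercetin": 3.6, "kaempferol": 5.4})
        peaks_models = [
            PeakModel(name, rt, area=float(response.expected(conc)),
                      sigma=shape["sigma"], tau=shape["tau"])
            for name, rt in sorted(rts.items(), key=lambda kv: kv[1])
        ]
        trace = simulate_trace(
            peaks_models,
            run_length=trace_cfg.get("run_length", 10.0),
            sampling_rate=trace_cfg.get("sampling_rate", 100.0),
            baseline_drift=trace_cfg.get("baseline_drift", 0.0),
            noise_sd=trace_cfg.get("noise_sd", 50.0),
            seed=seed + 5,
        )
        detected = detect_peaks(trace, trace_cfg.get("min_height", 500.0))
        assignment = assign_and_resolve(detected, rts,
                                        sel_cfg.get("tolerance", 0.3))
        selectivity = selectivity_check(assignment, set(rts),
                                        thresholds.min_resolution)
        gates.append(selectivity.passed)

    # ---- robustness ----------------------------------------------------
    rob_cfg = config.get("robustness")
    robustness_rows: list[RobustnessComparison] = []
    if rob_cfg is None:
        not_assessed.append("robustness")
    else:
        conc = rob_cfg.get("concentration", 150.0)
        base_peak = PeakModel(analyte, 3.6, area=float(response.expected(conc)),
                              sigma=shape["sigma"], tau=shape["tau"])

        def summarize(peak_model, sub_seed):
            tr = simulate_trace(
                [peak_model],
                run_length=trace_cfg.get("run_length", 10.0),
                sampling_rate=trace_cfg.get("sampling_rate", 100.0),
                baseline_drift=trace_cfg.get("baseline_drift", 0.0),
                noise_sd=trace_cfg.get("noise_sd", 50.0),
                seed=sub_seed,
            )
            found = detect_peaks(tr, trace_cfg.get("min_height", 500.0))
            return max(found, key=lambda p: p.height)

        optimized = summarize(base_peak, seed + 6)
        for k, pert in enumerate(rob_cfg.get("perturbations", [])):
            perturbation = RobustnessPerturbation(**pert)
            perturbed = summarize(apply_perturbation(base_peak, perturbation),
                                  seed + 7 + k)
            robustness_rows.append(
                robustness_compare(optimized, perturbed, perturbation.name)
            )

    # ---- stability -----------------------------------------------------
    stab_cfg = config.get("stability")
    stability_rows: list[StabilityResult] = []
    if stab_cfg is None:
        not_assessed.append("stability")
    else:
        levels = stab_cfg.get("levels", [0.57, 5.0, 125.0])
        reps = stab_cfg.get("replicates", 3)
        for j, (cond, rate) in enumerate(sorted(stab_cfg["scenarios"].items())):
            scenario = StabilityScenario(cond, rate)
            day0 = simulate_area_table(levels, response, reps, 1,
                                       seed=seed + 10 + j, analyte=analyte)
            for day in stab_cfg.get("days", [5, 7]):
                fresh = simulate_area_table(levels, response, reps, 1,
                                            seed=seed + 10 + j + 100 * day,
                                            analyte=analyte)
                dayx = apply_stability(fresh, scenario, day)
                for level in levels:
                    v0 = day0.loc[np.isclose(day0["concentration_ug_per_ml"],
                                             level), "area"]
                    vx = dayx.loc[np.isclose(dayx["concentration_ug_per_ml"],
                                             level), "area"]
                    stability_rows.append(
                        stability(v0, vx, day, condition=cond, level=level)
                    )

    report = ValidationReport(
        curves=curves,
        linearity=linearity,
        accordance=accord_rows,
        sensitivity=sensitivity,
        precision=precision_rows,
        accuracy=accuracy_rows,
        selectivity=selectivity,
        robustness=robustness_rows,
        stability=stability_rows,
        not_assessed=not_assessed,
        overall_pass=bool(all(gates)),
        meta={"seed": seed, "config_hash": _config_hash(config),
              "version": __version__, "analyte": analyte},
    )
    return report


# ---------------------------------------------------------------------------
# rendering


def _fmt(x, nd=2):
    if x is None:
        return "-"
    return f"{round_half_up(float(x), nd):.{nd}f}"


def _text_table(header: list[str], rows: list[list[str]]) -> list[str]:
    widths = [max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
              for i, h in enumerate(header)]
    out = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    for r in rows:
        out.append("  ".join(c.ljust(w) for c, w in zip(r, widths)))
    return out


def render_report(report: ValidationReport, format: str = "text") -> str:
    """Render a validation report.

    ``text`` gives the human-readable section-by-section report at
    conventional rounding (half-up, two decimals for percentages);
    ``delimited`` gives tab-separated blocks; ``json`` is the lossless
    machine format (``parse_report`` inverts it exactly).
    """
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, allow_nan=True)
    sep = "\t" if format == "delimited" else None
    if format not in ("text", "delimited"):
        raise ValueError("format must be 'text', 'delimited' or 'json'")

    blocks: list[str] = []
    meta = report.meta

    def table(title, header, rows):
        if sep is None:
            blocks.append("\n".join(
                [title, *_text_table(header, rows)]))
        else:
            lines = [f"## {title}", sep.join(header)]
            lines += [sep.join(r) for r in rows]
            blocks.append("\n".join(lines))

    blocks.append(
        f"{meta.get('analyte', 'analyte')} HPLC-DAD method validation report\n"
        f"seed={meta.get('seed')} config={meta.get('config_hash')} "
        f"version={meta.get('version')}"
    )

    table(
        "Linearity",
        ["curve", "range (ug/mL)", "equation", "r2", "r"],
        [[name,
          f"{c.range_low:g}-{c.range_high:g}",
          f"y = {c.slope:.6g}x + {c.intercept:.6g}",
          f"{c.r2:.4f}", f"{c.r:.4f}"]
         for name, c in report.curves.items()],
    )
    table(
        "Backcalculation accordance",
        ["curve", "nominal", "obtained", "accordance (%)"],
        [[r["curve"], f"{r['nominal']:g}", _fmt(r["obtained"]),
          _fmt(r["accordance"])]
         for r in report.accordance],
    )
    table(
        "Linearity criteria",
        ["curve", "slope RSD (%)", "95% CI intercept", "zero in CI", "pass"],
        [[name, _fmt(a.slope_rsd),
          f"({a.intercept_ci[0]:.6g}, {a.intercept_ci[1]:.6g})",
          str(a.zero_in_ci), str(a.passed)]
         for name, a in report.linearity.items()],
    )
    if report.sensitivity is not None:
        s = report.sensitivity
        table("Sensitivity",
              ["blank SD", "slope", "LOD (ug/mL)", "LOQ (ug/mL)"],
              [[_fmt(s.blank_sd), _fmt(s.slope), f"{s.lod:.4g}",
                f"{s.loq:.4g}"]])
    if report.precision:
        table("Precision",
              ["level (ug/mL)", "intraday RSD (%)", "interday RSD (%)", "pass"],
              [[f"{r.level:g}", _fmt(r.intraday_rsd), _fmt(r.interday_rsd),
                str(r.passed)] for r in report.precision])
    if report.accuracy:
        table("Accuracy",
              ["level (ug/mL)", "obtained (ug/mL)", "accuracy (%)", "pass"],
              [[f"{r.level:g}", _fmt(r.obtained_mean), _fmt(r.accuracy),
                str(r.passed)] for r in report.accuracy])
    if report.selectivity is not None:
        s = report.selectivity
        rows = [[name, _fmt(t)] for name, t in sorted(s.matched.items())]
        table("Selectivity: matched analytes",
              ["analyte", "apex (min)"], rows)
        table("Selectivity: resolutions",
              ["pair", "Rs"],
              [[f"{a}/{b}", _fmt(rs)] for (a, b), rs in s.resolutions])
        blocks.append("Selectivity verdict: "
                      + ("pass" if s.passed else "FAIL: " + "; ".join(s.messages)))
    if report.robustness:
        table("Robustness",
              ["parameter", "optimized area", "perturbed area",
               "area (%)", "rt difference (min)"],
              [[r.parameter, f"{r.optimized_area:.6g}",
                f"{r.perturbed_area:.6g}", _fmt(r.area_percent),
                _fmt(r.rt_difference, 1)] for r in report.robustness])
    if report.stability:
        table("Stability",
              ["condition", "level (ug/mL)", "day", "stability (%)"],
              [[r.condition, f"{r.level:g}", str(r.day), _fmt(r.stability)]
               for r in report.stability])
    if report.not_assessed:
        blocks.append("Not assessed: " + ", ".join(report.not_assessed))
    blocks.append("Overall: " + ("PASS" if report.overall_pass else "FAIL"))
    return "\n\n".join(blocks) + "\n"


def parse_report(document: str) -> ValidationReport:
    """Inverse of ``render_report(..., format='json')``."""
    return ValidationReport.from_dict(json.loads(document))
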