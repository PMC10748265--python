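"""Worked-example dataset: summary figures of a quercetin HPLC-DAD validation.

A complete, internally consistent set of reported figures from a quercetin
method validation — calibration equations over the nine-standard design,
the backcalculation grid, slope dispersion statistics, accuracy pairs,
robustness and stability measurements — bundled so the statistics and the
report renderer can be exercised against known numbers without any
simulation step. Only summary quantities are included (raw replicate areas
are not part of the dataset), so dispersion statistics that require raw
replicates, such as intercept confidence bounds or precision RSDs, appear
here as reference values to display, not as reproducible targets.

All concentrations are ug/mL, areas are detector units, times minutes.
"""

from __future__ import annotations

from .metrics import PeakSummary

#: Nine calibration standards of the validated design.
STANDARD_LEVELS = (0.14, 0.35, 0.57, 2.8, 5.0, 65.0, 125.0, 185.0, 245.0)

#: Fitted calibration equations: full-range and the two adjusted sub-ranges.
CALIBRATION_EQUATIONS = {
    "nonadjusted": {
        "slope": 15485.0,
        "intercept": 11659.0,
        "r2": 0.9976,
        "r": 0.9988,
        "range": (0.14, 245.0),
        "slope_sd": 289.47,
        "intercept_ci": (-65423.0, 88741.0),
    },
    "adjusted_1": {  # low range
        "slope": 15262.0,
        "intercept": -271.48,
        "r2": 0.9994,
        "r": 0.9997,
        "range": (0.14, 5.0),
        "slope_sd": 211.13,
        "intercept_ci": (-2006.0, 1463.0),
    },
    "adjusted_2": {  # high range
        "slope": 15317.0,
        "intercept": 42292.0,
        "r2": 0.9954,
        "r": 0.9977,
        "range": (5.0, 245.0),
        "slope_sd": 601.69,
        "intercept_ci": (-247002.0, 331585.0),
    },
}

#: Backcalculated standards (obtained concentration per curve; None where the
#: standard lies outside the adjusted curve's range).
BACKCALCULATION = [
    # (nominal, nonadjusted, adjusted_1, adjusted_2)
    (0.14, -0.62, 0.15, None),
    (0.35, -0.37, 0.41, None),
    (0.57, -0.29, 0.49, None),
    (2.8, 1.98, 2.8, None),
    (5.0, 4.16, 5.0, 2.2),
    (65.0, 64.25, None, 63.0),
    (125.0, 130.06, None, 129.0),
    (185.0, 193.26, None, 193.0),
    (245.0, 236.40, None, 234.0),
]

#: Accuracy study: (real concentration, obtained concentration). The three
#: low levels quantify under adjusted curve 1, the three high under curve 2.
ACCURACY_PAIRS = [
    (0.35, 0.31),
    (0.49, 0.51),
    (0.57, 0.52),
    (49.0, 52.0),
    (125.0, 121.0),
    (196.0, 217.0),
]

#: Reported precision RSDs (percent) — reference display values only; the
#: raw replicates behind them are not part of this dataset.
PRECISION_RSDS = {
    0.35: {"intraday": 5.66, "interday": 9.42},
    0.57: {"intraday": 5.47, "interday": 8.19},
    5.0: {"intraday": 6.74, "interday": 6.87},
    125.0: {"intraday": 2.41, "interday": 7.38},
    185.0: {"intraday": 2.64, "interday": 7.18},
}

#: Robustness study: optimized vs deliberately perturbed runs.
ROBUSTNESS = {
    "pH": {
        "optimized": PeakSummary(area=7_304_837.0, retention_time=3.8),
        "perturbed": PeakSummary(area=6_741_931.0, retention_time=3.8),
    },
    "flow_rate": {
        "optimized": PeakSummary(area=6_111_868.0, retention_time=3.7),
        "perturbed": PeakSummary(area=4_299_546.0, retention_time=2.4),
    },
}

#: Stability study: mean triplicate areas by condition, level and day.
STABILITY_MEANS = {
    ("minus20C", 0.57): {0: 7129.0, 5: 7929.0, 7: 8737.0},
    ("minus20C", 5.0): {0: 71_284.0, 5: 78_463.0, 7: 77_477.0},
    ("minus20C", 125.0): {0: 2_170_741.0, 5: 2_347_331.0, 7: 2_155_391.0},
    ("plus4C", 0.57): {0: 8048.0, 5: 8758.0, 7: 8697.0},
    ("plus4C", 5.0): {0: 74_799.0, 5: 83_905.0, 7: 78_945.0},
    ("plus4C", 125.0): {0: 2_123_647.0, 5: 2_318_601.0, 7: 2_255_046.0},
    ("roomT", 0.57): {0: 7799.0, 5: 6674.0, 7: 5336.0},
    ("roomT", 5.0): {0: 73_338.0, 5: 75_772.0, 7: 67_525.0},
    ("roomT", 125.0): {0: 2_246_811.0, 5: 2_474_717.0, 7: 2_378_043.0},
}

#: Retention times of the three flavonoids under the optimized method.
RETENTION_TIMES = {"rutin": 2.5, "quercetin": 3.6, "kaempferol": 5.4}

#: Reported detection and quantification limits.
LOD_UG_PER_ML = 0.046
LOQ_UG_PER_ML = 0.14
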