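# Methods

This note records the models, conventions, and numerical choices behind
`chromval`, and what the synthetic study can and cannot demonstrate.

## Detector response and calibration

Peak area is modeled as a straight line in concentration,
`y = m·c + b`, fitted by unweighted ordinary least squares on every
replicate point (not level means). The dispersion statistics are the
classical OLS ones: slope and intercept standard errors, Pearson `r`,
`r² = r·r`, and the RMS residual with `n − 2` degrees of freedom.
Weighted regression is deliberately out of scope: the workflow's remedy
for heteroscedasticity is the *split-curve* strategy — the nine-level
design (0.14, 0.35, 0.57, 2.8, 5, 65, 125, 185, 245 µg/mL) is divided at
the 5 µg/mL standard into a low-range and a high-range curve of five
levels each, the split level belonging to both so each adjusted range
stays anchored. Quantification inverts the curve whose range covers the
expected concentration; concentrations at the split level use the
low-range curve, since the detection and quantification limits live in
that range. Backcalculated concentrations may be negative under the
full-range curve (areas below its fitted intercept); this is reported,
not clipped.

Linearity is judged by three configurable rules: `r ≥ 0.99` (and
`r² > 0.995` as a threshold option), slope RSD `s_m/m × 100 < 5 %`, and
zero contained in the 95 % Student-t interval `b ± t₀.₉₇₅,ₙ₋₂·SE(b)`.
The zero-inclusion check carries a numerical pad of `1e-7·max(1, |b|)`
so an exactly collinear fit — whose interval degenerates to a point up
to float rounding — counts as containing zero.

## Synthetic chromatograms

Peaks are exponentially modified Gaussians: a Gaussian of width σ
convolved with an exponential of time constant τ (τ = 0 gives a
symmetric peak). The kernel is parameterized through the normalized EMG
density so its integral equals the requested area *exactly* — the
amplitude is derived, never supplied — which makes integration tests
analytic. Because the EMG mode sits downstream of the Gaussian center,
the kernel is shifted by a numerically computed mode offset so the
*apex* lands at the nominal retention time; apex-recovery tests then
read ±0.02 min against 2.5 / 3.6 / 5.4 min for rutin, quercetin, and
kaempferol. τ below 10⁻⁶·σ falls back to a pure Gaussian (the EMG pdf is
numerically unstable there). A trace is the kernel sum plus a linear
baseline (`units/min` drift) and i.i.d. Gaussian noise; defaults are a
10-minute run at 100 points/min. The stepped flow-rate program of the
underlying method is not mechanistically simulated; robustness effects
enter as net area/retention perturbations (below).

Defaults (chosen once, before any acceptance measurement): σ = 0.05 min
and τ = 0.02 min — narrow peaks with the mild residual tailing typical
of reversed-phase quercetin chromatography (tailing factor ≈ 1.03);
trace noise 50 detector units, giving single-digit-thousands
signal-to-noise at mid concentrations.

## Peak processing

The baseline estimate is a centered rolling median (default 2-min
window), valid because peaks occupy well under half of any window;
noise is the scaled median absolute deviation of the residual. Peaks
are local maxima above baseline + `min_height` (with prominence
`min_height/2` so noise ripples on a flank are not counted), and each
boundary is walked outward until the baseline-subtracted signal falls
inside the noise band (3× the robust noise, floored at `boundary_frac`
of the tallest excursion — default 10⁻⁶ — so noiseless traces
terminate). Adjacent peaks are cut at the valley minimum, guaranteeing
disjoint intervals. Integration is the trapezoid of the
baseline-subtracted signal, with the integration baseline the straight
line between the boundary intensities. The tailing factor is the USP
convention `T = W₀₅/(2f)` at 5 % of apex height; resolution uses
baseline width `w = 4σ` estimated from the half-height width
(`w = 1.698·W₅₀`). Assignment is greedy nearest-retention-time within a
tolerance (default 0.3 min), deterministic by (distance, apex time);
one peak matching two expected analytes within tolerance is an
ambiguity error rather than a silent choice.

## Peak-area tables and their noise

An observation at concentration `c` is
`y = m·c + b + ε_add + ε_prop`, with `ε_add ~ N(0, σ_add²)` and
`ε_prop ~ N(0, (cv·(m·c + b))²)`, laid out as level × replicate × day
rows; zero-concentration rows are valid blanks. Defaults: slope 15 485
area units per µg/mL (the validated response); intercept 0, because a
blank injection carries no analyte absorbance at the quercetin
retention time — a real *fitted* calibration intercept can still be
far from zero through slight curvature of real data, which is a fitting
artifact the generator intentionally does not emulate; σ_add = 212.7
area units, the blank SD implied by a ≈0.046 µg/mL detection limit
through `δ = LOD·s/3.3`; cv = 0.04, which puts repeatability RSDs near
4 %, inside the 2.4–6.7 % band typical of this assay. The generator has
*no between-day variance component*, so simulated interday RSD tracks
intraday RSD; real intermediate precision (7–9 %) is larger than the
simulation produces. Passing precision tests therefore demonstrates the
statistics, not day-effect realism.

Storage drift is geometric: areas scale by `(1 + r)^day`, a single
per-day rate per condition (two time points per condition cannot
identify anything richer). Default rates — +0.02/day at −20 °C,
+0.015/day at 4 °C (slow evaporative concentration), −0.05/day at room
temperature (degradation) — emulate the observed magnitudes (≈110 % at
day 5 frozen, ≈68 % at day 7 ambient). Robustness perturbations are
data, not chemistry: a named multiplicative area scale and additive
retention shift (pH: ×0.9229, 0.0 min; flow: ×0.7035, −1.3 min).

## Validation statistics

- `LOD = 3.3·δ/s`, and `LOQ = LOD·(10/3.3)` so the LOQ/LOD ratio is
  exact by construction; δ is the sample SD of the blank areas (ten
  blanks in triplicate by default).
- Precision is computed on backcalculated concentrations when a curve is
  supplied, otherwise on areas; the two agree only for a zero-intercept
  line, hence the explicit switch. Intraday RSD is the within-day RSD
  averaged over days; interday RSD pools all replicates across days —
  the conservative of the two common readings (the alternative, RSD of
  daily means, is smaller whenever day effects are absent).
- Accuracy is the mean backcalculated concentration over the level's
  replicates divided by the nominal value (×100), judged against
  85–115 %. Replicate count is a configuration value (designs with n = 3
  and n = 5 both occur in practice).
- Stability compares triplicate means; day 0 against itself is defined
  as exactly 100 %.
- Selectivity passes when every required analyte is matched exactly once
  and all adjacent resolutions are ≥ 1.5.

All thresholds (15 % RSD, 85–115 %, 5 % slope RSD, r ≥ 0.99, Rs ≥ 1.5,
95 % confidence) live in `ValidationThresholds`. The orchestrated report
gates its overall verdict on linearity, precision, accuracy, and
selectivity; sensitivity, robustness, and stability have no universal
acceptance band and are reported as informational. Sections without
inputs are flagged not-assessed and never affect the verdict.

## Parameter-recovery diagnostics

Proportional noise makes calibration strongly heteroscedastic: the
highest standards carry both the largest leverage and the largest
variance, so the classical homoscedastic OLS slope interval materially
undercovers the generating slope over the full nine-level range (≈77 %
observed at cv = 5 % instead of the nominal 95 %). Recovery checks
therefore use heteroskedasticity-consistent (HC3) slope intervals
(`slope_confidence_interval(robust=True)`), which restore ≈95 %
coverage. This is a diagnostic-only choice: the reported linearity
statistic `s_m` remains the classical OLS standard error, which is the
convention validation reports use.

Relatedly, splitting does not shrink the high curve's *absolute*
residual SD below the global curve's (the global fit pools the tiny
low-level residuals into its RMS); the guaranteed and meaningful
property, which the tests assert, is that each sub-curve's residual SD
is no larger than the SD of the global line's residuals restricted to
the same sub-range — least-squares optimality on the subset, and
precisely why splitting improves low-range backcalculation.

## Numerical conventions and problem sizes

Report percentages display with half-up rounding to two decimals (one
decimal for accuracy), full precision retained internally; the JSON
render is lossless and `parse_report` inverts it exactly. Seeds are
explicit arguments everywhere; identical seed and parameters give
bit-identical traces, tables, and reports. Simulation sizes mirror the
reference design throughout — 9 levels × 3 replicates × 3 days for
calibration, 30 blanks, 5 levels × 15 measurements for precision, 6
levels × 3 for accuracy, 200 seeded repetitions for coverage and 100
for the repeatability envelope — small enough that the whole suite runs
in seconds while keeping Monte-Carlo envelopes comfortably away from
their bounds.

## Known limitations

The generator draws areas directly for table-based sections rather than
integrating a trace per injection; the trace path is exercised by the
selectivity, robustness, and round-trip pipelines. No between-day
variance, no calibration curvature, no carryover, no co-elution or
matrix interferents, no spectral (multi-wavelength) dimension — the DAD
wavelength is metadata only. Printed-figure reproduction is limited to
quantities whose inputs are printed: intercept confidence bounds and
precision RSDs from the worked example require raw replicate areas that
are not part of the dataset, so they are covered by a CI-oracle
equivalence test and a seeded repeatability envelope instead.
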