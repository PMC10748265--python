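#!/usr/bin/env python
"""Generate the synthetic validation study: chromatograms and area tables.

Writes, under results/data/:
  * selectivity_trace.txt — the three-flavonoid chromatogram (0.245 ug/mL each)
  * calibration.csv       — nine standards, triplicate x 3 days
  * blanks.csv            — ten blanks in triplicate
  * precision.csv         — five levels, triplicate x 5 days
  * accuracy.csv          — six levels in triplicate
"""

import argparse
from pathlib import Path

from chromval import io as cio
from chromval.synthetic import (
    RETENTION_TIMES,
    STANDARD_LEVELS,
    PeakModel,
    ResponseModel,
    simulate_area_table,
    simulate_trace,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

out = Path(__file__).resolve().parent.parent / "results" / "data"
out.mkdir(parents=True, exist_ok=True)
response = ResponseModel()

peaks = [PeakModel(n, rt, area=float(response.expected(0.245)))
         for n, rt in sorted(RETENTION_TIMES.items(), key=lambda kv: kv[1])]
trace = simulate_trace(peaks, noise_sd=50.0, seed=args.seed + 5)
cio.write_trace(trace, out / "selectivity_trace.txt")

tables = {
    "calibration.csv": simulate_area_table(list(STANDARD_LEVELS), response,
                                           3, 3, seed=args.seed + 1),
    "blanks.csv": simulate_area_table([0.0] * 10, response, 3, 1,
                                      seed=args.seed + 2),
    "precision.csv": simulate_area_table([0.35, 0.57, 5.0, 125.0, 185.0],
                                         response, 3, 5, seed=args.seed + 3),
    "accuracy.csv": simulate_area_table([0.35, 0.49, 0.57, 49.0, 125.0, 196.0],
                                        response, 3, 1, seed=args.seed + 4),
}
for name, table in tables.items():
    cio.write_area_table(table, out / name)
    print(f"{name}: {len(table)} observations")
print(f"selectivity trace: {trace.times.size} samples over "
      f"{trace.times[-1]:.0f} min -> {out}")
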