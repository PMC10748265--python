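#!/usr/bin/env python
"""Integrate the selectivity chromatogram and assign the three flavonoids.

Reads results/data/selectivity_trace.txt (run 01 first), detects and
integrates peaks, computes tailing factors, assigns rutin / quercetin /
kaempferol by retention time, and reports pairwise resolutions. Writes
results/peaks.csv.
"""

import pandas as pd

from chromval import io as cio
from chromval.metrics import selectivity_check
from chromval.peaks import assign_and_resolve, detect_peaks
from chromval.synthetic import RETENTION_TIMES

from pathlib import Path

results = Path(__file__).resolve().parent.parent / "results"
trace = cio.read_trace(results / "data" / "selectivity_trace.txt")

detected = detect_peaks(trace, min_height=500.0)
assignment = assign_and_resolve(detected, RETENTION_TIMES, tolerance=0.3)
verdict = selectivity_check(assignment, set(RETENTION_TIMES))

frame = pd.DataFrame(
    [{"analyte": p.assigned_analyte or "unassigned",
      "apex_min": round(p.apex_time, 3),
      "area": round(p.area, 1), "height": round(p.height, 1),
      "tailing": round(p.tailing, 3) if p.tailing else None}
     for p in assignment.peaks]
)
frame.to_csv(results / "peaks.csv", index=False)

print(frame.to_string(index=False))
for (a, b), rs in assignment.resolutions:
    print(f"Rs {a}/{b} = {rs:.2f}")
print("selectivity:", "pass" if verdict.passed else verdict.messages)
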