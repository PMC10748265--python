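"""Text I/O: traces, peak-area tables, and YAML configuration.

Traces are two-column delimited text (minutes, intensity) with ``#``
header comments carrying wavelength and analyte annotations; area tables
are CSV with the canonical observation columns; configuration is flat
YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .peaks import ChromatogramTrace

AREA_COLUMNS = [
    "analyte",
    "concentration_ug_per_ml",
    "replicate",
    "day",
    "condition",
    "area",
]


def write_trace(trace: ChromatogramTrace, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# wavelength_nm: {trace.wavelength_nm:g}"]
    if trace.annotations:
        for name, rt in sorted(trace.annotations.items()):
            lines.append(f"# analyte: {name} retention_time_min: {rt:g}")
    lines.append("# time_min\tintensity")
    for t, y in zip(trace.times, trace.intensities):
        lines.append(f"{t:.10g}\t{y:.12g}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> ChromatogramTrace:
    path = Path(path)
    wavelength = 368.0
    annotations: dict[str, float] = {}
    for line in path.read_text().splitlines():
        if not line.startswith("#"):
            continue
        body = line.lstrip("#").strip()
        if body.startswith("wavelength_nm:"):
            wavelength = float(body.split(":", 1)[1])
        elif body.startswith("analyte:"):
            parts = body.split()
            annotations[parts[1]] = float(parts[3])
    data = np.loadtxt(path, comments="#")
    return ChromatogramTrace(
        data[:, 0], data[:, 1], wavelength_nm=wavelength,
        annotations=annotations or None,
    )


def write_area_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=AREA_COLUMNS)


def read_area_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(AREA_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"area table missing columns: {sorted(missing)}")
    return table


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    return cfg


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
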