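"""Trace CSV and report JSON files.

TraceFileSchema: CSV with header columns time_s, sap_measured_mmhg,
sap_true_mmhg, map_true_mmhg, fluid_rate_ml_kg_min, ne_rate_ug_kg_min,
blood_volume_ml, hct_fraction, lactate_mmol_l, shed_volume_ml on a
uniform 0.2 s grid. Pressures are stored to 0.01 mmHg and rates to
0.001 — enough to re-derive every performance metric exactly from file.
Columns are header-keyed, so column order does not matter on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import PressureTrace

__all__ = [
    "TRACE_COLUMNS",
    "REPORT_KEYS",
    "TraceParseError",
    "write_trace",
    "read_trace",
    "write_report",
    "report_from_result",
]

TRACE_COLUMNS: tuple[str, ...] = (
    "time_s",
    "sap_measured_mmhg",
    "sap_true_mmhg",
    "map_true_mmhg",
    "fluid_rate_ml_kg_min",
    "ne_rate_ug_kg_min",
    "blood_volume_ml",
    "hct_fraction",
    "lactate_mmol_l",
    "shed_volume_ml",
)

_COLUMN_DECIMALS = {
    "time_s": 1,
    "sap_measured_mmhg": 2,
    "sap_true_mmhg": 2,
    "map_true_mmhg": 2,
    "fluid_rate_ml_kg_min": 3,
    "ne_rate_ug_kg_min": 3,
    "blood_volume_ml": 3,
    "hct_fraction": 4,
    "lactate_mmol_l": 3,
    "shed_volume_ml": 3,
}

REPORT_KEYS: tuple[str, ...] = (
    "arm", "seed", "rising_time_s", "pct_in_target", "pct_below",
    "pct_above", "mdpe", "mdape", "wobble", "global_score",
    "n_adjustments", "fluid_volume_ml_kg", "mean_ne_rate_ug_kg_min",
    "config_digest",
)


class TraceParseError(ValueError):
    """A trace file violates the schema; the message names the row."""


def write_trace(path: str | Path, arrays: dict) -> None:
    """Write a trajectory dict (TraceFileSchema columns) to CSV."""
    missing = set(TRACE_COLUMNS) - set(arrays)
    if missing:
        raise ValueError(f"missing trace columns: {sorted(missing)}")
    cols = {c: np.asarray(arrays[c], dtype=float) for c in TRACE_COLUMNS}
    n = len(cols["time_s"])
    with open(path, "w", newline="") as fh:
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        fmts = [f"%.{_COLUMN_DECIMALS[c]}f" for c in TRACE_COLUMNS]
        for i in range(n):
            fh.write(
                ",".join(f % cols[c][i] for f, c in zip(fmts, TRACE_COLUMNS)) + "\n"
            )


def read_trace(path: str | Path, dt_tol: float = 1e-6):
    """Read a trace CSV back into (PressureTrace, DataFrame).

    Validates the header (by name, any column order), the uniform time
    grid and value finiteness; errors name the first offending row.
    """
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise TraceParseError(f"missing column(s): {sorted(missing)}")
    extra = set(df.columns) - set(TRACE_COLUMNS)
    if extra:
        raise TraceParseError(f"unknown column(s): {sorted(extra)}")
    df = df[list(TRACE_COLUMNS)]
    if len(df) == 0:
        raise TraceParseError("trace file has no data rows")
    values = df.to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
    if bad.size:
        raise TraceParseError(f"non-finite value at data row {int(bad[0]) + 1}")
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        steps = np.diff(t)
        dt = steps[0]
        off = np.flatnonzero(np.abs(steps - dt) > max(dt_tol, 1e-9 * abs(dt)))
        if off.size:
            i = int(off[0])
            raise TraceParseError(
                f"non-uniform time grid at t={t[i + 1]:g} s (data row {i + 2}): "
                f"step {steps[i]:g} != {dt:g}"
            )
    else:
        dt = 0.2
    trace = PressureTrace(
        sap=df["sap_measured_mmhg"].to_numpy(), dt=float(dt), t0=float(t[0])
    )
    return trace, df


def report_from_result(result, config_digest: str) -> dict:
    """ReportFileSchema dict for one run."""
    rep = result.report
    out = {
        "arm": result.arm,
        "seed": result.seed,
        "rising_time_s": rep.rising_time,
        "pct_in_target": rep.pct_in_target,
        "pct_below": rep.pct_below,
        "pct_above": rep.pct_above,
        "mdpe": rep.mdpe,
        "mdape": rep.mdape,
        "wobble": rep.wobble,
        "global_score": rep.global_score,
        "n_adjustments": rep.n_adjustments,
        "fluid_volume_ml_kg": result.fluid_volume_ml_kg,
        "mean_ne_rate_ug_kg_min": result.mean_ne_rate_ug_kg_min,
        "shed_volume_ml_kg": result.shed_volume_ml_kg,
        "target_reached": rep.target_reached,
        "died": result.died,
        "config_digest": config_digest,
    }
    return out


def write_report(path: str | Path, report: dict) -> None:
    """Write a report dict as deterministic (sorted-key) JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
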