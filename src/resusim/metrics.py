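"""Two-phase performance analysis of a resuscitation pressure trace.

The resuscitation hour is split into a rising phase (until systolic
pressure first reaches the lower target threshold, sustained) and a
stabilization phase. Varvel-style performance-error statistics and
band-occupancy fractions are computed on the stabilization segment:

* PE_i    = 100 * (SAP_i - setpoint) / setpoint, setpoint 85 mmHg
* MDPE    = median(PE)                        (bias, %)
* MDAPE   = median(|PE|)                      (inaccuracy, %)
* wobble  = median(|PE_i - MDPE|)             (intra-run variability, %)
* global score = (MDAPE + wobble) / (% time in target) * 100
  (lower is better; undefined when the trace never enters the band)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .controllers import TargetSpec, count_adjustments

__all__ = [
    "PressureTrace",
    "PerformanceReport",
    "split_rising_phase",
    "performance_errors",
    "mdpe",
    "mdape",
    "wobble",
    "band_fractions",
    "global_score",
    "summarize",
]

#: consecutive samples (2 s at the 0.2 s grid) a threshold crossing must
#: hold to count as sustained, rejecting single-sample noise spikes
SUSTAIN_SAMPLES = 10


@dataclass
class PressureTrace:
    """Uniformly sampled systolic arterial pressure series."""

    sap: np.ndarray  # mmHg
    dt: float = 0.2  # s
    t0: float = 0.0  # s

    def __post_init__(self) -> None:
        self.sap = np.asarray(self.sap, dtype=float)
        if self.sap.ndim != 1:
            raise ValueError("sap must be one-dimensional")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sap.size and (
            not np.all(np.isfinite(self.sap)) or np.any(self.sap < 0)
        ):
            raise ValueError("sap values must be finite and >= 0")

    def __len__(self) -> int:
        return self.sap.size

    @property
    def duration(self) -> float:
        return self.sap.size * self.dt


@dataclass
class PerformanceReport:
    """Per-run performance summary; stabilization metrics are None when
    the target was never reached."""

    rising_time: float  # s
    pct_in_target: float | None
    pct_below: float | None
    pct_above: float | None
    mdpe: float | None
    mdape: float | None
    wobble: float | None
    global_score: float | None
    n_adjustments: int
    target_reached: bool = True
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "rising_time_s": self.rising_time,
            "pct_in_target": self.pct_in_target,
            "pct_below": self.pct_below,
            "pct_above": self.pct_above,
            "mdpe": self.mdpe,
            "mdape": self.mdape,
            "wobble": self.wobble,
            "global_score": self.global_score,
            "n_adjustments": self.n_adjustments,
            "target_reached": self.target_reached,
        }
        d.update(self.extras)
        return d


def split_rising_phase(
    trace: PressureTrace,
    spec: TargetSpec | None = None,
    sustain: int = SUSTAIN_SAMPLES,
) -> tuple[int, float]:
    """Index and time of the end of the rising phase.

    Returns ``(i, rising_time)`` where ``i`` is the first sample from
    which SAP stays at or above the rising threshold for at least
    ``sustain`` consecutive samples, and ``rising_time = i * dt``. If no
    sustained crossing exists, ``i == len(trace)`` (empty stabilization
    segment) and the rising time is the full duration.
    """
    if len(trace) == 0:
        raise ValueError("trace is empty")
    spec = spec or TargetSpec()
    above = trace.sap >= spec.rising_threshold
    if trace.sap.size < sustain:
        return trace.sap.size, trace.duration
    # run length of consecutive True starting at each index
    window = np.lib.stride_tricks.sliding_window_view(above, sustain)
    sustained = window.all(axis=1)
    idx = np.flatnonzero(sustained)
    if idx.size == 0:
        return trace.sap.size, trace.duration
    return int(idx[0]), float(idx[0]) * trace.dt


def performance_errors(
    segment: PressureTrace | np.ndarray, spec: TargetSpec | None = None
) -> np.ndarray:
    """Percent performance error of every sample relative to the setpoint."""
    spec = spec or TargetSpec()
    sap = segment.sap if isinstance(segment, PressureTrace) else np.asarray(segment, float)
    if sap.size == 0:
        raise ValueError("segment is empty")
    return 100.0 * (sap - spec.setpoint) / spec.setpoint


def mdpe(pe: np.ndarray) -> float:
    """Median performance error (bias, %)."""
    pe = np.asarray(pe, float)
    if pe.size == 0:
        raise ValueError("empty PE series")
    return float(np.median(pe))


def mdape(pe: np.ndarray) -> float:
    """Median absolute performance error (inaccuracy, %)."""
    pe = np.asarray(pe, float)
    if pe.size == 0:
        raise ValueError("empty PE series")
    return float(np.median(np.abs(pe)))


def wobble(pe: np.ndarray) -> float:
    """Median absolute deviation of each PE from the MDPE (%)."""
    pe = np.asarray(pe, float)
    if pe.size == 0:
        raise ValueError("empty PE series")
    return float(np.median(np.abs(pe - np.median(pe))))


def band_fractions(
    segment: PressureTrace | np.ndarray, spec: TargetSpec | None = None
) -> tuple[float, float, float]:
    """(pct_in, pct_below, pct_above) occupancy of the target band.

    Band edges are inclusive: samples exactly at band_low or band_high
    count as in target.
    """
    spec = spec or TargetSpec()
    sap = segment.sap if isinstance(segment, PressureTrace) else np.asarray(segment, float)
    if sap.size == 0:
        raise ValueError("segment is empty")
    n = sap.size
    below = np.count_nonzero(sap < spec.band_low)
    above = np.count_nonzero(sap > spec.band_high)
    inside = n - below - above
    return 100.0 * inside / n, 100.0 * below / n, 100.0 * above / n


def global_score(mdape_pct: float, wobble_pct: float, pct_in: float) -> float:
    """Composite performance score: (MDAPE + wobble) / pct-in-target * 100.

    Lower is better. Undefined (ValueError) when pct_in is zero.
    """
    if pct_in <= 0:
        raise ValueError("global score undefined when time in target is zero")
    return (mdape_pct + wobble_pct) / pct_in * 100.0


def summarize(
    trace: PressureTrace,
    commands=None,
    spec: TargetSpec | None = None,
    mode: str = "closed_loop",
    n_adjustments: int | None = None,
) -> PerformanceReport:
    """Full two-phase performance report for one resuscitation trace.

    PE statistics and band fractions are computed on the stabilization
    segment only. ``n_adjustments`` may be supplied directly (e.g. a
    manual policy's own intervention counter); otherwise it is counted
    from the command sequence.
    """
    spec = spec or TargetSpec()
    if n_adjustments is None:
        n_adjustments = count_adjustments(commands or [], mode=mode)
    split, rising_time = split_rising_phase(trace, spec)
    if split >= len(trace):
        return PerformanceReport(
            rising_time=rising_time,
            pct_in_target=None, pct_below=None, pct_above=None,
            mdpe=None, mdape=None, wobble=None, global_score=None,
            n_adjustments=n_adjustments, target_reached=False,
        )
    seg = trace.sap[split:]
    pe = performance_errors(seg, spec)
    pct_in, pct_below, pct_above = band_fractions(seg, spec)
    md, mda, wob = mdpe(pe), mdape(pe), wobble(pe)
    score = global_score(mda, wob, pct_in) if pct_in > 0 else None
    full_in, full_below, full_above = band_fractions(trace.sap, spec)
    return PerformanceReport(
        rising_time=rising_time,
        pct_in_target=pct_in, pct_below=pct_below, pct_above=pct_above,
        mdpe=md, mdape=mda, wobble=wob, global_score=score,
        n_adjustments=n_adjustments, target_reached=True,
        extras={
            "pct_in_target_full": full_in,
            "pct_below_full": full_below,
            "pct_above_full": full_above,
        },
    )
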