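"""Resuscitation decision policies.

Five arms act on measured systolic arterial pressure (SAP) sampled
every 0.2 s, all titrating toward a hypotensive-resuscitation target
of SAP 85 mmHg (band 80-90):

* ``PIController`` (CL-PI) — proportional-integral fluid control on the
  continuous SAP stream, with conditional-integration anti-windup.
* ``FuzzyController`` (CL-FL) — fluid rate from a fuzzy map of the
  error of the one-minute mean SAP, weighted-mean defuzzification.
* ``CombinedController`` (CL-FNE) — PI fluid plus a fuzzy norepinephrine
  channel coupled through a fluid-volume/NE-rate ratio: the cumulative
  fluid given sets the norepinephrine ceiling, so fluid always leads.
* ``ManualFluidPolicy`` (M-F) — a clinician's standardized protocol:
  fixed 2 mL/kg/min infusion toggled with hysteresis around the target
  at a human decision cadence.
* ``ManualFNEPolicy`` (M-FNE) — standardized alternating escalation of
  10 mL/kg boluses (max 3) and norepinephrine steps every 3 min, with a
  de-escalation rule above 88 mmHg.

Every fluid channel passes through the shared safety clamp: at most
4 mL/kg/min while SAP < 70 mmHg and 2.5 mL/kg/min at or above 70,
applied against the instantaneous measured SAP at command time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .plant import InfusionCommand

__all__ = [
    "TargetSpec",
    "ClampSchedule",
    "PIConfig",
    "PIController",
    "FuzzySet",
    "FuzzyConfig",
    "FuzzyController",
    "CombinedConfig",
    "CombinedController",
    "ManualFConfig",
    "ManualFluidPolicy",
    "ManualFNEConfig",
    "ManualFNEPolicy",
    "clamp_rate",
    "fuzzy_eval",
    "count_adjustments",
    "DEFAULT_FLUID_SETS",
    "DEFAULT_NE_SETS",
]


@dataclass(frozen=True)
class TargetSpec:
    """Pressure target: setpoint, target band and rising-phase threshold."""

    setpoint: float = 85.0
    band_low: float = 80.0
    band_high: float = 90.0
    rising_threshold: float = 80.0

    def __post_init__(self) -> None:
        if not self.band_low < self.setpoint < self.band_high:
            raise ValueError("require band_low < setpoint < band_high")
        if self.rising_threshold > self.band_low:
            raise ValueError("rising_threshold must be <= band_low")


@dataclass(frozen=True)
class ClampSchedule:
    """SAP-dependent maximal fluid rate."""

    low_sap_threshold: float = 70.0
    max_rate_below: float = 4.0
    max_rate_at_or_above: float = 2.5

    def __post_init__(self) -> None:
        if not self.max_rate_below >= self.max_rate_at_or_above > 0:
            raise ValueError("require max_rate_below >= max_rate_at_or_above > 0")


def clamp_rate(raw_rate: float, sap: float, schedule: ClampSchedule) -> float:
    """Clip a fluid rate to [0, limit(sap)]; the 70 mmHg boundary takes
    the lower (2.5 mL/kg/min) limit."""
    if not math.isfinite(raw_rate):
        raise ValueError("raw_rate must be finite")
    limit = (
        schedule.max_rate_below
        if sap < schedule.low_sap_threshold
        else schedule.max_rate_at_or_above
    )
    return min(max(raw_rate, 0.0), limit)


# ---------------------------------------------------------------------------
# PI fluid controller

@dataclass(frozen=True)
class PIConfig:
    kp: float = 0.08  # mL/kg/min per mmHg
    ki: float = 0.002  # mL/kg/min per mmHg*s
    dt: float = 0.2  # s
    target: TargetSpec = field(default_factory=TargetSpec)
    clamp: ClampSchedule = field(default_factory=ClampSchedule)
    anti_windup: bool = True

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0:
            raise ValueError("gains must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


class PIController:
    """PI fluid controller on the continuous SAP stream.

    Anti-windup by conditional integration: the integral is frozen
    whenever integrating would push the raw command further into the
    clamp (either the SAP-dependent ceiling or the zero floor).
    """

    def __init__(self, cfg: PIConfig):
        self.cfg = cfg
        self.integral = 0.0  # mmHg*s
        self.last_rate = 0.0  # mL/kg/min

    def update(self, sap: float) -> float:
        cfg = self.cfg
        if not math.isfinite(sap):
            # sensor fault: hold the last commanded rate
            return self.last_rate
        e = cfg.target.setpoint - sap
        if cfg.anti_windup:
            raw_probe = cfg.kp * e + cfg.ki * self.integral
            limit = (
                cfg.clamp.max_rate_below
                if sap < cfg.clamp.low_sap_threshold
                else cfg.clamp.max_rate_at_or_above
            )
            saturating_high = raw_probe >= limit and e > 0
            saturating_low = raw_probe <= 0.0 and e < 0
            if not (saturating_high or saturating_low):
                self.integral += e * cfg.dt
        else:
            self.integral += e * cfg.dt
        raw = cfg.kp * e + cfg.ki * self.integral
        self.last_rate = clamp_rate(raw, sap, cfg.clamp)
        return self.last_rate


# ---------------------------------------------------------------------------
# fuzzy controller

@dataclass(frozen=True)
class FuzzySet:
    """Triangular membership (a, b, c); +/-inf feet make shoulders."""

    label: str
    a: float
    b: float
    c: float

    def membership(self, e: float) -> float:
        if e == self.b:
            return 1.0
        if self.a < e < self.b:
            return 1.0 if math.isinf(self.a) else (e - self.a) / (self.b - self.a)
        if self.b < e < self.c:
            return 1.0 if math.isinf(self.c) else (self.c - e) / (self.c - self.b)
        return 0.0


# error universe: e = setpoint - meanSAP (mmHg), positive = hypotensive
DEFAULT_ERROR_SETS: tuple[FuzzySet, ...] = (
    FuzzySet("NB", -math.inf, -10.0, -5.0),
    FuzzySet("NS", -10.0, -5.0, 0.0),
    FuzzySet("ZE", -5.0, 0.0, 5.0),
    FuzzySet("PS", 0.0, 5.0, 10.0),
    FuzzySet("PM", 5.0, 10.0, 20.0),
    FuzzySet("PB", 10.0, 20.0, math.inf),
)

#: fluid rule table, mL/kg/min
DEFAULT_FLUID_SETS: dict[str, float] = {
    "NB": 0.0, "NS": 0.0, "ZE": 0.0, "PS": 0.8, "PM": 1.6, "PB": 4.0,
}

#: norepinephrine rule table, ug/kg/min (used by the combined controller)
DEFAULT_NE_SETS: dict[str, float] = {
    "NB": 0.0, "NS": 0.0, "ZE": 0.2, "PS": 0.5, "PM": 1.0, "PB": 2.0,
}


@dataclass(frozen=True)
class FuzzyConfig:
    window: float = 60.0  # s between output updates
    dt: float = 0.2  # s, sample grid
    target: TargetSpec = field(default_factory=TargetSpec)
    error_sets: tuple[FuzzySet, ...] = DEFAULT_ERROR_SETS
    output_singletons: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLUID_SETS)
    )
    clamp: ClampSchedule | None = field(default_factory=ClampSchedule)

    def __post_init__(self) -> None:
        if self.window <= 0 or self.dt <= 0:
            raise ValueError("window and dt must be positive")
        missing = {s.label for s in self.error_sets} - set(self.output_singletons)
        if missing:
            raise ValueError(f"no output singleton for fuzzy sets: {sorted(missing)}")
        if any(v < 0 for v in self.output_singletons.values()):
            raise ValueError("output singletons must be >= 0")


def fuzzy_eval(mean_sap: float, cfg: FuzzyConfig) -> float:
    """Defuzzified output for a window-mean SAP (weighted singleton mean).

    Returns 0 when the error falls outside every membership support
    (out-of-universe input).
    """
    e = cfg.target.setpoint - mean_sap
    num = 0.0
    den = 0.0
    for fs in cfg.error_sets:
        mu = fs.membership(e)
        if mu > 0.0:
            num += mu * cfg.output_singletons[fs.label]
            den += mu
    return num / den if den > 0.0 else 0.0


class FuzzyController:
    """Fuzzy fluid controller updating once per completed window.

    Accumulates the 0.2 s SAP samples, recomputes the defuzzified rate
    from the window-mean SAP each time a window completes, and holds it
    in between. The safety clamp is applied per sample against the
    instantaneous SAP so the rate limits hold between window updates.
    """

    def __init__(self, cfg: FuzzyConfig):
        self.cfg = cfg
        self._n_window = max(1, round(cfg.window / cfg.dt))
        self._sum = 0.0
        self._count = 0
        self.current_raw = 0.0  # defuzzified, pre-clamp

    def update(self, sap: float) -> float:
        self._sum += sap
        self._count += 1
        if self._count >= self._n_window:
            mean_sap = self._sum / self._count
            self.current_raw = fuzzy_eval(mean_sap, self.cfg)
            self._sum = 0.0
            self._count = 0
        if self.cfg.clamp is not None:
            return clamp_rate(self.current_raw, sap, self.cfg.clamp)
        return self.current_raw


# ---------------------------------------------------------------------------
# combined fluid + norepinephrine controller

@dataclass(frozen=True)
class CombinedConfig:
    pi: PIConfig = field(default_factory=PIConfig)
    fuzzy: FuzzyConfig = field(
        default_factory=lambda: FuzzyConfig(
            output_singletons=dict(DEFAULT_NE_SETS), clamp=None
        )
    )
    ratio: float = 10.0  # mL/kg of cumulative fluid per ug/kg/min of allowed NE
    ne_enable_sap: float = 88.0  # NE pathway retargeted only below this mean SAP
    ne_decay_factor: float = 0.5  # per window, while mean SAP above band_high
    ne_ceiling: float = 3.0  # ug/kg/min hard cap

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if not 0.0 <= self.ne_decay_factor < 1.0:
            raise ValueError("ne_decay_factor must be in [0, 1)")


class CombinedController:
    """CL-FNE: PI fluid channel plus fuzzy NE channel under a ratio rule.

    The norepinephrine command can never exceed cumulative fluid volume
    divided by the configured ratio — a fluid volume buys a
    norepinephrine allowance, so the pressor cannot run ahead of volume
    resuscitation. Conditional rules: the NE target is refreshed from
    the fuzzy map only while the window-mean SAP is below
    ``ne_enable_sap``, and decays geometrically while the mean sits
    above the target band.
    """

    def __init__(self, cfg: CombinedConfig):
        self.cfg = cfg
        self.pi = PIController(cfg.pi)
        self._n_window = max(1, round(cfg.fuzzy.window / cfg.fuzzy.dt))
        self._sum = 0.0
        self._count = 0
        self.ne_held = 0.0  # fuzzy NE target, pre-ceiling
        self.cumulative_fluid = 0.0  # mL/kg

    def update(self, sap: float, t: float) -> InfusionCommand:
        cfg = self.cfg
        fluid = self.pi.update(sap)
        self.cumulative_fluid += fluid * cfg.pi.dt / 60.0

        self._sum += sap
        self._count += 1
        if self._count >= self._n_window:
            mean_sap = self._sum / self._count
            if mean_sap > cfg.fuzzy.target.band_high:
                self.ne_held *= cfg.ne_decay_factor
            elif mean_sap < cfg.ne_enable_sap:
                self.ne_held = fuzzy_eval(mean_sap, cfg.fuzzy)
            self._sum = 0.0
            self._count = 0

        ne = min(self.ne_held, self.cumulative_fluid / cfg.ratio, cfg.ne_ceiling)
        return InfusionCommand(t=t, fluid_rate=fluid, ne_rate=max(0.0, ne))


# ---------------------------------------------------------------------------
# standardized manual protocols

@dataclass(frozen=True)
class ManualFConfig:
    fixed_rate: float = 2.0  # mL/kg/min
    decision_tick: float = 2.0  # s, human cadence
    start_below: float = 83.0  # mmHg
    stop_at_or_above: float = 87.0  # mmHg

    def __post_init__(self) -> None:
        if self.fixed_rate <= 0 or self.decision_tick <= 0:
            raise ValueError("fixed_rate and decision_tick must be positive")
        if self.start_below >= self.stop_at_or_above:
            raise ValueError("hysteresis requires start_below < stop_at_or_above")


class ManualFluidPolicy:
    """M-F: fixed-rate infusion toggled with hysteresis by a clinician."""

    def __init__(self, cfg: ManualFConfig, dt: float = 0.2):
        self.cfg = cfg
        self.dt = dt
        self._tick_every = max(1, round(cfg.decision_tick / dt))
        self._i = 0
        self.on = False
        self.interventions = 0

    def update(self, sap: float) -> float:
        if self._i % self._tick_every == 0:
            if not self.on and sap < self.cfg.start_below:
                self.on = True
                self.interventions += 1
            elif self.on and sap >= self.cfg.stop_at_or_above:
                self.on = False
                self.interventions += 1
        self._i += 1
        return self.cfg.fixed_rate if self.on else 0.0


@dataclass(frozen=True)
class ManualFNEConfig:
    bolus_volume: float = 10.0  # mL/kg
    bolus_rate: float = 2.0  # mL/kg/min
    max_boluses: int = 3
    ne_start: float = 0.1  # ug/kg/min
    escalation_interval: float = 180.0  # s
    escalation_steps: tuple[float, ...] = (0.1, 0.2, 0.4, 0.8)  # increments
    decrease_trigger: float = 88.0  # mmHg
    ne_ceiling: float = 3.0  # ug/kg/min
    decision_tick: float = 2.0  # s
    target_reached_at: float = 85.0  # mmHg; "target not reached" below this
    start_below: float = 83.0  # mmHg; physician starts/resumes the infusion
    stop_at_or_above: float = 87.0  # mmHg; physician stops the infusion
    strict_alternation: bool = True

    def __post_init__(self) -> None:
        if self.max_boluses < 0:
            raise ValueError("max_boluses must be >= 0")
        for name in ("bolus_volume", "bolus_rate", "ne_start",
                     "escalation_interval", "ne_ceiling", "decision_tick"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


class ManualFNEPolicy:
    """M-FNE: alternating fluid boluses and norepinephrine escalation.

    The clinician gives up to three 10 mL/kg boluses at 2 mL/kg/min,
    starting or resuming the pump while SAP is below the start threshold
    and stopping it on reaching the stop threshold or on completing the
    bolus volume. Norepinephrine starts at 0.1 ug/kg/min and, while the
    target is unreached, steps up through the configured increments
    every 3 min (doubling schedule by default: 0.1 -> 0.2 -> 0.4 -> 0.8
    -> 1.6). Under strict alternation a completed bolus must be followed
    by an NE change before the next bolus starts. When SAP exceeds the
    decrease trigger, the rate is stepped down by the arithmetic mean of
    the two most recent increments, at the same 3-min cadence.
    """

    def __init__(self, cfg: ManualFNEConfig, dt: float = 0.2):
        self.cfg = cfg
        self.dt = dt
        self._tick_every = max(1, round(cfg.decision_tick / dt))
        self._i = 0
        self.bolus_active = False
        self.bolus_delivered = 0.0  # mL/kg within current bolus
        self.boluses_given = 0
        self.total_bolus_volume = 0.0  # mL/kg
        self._bolus_exhausted = True  # no interrupted bolus pending
        self.ne = 0.0
        self._ne_started = False
        self._step_idx = 0
        self._increments: list[float] = []
        self._last_ne_change: float | None = None
        self._need_ne_before_bolus = False
        self.interventions = 0

    def _ne_due(self, t: float) -> bool:
        return (
            self._last_ne_change is None
            or t - self._last_ne_change >= self.cfg.escalation_interval - 1e-9
        )

    def update(self, sap: float, t: float) -> InfusionCommand:
        cfg = self.cfg
        if self._i % self._tick_every == 0:
            unreached = sap < cfg.target_reached_at

            # fluid bolus bookkeeping
            if self.bolus_active:
                if self.bolus_delivered >= cfg.bolus_volume - 1e-9:
                    self.bolus_active = False
                    self._bolus_exhausted = True
                    self._need_ne_before_bolus = cfg.strict_alternation
                    self.interventions += 1  # pump stopped, bolus complete
                elif sap >= cfg.stop_at_or_above:
                    self.bolus_active = False
                    self.interventions += 1  # pump stopped at target
            elif sap < cfg.start_below:
                if not self._bolus_exhausted:
                    # resume the interrupted bolus's remaining volume
                    self.bolus_active = True
                    self.interventions += 1
                elif (
                    self.boluses_given < cfg.max_boluses
                    and not self._need_ne_before_bolus
                ):
                    self.bolus_active = True
                    self.bolus_delivered = 0.0
                    self._bolus_exhausted = False
                    self.boluses_given += 1
                    self.interventions += 1  # pump started

            # norepinephrine escalation / de-escalation
            if sap > cfg.decrease_trigger and self.ne > 0.0 and self._ne_due(t):
                recent = self._increments[-2:]
                dec = sum(recent) / len(recent) if recent else self.ne
                self.ne = max(0.0, self.ne - dec)
                self._last_ne_change = t
                self.interventions += 1
            elif unreached and self._ne_due(t):
                if not self._ne_started:
                    self.ne = cfg.ne_start
                    self._ne_started = True
                    self._increments.append(cfg.ne_start)
                    self._last_ne_change = t
                    self._need_ne_before_bolus = False
                    self.interventions += 1
                elif self._step_idx < len(cfg.escalation_steps):
                    inc = cfg.escalation_steps[self._step_idx]
                    self._step_idx += 1
                    self.ne = min(cfg.ne_ceiling, self.ne + inc)
                    self._increments.append(inc)
                    self._last_ne_change = t
                    self._need_ne_before_bolus = False
                    self.interventions += 1
        self._i += 1

        fluid = cfg.bolus_rate if self.bolus_active else 0.0
        if self.bolus_active:
            delivered = fluid * self.dt / 60.0
            self.bolus_delivered += delivered
            self.total_bolus_volume += delivered
        return InfusionCommand(t=t, fluid_rate=fluid, ne_rate=self.ne)


def count_adjustments(commands, mode: str = "closed_loop") -> int:
    """Number of rate changes in a time-ordered command sequence.

    Counts indices where either the fluid or the norepinephrine rate
    differs from the previous command. For the manual policies this
    equals the intervention counter those policies maintain (they only
    change rates at decision ticks).
    """
    if mode not in ("manual", "closed_loop"):
        raise ValueError("mode must be 'manual' or 'closed_loop'")
    n = 0
    prev = None
    for cmd in commands:
        if prev is not None and (
            cmd.fluid_rate != prev.fluid_rate or cmd.ne_rate != prev.ne_rate
        ):
            n += 1
        prev = cmd
    return n
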