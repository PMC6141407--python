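"""Full in-silico experiment: shock induction, five arms, cohort summaries.

Timeline per virtual rat (all phases on the 0.2 s grid):

1. 5 min rapid exsanguination driving true MAP down to 30 mmHg,
2. 60 min fixed-pressure clamp holding MAP in [30, 35] mmHg by
   withdrawing or re-infusing shed blood (shed volume recorded),
3. 60 min resuscitation under one of the five arm policies.

Cohorts sample per-rat physiology from the population spec with
deterministically derived child seeds, so any member re-runs standalone
bit-identically, and report median (IQR) summaries per arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import controllers as ctl
from . import metrics as mx
from . import plant as pl

__all__ = [
    "ARMS",
    "ProtocolConfig",
    "RunResult",
    "CohortSummary",
    "run_arm",
    "run_cohort",
    "shock_cohort",
    "cohort_member",
    "biomarker_delta",
    "summarize_cohort_table",
]

ARMS: tuple[str, ...] = ("M-F", "CL-PI", "CL-FL", "M-FNE", "CL-FNE")

#: cohort-summary variables drawn from each run's report and totals
SUMMARY_VARIABLES: tuple[str, ...] = (
    "rising_time_s", "pct_in_target", "pct_below", "pct_above",
    "mdpe", "mdape", "wobble", "global_score", "n_adjustments",
    "fluid_volume_ml_kg", "mean_ne_rate_ug_kg_min", "shed_volume_ml_kg",
    "baseline_map_mmhg", "peak_lactate_mmol_l",
    "lactate_shock_end_mmol_l", "lactate_resus_end_mmol_l",
    "hct_shock_end", "hct_resus_end",
)


@dataclass(frozen=True)
class ProtocolConfig:
    dt: float = 0.2  # s, control and sampling grid
    ramp_duration: float = 300.0  # s, rapid exsanguination
    clamp_duration: float = 3600.0  # s, fixed-pressure shock
    resus_duration: float = 3600.0  # s
    shock_map_low: float = 30.0  # mmHg
    shock_map_high: float = 35.0  # mmHg
    ramp_gain: float = 0.5  # mL/min per mmHg per kg toward MAP 30
    ramp_max_rate: float = 3.0  # mL/min withdrawal cap
    clamp_gain: float = 0.5  # mL/min per mmHg per kg inside the clamp
    target: ctl.TargetSpec = field(default_factory=ctl.TargetSpec)
    clamp_schedule: ctl.ClampSchedule = field(default_factory=ctl.ClampSchedule)
    pi: ctl.PIConfig = field(default_factory=ctl.PIConfig)
    fuzzy: ctl.FuzzyConfig = field(default_factory=ctl.FuzzyConfig)
    combined: ctl.CombinedConfig = field(default_factory=ctl.CombinedConfig)
    manual_f: ctl.ManualFConfig = field(default_factory=ctl.ManualFConfig)
    manual_fne: ctl.ManualFNEConfig = field(default_factory=ctl.ManualFNEConfig)
    population: pl.PopulationSpec = field(default_factory=pl.PopulationSpec)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("ramp_duration", "clamp_duration", "resus_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RunResult:
    """Everything produced by one virtual-rat run of one arm."""

    arm: str
    seed: int
    params: pl.PlantParams
    trace: mx.PressureTrace  # measured SAP over the resuscitation phase
    arrays: dict  # full resuscitation-phase trajectory (TraceFileSchema columns)
    report: mx.PerformanceReport
    fluid_volume_ml_kg: float
    mean_ne_rate_ug_kg_min: float
    shed_volume_ml_kg: float
    baseline_map_mmhg: float
    peak_lactate_mmol_l: float
    lactate_shock_end_mmol_l: float
    lactate_resus_end_mmol_l: float
    hct_shock_end: float
    hct_resus_end: float
    died: bool = False

    def summary_row(self) -> dict:
        row = {
            "fluid_volume_ml_kg": self.fluid_volume_ml_kg,
            "mean_ne_rate_ug_kg_min": self.mean_ne_rate_ug_kg_min,
            "shed_volume_ml_kg": self.shed_volume_ml_kg,
            "baseline_map_mmhg": self.baseline_map_mmhg,
            "peak_lactate_mmol_l": self.peak_lactate_mmol_l,
            "lactate_shock_end_mmol_l": self.lactate_shock_end_mmol_l,
            "lactate_resus_end_mmol_l": self.lactate_resus_end_mmol_l,
            "hct_shock_end": self.hct_shock_end,
            "hct_resus_end": self.hct_resus_end,
        }
        row.update(self.report.to_dict())
        row["rising_time_s"] = self.report.rising_time
        return row


def run_shock_phase(
    params: pl.PlantParams,
    config: ProtocolConfig,
    rng: np.random.Generator,
    state: pl.HemodynamicState | None = None,
) -> tuple[pl.HemodynamicState, dict]:
    """Exsanguination ramp plus fixed-pressure clamp.

    Returns the post-shock state and a dict with the shed volume per kg,
    peak lactate, shock-end lactate/hct and the fraction of clamp time
    the true MAP spent inside the clamp band.
    """
    dt = config.dt
    state = state if state is not None else pl.initial_state(params)
    no_infusion = pl.InfusionCommand(t=0.0, fluid_rate=0.0, ne_rate=0.0)
    g = config.ramp_gain * params.weight_kg

    n_ramp = round(config.ramp_duration / dt)
    for _ in range(n_ramp):
        map_, _ = pl.pressure_from_state(state, params)
        rate = min(g * max(0.0, map_ - config.shock_map_low), config.ramp_max_rate)
        state = pl.step(state, no_infusion, rate, dt, params, rng)

    n_clamp = round(config.clamp_duration / dt)
    in_band = 0
    peak_lactate = state.lactate
    for _ in range(n_clamp):
        rate = pl.clamp_shock_controller(
            state, params,
            band_low=config.shock_map_low, band_high=config.shock_map_high,
            gain=config.clamp_gain, max_rate=config.ramp_max_rate,
        )
        if rate == 0.0:
            in_band += 1
        state = pl.step(state, no_infusion, rate, dt, params, rng)
        if state.lactate > peak_lactate:
            peak_lactate = state.lactate
    info = {
        "shed_volume_ml_kg": state.shed_blood / params.weight_kg,
        "peak_lactate_mmol_l": peak_lactate,
        "lactate_shock_end_mmol_l": state.lactate,
        "hct_shock_end": state.hct,
        "clamp_in_band_fraction": in_band / n_clamp if n_clamp else 1.0,
    }
    return state, info


def _make_policy(arm: str, config: ProtocolConfig):
    """Uniform (sap, t) -> (fluid_rate, ne_rate) adapter for each arm."""
    if arm == "M-F":
        policy = ctl.ManualFluidPolicy(config.manual_f, dt=config.dt)
        return policy, lambda sap, t: (policy.update(sap), 0.0)
    if arm == "CL-PI":
        policy = ctl.PIController(config.pi)
        return policy, lambda sap, t: (policy.update(sap), 0.0)
    if arm == "CL-FL":
        policy = ctl.FuzzyController(config.fuzzy)
        return policy, lambda sap, t: (policy.update(sap), 0.0)
    if arm == "M-FNE":
        policy = ctl.ManualFNEPolicy(config.manual_fne, dt=config.dt)

        def fne(sap, t, policy=policy):
            cmd = policy.update(sap, t)
            return cmd.fluid_rate, cmd.ne_rate

        return policy, fne
    if arm == "CL-FNE":
        policy = ctl.CombinedController(config.combined)

        def clfne(sap, t, policy=policy):
            cmd = policy.update(sap, t)
            return cmd.fluid_rate, cmd.ne_rate

        return policy, clfne
    raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")


def run_arm(
    arm: str,
    params: pl.PlantParams,
    seed: int,
    config: ProtocolConfig | None = None,
) -> RunResult:
    """Run the full shock + resuscitation protocol for one virtual rat.

    Bit-reproducible from ``(arm, params, seed, config)``. Runs whose
    blood volume is exhausted are flagged ``died`` and carry no
    performance report (mirroring exclusion from performance analysis).
    """
    config = config or ProtocolConfig()
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    rng = np.random.default_rng(seed)
    dt = config.dt

    state = pl.initial_state(params)
    baseline_map, _ = pl.pressure_from_state(state, params)
    state, shock = run_shock_phase(params, config, rng, state)

    policy, decide = _make_policy(arm, config)
    n = round(config.resus_duration / dt)
    t_arr = np.arange(n) * dt
    sap_meas = np.empty(n)
    sap_true = np.empty(n)
    map_true = np.empty(n)
    fluid_arr = np.empty(n)
    ne_arr = np.empty(n)
    bv_arr = np.empty(n)
    hct_arr = np.empty(n)
    lac_arr = np.empty(n)
    shed_arr = np.empty(n)

    died = False
    for i in range(n):
        m, s = pl.pressure_from_state(state, params)
        meas = s + state.noise_state
        if meas < 0.0:
            meas = 0.0
        fluid, ne = decide(meas, i * dt)
        sap_meas[i] = meas
        sap_true[i] = s
        map_true[i] = m
        fluid_arr[i] = fluid
        ne_arr[i] = ne
        bv_arr[i] = state.blood_volume
        hct_arr[i] = state.hct
        lac_arr[i] = state.lactate
        shed_arr[i] = state.shed_blood
        cmd = pl.InfusionCommand(t=i * dt, fluid_rate=fluid, ne_rate=ne)
        state = pl.step(state, cmd, 0.0, dt, params, rng)
        if state.exhausted:
            died = True
            # truncate the recorded trajectory at the event
            sl = slice(0, i + 1)
            t_arr, sap_meas, sap_true, map_true = (
                t_arr[sl], sap_meas[sl], sap_true[sl], map_true[sl])
            fluid_arr, ne_arr, bv_arr, hct_arr, lac_arr, shed_arr = (
                fluid_arr[sl], ne_arr[sl], bv_arr[sl], hct_arr[sl],
                lac_arr[sl], shed_arr[sl])
            break

    trace = mx.PressureTrace(sap=sap_meas, dt=dt, t0=0.0)
    manual = arm in ("M-F", "M-FNE")
    if n == 0:
        report = mx.PerformanceReport(
            rising_time=0.0,
            pct_in_target=None, pct_below=None, pct_above=None,
            mdpe=None, mdape=None, wobble=None, global_score=None,
            n_adjustments=0, target_reached=False,
        )
    elif died:
        n_adj = int(policy.interventions) if manual else 0
        report = mx.PerformanceReport(
            rising_time=float(len(trace)) * dt,
            pct_in_target=None, pct_below=None, pct_above=None,
            mdpe=None, mdape=None, wobble=None, global_score=None,
            n_adjustments=n_adj, target_reached=False,
        )
    else:
        if manual:
            n_adj = int(policy.interventions)
        else:
            n_adj = int(np.count_nonzero(
                (np.diff(fluid_arr) != 0.0) | (np.diff(ne_arr) != 0.0)
            ))
        report = mx.summarize(trace, spec=config.target, n_adjustments=n_adj)

    arrays = {
        "time_s": t_arr,
        "sap_measured_mmhg": sap_meas,
        "sap_true_mmhg": sap_true,
        "map_true_mmhg": map_true,
        "fluid_rate_ml_kg_min": fluid_arr,
        "ne_rate_ug_kg_min": ne_arr,
        "blood_volume_ml": bv_arr,
        "hct_fraction": hct_arr,
        "lactate_mmol_l": lac_arr,
        "shed_volume_ml": shed_arr,
    }
    return RunResult(
        arm=arm,
        seed=int(seed),
        params=params,
        trace=trace,
        arrays=arrays,
        report=report,
        fluid_volume_ml_kg=float(np.sum(fluid_arr) * dt / 60.0),
        mean_ne_rate_ug_kg_min=float(np.mean(ne_arr)) if len(ne_arr) else 0.0,
        shed_volume_ml_kg=shock["shed_volume_ml_kg"],
        baseline_map_mmhg=baseline_map,
        peak_lactate_mmol_l=shock["peak_lactate_mmol_l"],
        lactate_shock_end_mmol_l=shock["lactate_shock_end_mmol_l"],
        lactate_resus_end_mmol_l=state.lactate,
        hct_shock_end=shock["hct_shock_end"],
        hct_resus_end=state.hct,
        died=died,
    )


# ---------------------------------------------------------------------------
# cohorts

def _child_seed(master_seed: int, arm_index: int, rat_index: int, stream: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), arm_index, rat_index, stream])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def cohort_member(
    master_seed: int,
    arm: str,
    rat_index: int,
    config: ProtocolConfig | None = None,
) -> RunResult:
    """Run one cohort member standalone, bit-identical to its in-cohort run."""
    config = config or ProtocolConfig()
    arm_index = ARMS.index(arm)
    rat_rng = np.random.default_rng(_child_seed(master_seed, arm_index, rat_index, 0))
    params = pl.sample_rat(config.population, rat_rng)
    sim_seed = _child_seed(master_seed, arm_index, rat_index, 1)
    return run_arm(arm, params, sim_seed, config)


def shock_cohort(
    n: int,
    master_seed: int = 0,
    config: ProtocolConfig | None = None,
) -> dict:
    """Shock phase only (ramp + clamp) over ``n`` sampled virtual rats.

    Returns arrays of per-rat baseline MAP, shed volume per kg, peak
    lactate and clamp-band occupancy — the plant's calibration
    quantities against the cohort's printed physiologic anchors.
    """
    config = config or ProtocolConfig()
    stream = len(ARMS)  # distinct from any arm's seed stream
    base_map, shed, peak_lac, in_band = [], [], [], []
    for j in range(n):
        rat_rng = np.random.default_rng(_child_seed(master_seed, stream, j, 0))
        params = pl.sample_rat(config.population, rat_rng)
        rng = np.random.default_rng(_child_seed(master_seed, stream, j, 1))
        state = pl.initial_state(params)
        m, _ = pl.pressure_from_state(state, params)
        _, info = run_shock_phase(params, config, rng, state)
        base_map.append(m)
        shed.append(info["shed_volume_ml_kg"])
        peak_lac.append(info["peak_lactate_mmol_l"])
        in_band.append(info["clamp_in_band_fraction"])
    return {
        "baseline_map_mmhg": np.asarray(base_map),
        "shed_volume_ml_kg": np.asarray(shed),
        "peak_lactate_mmol_l": np.asarray(peak_lac),
        "clamp_in_band_fraction": np.asarray(in_band),
    }


@dataclass
class CohortSummary:
    """Median (Q1-Q3) per arm and variable; linear-interpolation quartiles."""

    n_per_arm: int
    arms: tuple[str, ...]
    master_seed: int
    stats: dict  # arm -> variable -> {"median", "q1", "q3", "n"}
    quartile_method: str = "linear"

    def to_dict(self) -> dict:
        return {
            "n_per_arm": self.n_per_arm,
            "arms": list(self.arms),
            "master_seed": self.master_seed,
            "quartile_method": self.quartile_method,
            "stats": self.stats,
        }


def run_cohort(
    n_per_arm: int,
    arms: tuple[str, ...] = ARMS,
    master_seed: int = 0,
    config: ProtocolConfig | None = None,
) -> tuple[CohortSummary, list[RunResult]]:
    """Simulate ``n_per_arm`` virtual rats in each arm and summarize.

    Death-flagged runs are excluded from performance summaries (their
    physiologic totals still appear in the result list). Medians and
    quartiles use numpy's linear interpolation convention.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    config = config or ProtocolConfig()
    results: list[RunResult] = []
    stats: dict = {}
    for arm in arms:
        arm_rows = []
        for j in range(n_per_arm):
            res = cohort_member(master_seed, arm, j, config)
            results.append(res)
            if not res.died:
                arm_rows.append(res.summary_row())
        stats[arm] = _summarize_rows(arm_rows)
    summary = CohortSummary(
        n_per_arm=n_per_arm, arms=tuple(arms),
        master_seed=int(master_seed), stats=stats,
    )
    return summary, results


def _summarize_rows(rows: list[dict]) -> dict:
    out: dict = {}
    for var in SUMMARY_VARIABLES:
        vals = [r[var] for r in rows if r.get(var) is not None]
        if not vals:
            out[var] = {"median": None, "q1": None, "q3": None, "n": 0}
            continue
        arr = np.asarray(vals, dtype=float)
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
        out[var] = {
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "n": int(arr.size),
        }
    return out


def biomarker_delta(result: RunResult) -> tuple[float, float] | None:
    """(lactate change, hct change) from shock end to resuscitation end.

    Resuscitated runs show a lactate fall and crystalloid haemodilution
    (hct fall), larger in fluid-only arms. Death-flagged runs return None.
    """
    if result.died:
        return None
    return (
        result.lactate_resus_end_mmol_l - result.lactate_shock_end_mmol_l,
        result.hct_resus_end - result.hct_shock_end,
    )


def format_median_iqr(median: float | None, q1: float | None, q3: float | None,
                      digits: int = 1) -> str:
    if median is None:
        return "-"
    return f"{median:.{digits}f} ({q1:.{digits}f}-{q3:.{digits}f})"


def summarize_cohort_table(summary: CohortSummary) -> str:
    """Markdown table of median (Q1-Q3) per arm; JSON twin via to_dict()."""
    arms = summary.arms
    lines = [
        "| Variable | " + " | ".join(arms) + " |",
        "|---" * (len(arms) + 1) + "|",
    ]
    for var in SUMMARY_VARIABLES:
        cells = []
        for arm in arms:
            s = summary.stats[arm][var]
            cells.append(format_median_iqr(s["median"], s["q1"], s["q3"]))
        lines.append(f"| {var} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
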