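"""Virtual-rat hemodynamic plant.

A deliberately minimal digital twin of a rat in controlled haemorrhagic
shock, built to reproduce the printed physiologic anchors of the in-vivo
preparation it stands in for: ~348 g animals, baseline MAP ~89 mmHg, a
~25 mL/kg exsanguination bringing MAP to 30-35 mmHg, lactate peaking
near 5.6 mmol/L after an hour of shock, and crystalloid haemodilution.

Model structure
---------------
* One arterial pressure, driven by a logistic pressure-volume curve
  normalised so that full blood volume maps exactly to baseline MAP.
* Two fluid compartments: plasma and an interstitial sink. Infused
  crystalloid enters plasma and leaks first-order toward a retention
  equilibrium (a fixed fraction of infused volume stays intravascular
  at steady state).
* Red-cell mass changes only with whole-blood withdrawal/re-infusion,
  so hematocrit dilutes under crystalloid and is conserved under
  proportional hemorrhage.
* Norepinephrine acts through a first-order effect site feeding a Hill
  dose-response multiplier on MAP.
* Lactate follows first-order production (driven by hypoperfusion below
  a critical MAP) and clearance kinetics.
* Measurement noise is AR(1) Gaussian on the 0.2 s sampling grid,
  applied to systolic pressure only.

Integration is explicit Euler at the control grid (0.2 s); all model
time constants are >= 10 s so this is comfortably stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "PlantParams",
    "HemodynamicState",
    "InfusionCommand",
    "PopulationSpec",
    "initial_state",
    "pressure_from_state",
    "step",
    "clamp_shock_controller",
    "sample_rat",
]


@dataclass(frozen=True)
class PlantParams:
    """Physiologic parameters of one virtual rat.

    Volumes are in mL, pressures in mmHg, rates per minute unless noted.
    """

    weight: float = 348.0  # g
    blood_volume_per_kg: float = 64.0  # mL/kg, rodent convention
    baseline_hct: float = 0.40  # fraction
    baseline_map: float = 89.0  # mmHg
    map_curve_midpoint: float = 0.65  # fraction of total blood volume
    map_curve_steepness: float = 18.0  # dimensionless
    pulse_pressure_baseline: float = 25.0  # mmHg added to MAP at full volume
    pulse_pressure_hypovolemia_factor: float = 1.0  # exponent on the volume curve
    crystalloid_escape_rate: float = 0.10  # /min, plasma -> interstitium
    crystalloid_retention_fraction: float = 0.25  # intravascular fraction at SS
    ne_emax: float = 0.6  # maximal fractional MAP increase
    ne_ec50: float = 0.5  # ug/kg/min
    ne_hill: float = 1.5  # dimensionless
    ne_effect_tau: float = 30.0  # s, effect-site time constant
    lactate_baseline: float = 1.5  # mmol/L
    lactate_production_gain: float = 0.23  # mmol/L/min per unit hypoperfusion
    lactate_clearance_rate: float = 0.02  # /min
    map_critical: float = 60.0  # mmHg; production rises below this
    noise_sd: float = 2.0  # mmHg, stationary SD of measurement noise
    noise_ar1: float = 0.8  # AR(1) coefficient at the 0.2 s grid

    def __post_init__(self) -> None:
        positive = (
            "weight", "blood_volume_per_kg", "baseline_map",
            "map_curve_midpoint", "map_curve_steepness",
            "pulse_pressure_baseline", "pulse_pressure_hypovolemia_factor",
            "ne_emax", "ne_ec50", "ne_hill", "ne_effect_tau",
            "lactate_baseline", "lactate_production_gain",
            "lactate_clearance_rate", "map_critical",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"PlantParams.{name} must be strictly positive")
        if not 0.0 < self.baseline_hct < 1.0:
            raise ValueError("baseline_hct must be in (0, 1)")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValueError("noise_ar1 must be in [0, 1)")
        if not 0.0 < self.crystalloid_retention_fraction <= 1.0:
            raise ValueError("crystalloid_retention_fraction must be in (0, 1]")
        if self.noise_sd < 0 or self.crystalloid_escape_rate < 0:
            raise ValueError("noise_sd and crystalloid_escape_rate must be >= 0")

    @property
    def weight_kg(self) -> float:
        return self.weight / 1000.0

    @property
    def total_blood_volume(self) -> float:
        """Euvolemic blood volume, mL."""
        return self.weight_kg * self.blood_volume_per_kg


@dataclass
class HemodynamicState:
    """Instantaneous plant state.

    ``plasma_reference`` is the plasma volume toward which the leak
    relaxes: it falls with hemorrhage and rises by the retention
    fraction of every infused mL, so at steady state exactly
    ``crystalloid_retention_fraction`` of infused crystalloid stays
    intravascular.
    """

    t: float = 0.0  # s
    plasma_volume: float = 0.0  # mL
    red_cell_mass: float = 0.0  # mL
    plasma_reference: float = 0.0  # mL
    interstitial_excess: float = 0.0  # mL
    shed_blood: float = 0.0  # mL available for re-infusion
    ne_effect_site: float = 0.0  # ug/kg/min equivalent
    lactate: float = 1.5  # mmol/L
    noise_state: float = 0.0  # mmHg, AR(1) carry
    exhausted: bool = False  # volumes ran out; run no longer physiologic

    @property
    def blood_volume(self) -> float:
        return self.plasma_volume + self.red_cell_mass

    @property
    def hct(self) -> float:
        return self.red_cell_mass / self.blood_volume


@dataclass(frozen=True)
class InfusionCommand:
    """Commanded pump rates at a timestamp."""

    t: float  # s
    fluid_rate: float  # mL/kg/min
    ne_rate: float = 0.0  # ug/kg/min

    def __post_init__(self) -> None:
        if not (math.isfinite(self.fluid_rate) and math.isfinite(self.ne_rate)):
            raise ValueError("infusion rates must be finite")
        if self.fluid_rate < 0 or self.ne_rate < 0:
            raise ValueError("infusion rates must be >= 0")


def initial_state(params: PlantParams) -> HemodynamicState:
    """Euvolemic resting state for ``params``."""
    total = params.total_blood_volume
    plasma = total * (1.0 - params.baseline_hct)
    return HemodynamicState(
        t=0.0,
        plasma_volume=plasma,
        red_cell_mass=total * params.baseline_hct,
        plasma_reference=plasma,
        interstitial_excess=0.0,
        shed_blood=0.0,
        ne_effect_site=0.0,
        lactate=params.lactate_baseline,
        noise_state=0.0,
    )


def _volume_curve(v_frac: float, params: PlantParams) -> float:
    """Normalised logistic pressure-volume curve S(v), with S(1) = 1."""
    k = params.map_curve_steepness
    v50 = params.map_curve_midpoint
    num = 1.0 / (1.0 + math.exp(-k * (v_frac - v50)))
    den = 1.0 / (1.0 + math.exp(-k * (1.0 - v50)))
    return num / den


def _ne_multiplier(c: float, params: PlantParams) -> float:
    if c <= 0.0:
        return 1.0
    ch = c ** params.ne_hill
    return 1.0 + params.ne_emax * ch / (ch + params.ne_ec50 ** params.ne_hill)


def pressure_from_state(
    state: HemodynamicState, params: PlantParams
) -> tuple[float, float]:
    """Noise-free (MAP, SAP) in mmHg for the current state.

    MAP = baseline_map * S(v) * NE-multiplier, with S the normalised
    logistic volume curve; SAP adds a pulse-pressure term that is
    attenuated with hypovolemia (S raised to the configured exponent).
    """
    bv = state.blood_volume
    if not (math.isfinite(bv) and math.isfinite(state.ne_effect_site)):
        raise ValueError("non-finite plant state: integration has diverged")
    v_frac = bv / params.total_blood_volume
    s = _volume_curve(v_frac, params)
    map_ = params.baseline_map * s * _ne_multiplier(state.ne_effect_site, params)
    pulse = params.pulse_pressure_baseline * s ** params.pulse_pressure_hypovolemia_factor
    return map_, map_ + pulse


def step(
    state: HemodynamicState,
    cmd: InfusionCommand,
    hemorrhage_rate: float,
    dt: float,
    params: PlantParams,
    rng: np.random.Generator | None = None,
) -> HemodynamicState:
    """Advance the plant by one explicit-Euler step of ``dt`` seconds.

    ``hemorrhage_rate`` is whole-blood withdrawal in mL/min; negative
    values re-infuse shed blood (limited by the shed reservoir, returned
    at baseline hematocrit). Crystalloid enters plasma at
    ``cmd.fluid_rate`` (mL/kg/min); norepinephrine relaxes toward
    ``cmd.ne_rate`` with the effect-site time constant.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    w = params.weight_kg
    dt_min = dt / 60.0

    plasma = state.plasma_volume
    rcm = state.red_cell_mass
    ref = state.plasma_reference
    inter = state.interstitial_excess
    shed = state.shed_blood
    exhausted = state.exhausted

    # crystalloid in, first-order escape toward the retention equilibrium
    infused = cmd.fluid_rate * w * dt_min
    plasma += infused
    ref += params.crystalloid_retention_fraction * infused
    leak = params.crystalloid_escape_rate * max(0.0, plasma - ref) * dt_min
    plasma -= leak
    inter += leak

    # whole-blood exchange
    if hemorrhage_rate > 0.0:
        dv = hemorrhage_rate * dt_min
        bv = plasma + rcm
        dv = min(dv, bv)  # cannot withdraw more than exists
        hct = rcm / bv if bv > 0 else 0.0
        plasma -= dv * (1.0 - hct)
        ref -= dv * (1.0 - hct)
        rcm -= dv * hct
        shed += dv
    elif hemorrhage_rate < 0.0:
        dv = min(-hemorrhage_rate * dt_min, shed)
        plasma += dv * (1.0 - params.baseline_hct)
        ref += dv * (1.0 - params.baseline_hct)
        rcm += dv * params.baseline_hct
        shed -= dv

    if plasma < 0.0 or rcm < 0.0:
        plasma = max(plasma, 0.0)
        rcm = max(rcm, 0.0)
        exhausted = True

    # norepinephrine effect site
    ne = state.ne_effect_site + (cmd.ne_rate - state.ne_effect_site) * dt / params.ne_effect_tau

    # lactate kinetics against the post-update MAP
    interim = HemodynamicState(
        t=state.t, plasma_volume=plasma, red_cell_mass=rcm,
        plasma_reference=ref, interstitial_excess=inter, shed_blood=shed,
        ne_effect_site=ne, lactate=state.lactate,
        noise_state=state.noise_state, exhausted=exhausted,
    )
    map_, _ = pressure_from_state(interim, params)
    hypoperf = max(0.0, (params.map_critical - map_) / params.map_critical)
    dlac = (
        params.lactate_production_gain * hypoperf
        - params.lactate_clearance_rate * (state.lactate - params.lactate_baseline)
    ) * dt_min
    interim.lactate = max(0.0, state.lactate + dlac)

    # AR(1) measurement noise carry
    if params.noise_sd > 0.0 and rng is not None:
        phi = params.noise_ar1
        innov_sd = params.noise_sd * math.sqrt(1.0 - phi * phi)
        interim.noise_state = phi * state.noise_state + innov_sd * rng.standard_normal()
    else:
        interim.noise_state = params.noise_ar1 * state.noise_state

    interim.t = state.t + dt
    return interim


def measured_sap(state: HemodynamicState, params: PlantParams) -> float:
    """Noisy systolic pressure as seen by the controllers (>= 0)."""
    _, sap = pressure_from_state(state, params)
    return max(0.0, sap + state.noise_state)


def clamp_shock_controller(
    state: HemodynamicState,
    params: PlantParams,
    band_low: float = 30.0,
    band_high: float = 35.0,
    gain: float = 0.5,
    max_rate: float = 3.0,
) -> float:
    """Pressure-clamp bleed/re-infuse rate (mL/min) for the shock phase.

    Mimics the fixed-pressure preparation: withdraw blood while true
    MAP is above the band, re-infuse shed blood (if any remains) while
    below it, do nothing inside [band_low, band_high]. ``gain`` is in
    mL/min per mmHg per kg; the rate is capped at ``max_rate`` mL/min.
    """
    map_, _ = pressure_from_state(state, params)
    g = gain * params.weight_kg
    if map_ > band_high:
        return min(g * (map_ - band_high), max_rate)
    if map_ < band_low and state.shed_blood > 0.0:
        return -min(g * (band_low - map_), max_rate)
    return 0.0


# ---------------------------------------------------------------------------
# population sampling

#: fields that receive lognormal multiplicative between-animal variability,
#: with default log-scale sigmas sized to the cohort's printed IQRs
DEFAULT_DISPERSIONS: dict[str, float] = {
    "weight": 0.10,
    "baseline_map": 0.06,
    "map_curve_midpoint": 0.02,
    "map_curve_steepness": 0.10,
    "pulse_pressure_baseline": 0.10,
    "crystalloid_escape_rate": 0.15,
    "ne_ec50": 0.15,
    "lactate_production_gain": 0.20,
}


@dataclass(frozen=True)
class PopulationSpec:
    """Population medians plus lognormal dispersions for cohort sampling."""

    medians: PlantParams = field(default_factory=PlantParams)
    dispersions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISPERSIONS)
    )

    def __post_init__(self) -> None:
        names = {f.name for f in fields(PlantParams)}
        for key, sigma in self.dispersions.items():
            if key not in names:
                raise ValueError(f"unknown PlantParams field in dispersions: {key!r}")
            if sigma < 0:
                raise ValueError(f"dispersion for {key!r} must be >= 0")


def sample_rat(population: PopulationSpec, rng: np.random.Generator) -> PlantParams:
    """Draw one virtual rat's parameters.

    Multiplicative lognormal variability: each listed field is the
    configured median times exp(sigma * z). The population median of
    every field equals the configured median; zero dispersion returns
    it exactly. The rng stream is always consumed in a fixed field
    order so identical seeds give identical draws.
    """
    updates: dict[str, float] = {}
    for name in sorted(population.dispersions):
        sigma = population.dispersions[name]
        z = rng.standard_normal()
        if sigma > 0:
            updates[name] = getattr(population.medians, name) * math.exp(sigma * z)
    return replace(population.medians, **updates) if updates else population.medians
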