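# Methods

`resusim` is an in-silico testbed for arterial-pressure-guided closed-loop
resuscitation of haemorrhagic shock. It couples a minimal virtual-rat
hemodynamic plant to five decision policies — two standardized manual
protocols and three closed-loop controllers — and scores each
resuscitation with Varvel-style performance-error statistics. Everything
runs on the 0.2 s sampling grid of the real acquisition chain.

## The virtual-rat plant

The plant is a deliberately minimal lumped model, built so that every
printed physiologic anchor of the in-vivo preparation it emulates is
reachable: ~348 g animals, baseline MAP ~89 mmHg, a ~25 mL/kg
exsanguination bringing MAP to 30–35 mmHg, lactate peaking near
5.6 mmol/L after an hour of pressure-clamp shock, and crystalloid
haemodilution of hematocrit.

**Pressure–volume curve.** Mean arterial pressure is

    MAP = MAP₀ · S(v) · (1 + E_max · cʰ / (cʰ + EC₅₀ʰ))

where `v` is blood volume as a fraction of the euvolemic total,
`S(v) = σ(k(v − v₅₀)) / σ(k(1 − v₅₀))` is a logistic normalised so that
`S(1) = 1` (full volume maps exactly to baseline MAP), and the bracketed
term is a Hill dose–response in the norepinephrine effect-site
concentration `c`. Defaults `v₅₀ = 0.65`, `k = 18` were solved
analytically against two anchors: total blood volume 64 mL/kg (standard
rodent convention) and MAP = 30 mmHg after withdrawal of 24.8 mL/kg.
Systolic pressure adds a pulse-pressure term `PP₀ · S(v)^γ`
(default PP₀ = 25 mmHg, γ = 1) that shrinks with hypovolemia; the
controllers act on SAP, as in the experimental setup.

**Fluid compartments.** Infused crystalloid enters plasma and leaks
first-order (default 0.10 min⁻¹) toward a moving reference volume that
rises by the retention fraction (default 0.25) of every infused mL — so
at steady state exactly 25 % of infused crystalloid stays intravascular,
which makes fluid-only arms need ~20–35 mL/kg to hold the target, the
printed order of magnitude. Red-cell mass changes only with whole-blood
withdrawal or re-infusion: hemorrhage at the current hematocrit leaves
hct unchanged, crystalloid dilutes it.

**Norepinephrine.** First-order effect site (τ = 30 s) feeding the Hill
multiplier (E_max = 0.6, EC₅₀ = 0.5 µg/kg/min, h = 1.5), sized so that
doses in the experimentally used 0.1–2 µg/kg/min range produce
meaningful but saturating pressure support.

**Lactate.** `dL/dt = g · max(0, (MAP_c − MAP)/MAP_c) − k_cl (L − L₀)`
with MAP_c = 60 mmHg, clearance 0.02 min⁻¹, baseline 1.5 mmol/L. The
production gain (0.23 mmol/L/min) was calibrated numerically so the
65-min shock phase peaks near 5.6 mmol/L.

**Measurement noise.** AR(1) Gaussian on the 0.2 s grid (stationary SD
2 mmHg, coefficient 0.8, ≈1 s correlation time), applied to measured SAP
only. The real waveform noise amplitude is unreported; this is a free
parameter.

**Integration.** Explicit Euler at 0.2 s. All model time constants are
≥ 10 s, so the scheme is stable and the discretization error is far
below the measurement noise. With zero noise the entire trajectory is
bit-reproducible from (parameters, seed, command sequence).

**Population sampling.** Per-rat parameters are drawn with
multiplicative lognormal variability around the configured medians
(weight σ=0.10, baseline MAP σ=0.06, curve midpoint σ=0.02, curve
steepness σ=0.10, pulse pressure σ=0.10, escape rate σ=0.15, NE EC₅₀
σ=0.15, lactate gain σ=0.20 on the log scale), sized so cohort IQRs are
comparable to the printed ones. Medians are preserved exactly by
construction (the median of a lognormal is its scale).

## Shock induction

A 5-min exsanguination ramp withdraws blood proportionally to the
distance of true MAP from 30 mmHg (capped at 3 mL/min), then a 60-min
fixed-pressure clamp withdraws or re-infuses shed blood whenever true
MAP leaves [30, 35] mmHg. Shed blood is credited to a reservoir and
returned at baseline hematocrit. On default parameters the clamp holds
MAP in band essentially 100 % of the time and the median cohort shed
volume is ~24.9 mL/kg.

## The five arms

All fluid channels pass through the shared safety clamp — at most
4 mL/kg/min while SAP < 70 mmHg, 2.5 mL/kg/min at or above 70 (boundary
inclusive) — applied against the instantaneous measured SAP at command
time, so the limits hold even between a window-based controller's
updates. The pressure target is SAP 85 mmHg, band 80–90.

* **CL-PI** — proportional–integral control of fluid rate on the
  continuous SAP stream (kp = 0.08 mL/kg/min/mmHg, ki = 0.002
  mL/kg/min/mmHg·s). The original gains are not public; these defaults
  were chosen by simulation to satisfy the shipped convergence check
  (settle within ±2 mmHg of 85 on the noiseless default plant). Anti-
  windup by conditional integration: the integral freezes whenever
  integrating would push the raw command further into the clamp.
* **CL-FL** — fluid rate from a fuzzy map of the error of the
  one-minute mean SAP. Six triangular/shoulder sets on the error
  (feet at −10, −5, 0, 5, 10, 20 mmHg) with singleton outputs
  (0/0/0/0.8/1.6/4.0 mL/kg/min) and weighted-mean defuzzification; the
  original membership functions are not public, so this is a redesign,
  fully exposed in config. Output is monotone in the error by
  construction (tested).
* **CL-FNE** — PI fluid channel plus a fuzzy norepinephrine channel
  (singletons 0/0/0.2/0.5/1.0/2.0 µg/kg/min on the same error sets,
  updated on the 1-min mean) coupled by a fluid/NE ratio rule: the NE
  command can never exceed cumulative fluid volume divided by the ratio
  (default 10 mL/kg per µg/kg/min), so volume always leads and the
  pressor cannot run ahead of fluid. Two further conditional rules
  mimic clinical behaviour: the NE target is only refreshed while the
  window-mean SAP is below 88 mmHg, and decays by half per window while
  the mean sits above the band. A single coupled loop, not two parallel
  ones — two independent loops oscillate against each other.
* **M-F** — the standardized manual fluid protocol: fixed 2 mL/kg/min,
  started and stopped by the clinician targeting 85 mmHg. Modelled with
  a 2 s decision cadence and a ±2 mmHg hysteresis (start < 83, stop
  ≥ 87); the real clinician's thresholds are unreported.
* **M-FNE** — alternating escalation: up to three 10 mL/kg boluses at
  2 mL/kg/min, each started/resumed below 83 mmHg and stopped at
  87 mmHg or on completing its volume; norepinephrine starts at
  0.1 µg/kg/min and doubles every 3 min while the target is unreached
  (0.1→0.2→0.4→0.8→1.6; the exact step sizes are unreported, the
  doubling schedule is consistent with the reported mean dose), capped
  at 3 µg/kg/min. Above 88 mmHg the rate steps down by the arithmetic
  mean of the two most recent increments, at the same cadence. Strict
  alternation: a completed bolus must be followed by an NE change
  before the next bolus (configurable).

## Performance metrics

The resuscitation hour is split at the first sample from which SAP
stays ≥ 80 mmHg for 2 s (10 consecutive samples — the sustain rule
rejects single-sample noise spikes; its length is a design choice).
Rising time is that sample's offset. On the stabilization segment only:
PE_i = 100·(SAP_i − 85)/85; MDPE = median(PE); MDAPE = median(|PE|);
wobble = median(|PE_i − MDPE|); band occupancy by sample counting with
inclusive edges (80 and 90 count as in target); global score =
(MDAPE + wobble)/(% time in target) × 100, undefined when the band is
never occupied. The PE reference (85 mmHg) is the titration target and
band midpoint. Even-length medians are the mean of the two central
order statistics. Adjustment counts are rate-change counts of the
command sequence; for the manual arms they equal the policies' own
intervention counters.

Composing the printed combined-manual group medians (MDAPE 4.5, wobble
3.3, 60.1 % in target) under this global-score formula gives 12.98 ≈ 13
at the table's precision, and the fluid-manual medians give 8.46 ≈ 8 —
group medians compose only approximately across animals, so agreement
at rounding precision is the relevant check.

## Cohorts and reproducibility

Cohorts sample n rats per arm; child seeds derive from
`SeedSequence([master_seed, arm_index, rat_index, stream])`, so any
member re-runs standalone bit-identically. Summaries are median (IQR)
with numpy's linear-interpolation quartile convention (recorded in the
output metadata). Runs whose blood volume is exhausted are flagged as
deaths and excluded from performance summaries. Statistical inference
(rank tests etc.) is deliberately out of scope; only median/IQR
summaries are produced.

Default problem sizes — 50-rat calibration cohorts and 10 rats per arm
for the five-arm comparison — match the study scale and keep a full
five-arm cohort under half a minute on one core.

## What the synthetic cohort does and does not show

The plant reproduces the anchors it was calibrated to (baseline MAP,
shed volume, peak lactate, dilution) and the qualitative closed-loop
physiology: norepinephrine co-administration reduces fluid need and
haemodilution, and the combined closed-loop arm rises faster than the
alternating manual protocol. It does not model coagulopathy,
re-bleeding, acid–base chemistry beyond lactate, transcapillary refill
during shock (hematocrit stays at baseline through hemorrhage), or
inter-animal variability in drug responsiveness beyond lognormal
parameter scatter. Passing tests therefore validate the algorithms and
the metric pipeline, not animal-level predictive fidelity; absolute
performance numbers (e.g. % time in target) are better on the synthetic
plant than in vivo because the plant is smoother than a real rat.

## Numerical and degenerate-input conventions

Non-finite measured SAP makes the PI controller hold its last rate
(sensor-fault contract); a fuzzy error outside every membership support
returns zero rate; an empty PE series or zero time-in-target yields
absent metrics rather than NaNs; volumes are clamped at zero and the
run flagged on exhaustion; trace files are validated for header,
uniform grid and finiteness with row-level error messages. Pressures
are stored to 0.01 mmHg and rates to 0.001, enough to re-derive every
metric exactly from file.
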