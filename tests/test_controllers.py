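"""Decision policies: clamps, PI, fuzzy, combined, manual protocols."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resusim.controllers import (
    DEFAULT_NE_SETS,
    ClampSchedule,
    CombinedConfig,
    CombinedController,
    FuzzyConfig,
    FuzzyController,
    FuzzySet,
    ManualFConfig,
    ManualFluidPolicy,
    ManualFNEConfig,
    ManualFNEPolicy,
    PIConfig,
    PIController,
    TargetSpec,
    clamp_rate,
    count_adjustments,
    fuzzy_eval,
)
from resusim.plant import InfusionCommand

SCHEDULE = ClampSchedule()


class TestClampRate:
    @pytest.mark.parametrize(
        "raw,sap,expected",
        [
            (10.0, 65.0, 4.0),  # deep hypotension cap
            (10.0, 70.0, 2.5),  # boundary is inclusive on the >= side
            (10.0, 85.0, 2.5),
            (-0.5, 85.0, 0.0),  # rates are nonnegative
            (1.0, 65.0, 1.0),  # clamp not binding
        ],
    )
    def test_examples(self, raw, sap, expected):
        assert clamp_rate(raw, sap, SCHEDULE) == expected

    def test_nonfinite_raw_rejected(self):
        with pytest.raises(ValueError):
            clamp_rate(math.nan, 80.0, SCHEDULE)

    @settings(max_examples=200, deadline=None)
    @given(raw=st.floats(-10, 50), sap=st.floats(0, 150))
    def test_limits_always_respected(self, raw, sap):
        out = clamp_rate(raw, sap, SCHEDULE)
        assert 0.0 <= out <= 4.0
        if sap >= 70.0:
            assert out <= 2.5


class TestPIController:
    def test_zero_error_zero_rate(self):
        pi = PIController(PIConfig())
        assert pi.update(85.0) == 0.0

    def test_single_step_hand_arithmetic(self):
        # e = 10: raw = 0.08*10 + 0.002*(10*0.2) = 0.804, clamp not binding
        pi = PIController(PIConfig(kp=0.08, ki=0.002, dt=0.2))
        assert pi.update(75.0) == pytest.approx(0.804)

    def test_deep_hypotension_saturates_at_four(self):
        pi = PIController(PIConfig(kp=1.0, ki=0.1))
        assert pi.update(50.0) == 4.0

    def test_sensor_fault_holds_last_rate(self):
        pi = PIController(PIConfig())
        r = pi.update(75.0)
        assert pi.update(math.nan) == r
        assert pi.update(math.inf) == r

    def test_anti_windup_freezes_integral_at_saturation(self):
        pi = PIController(PIConfig(kp=1.0, ki=0.1))
        for _ in range(100):
            pi.update(40.0)
        frozen = PIController(PIConfig(kp=1.0, ki=0.1))
        frozen.update(40.0)
        # integral must not accumulate while the output is clamped
        assert pi.integral == pytest.approx(frozen.integral)

    def test_windup_without_anti_windup(self):
        pi = PIController(PIConfig(kp=1.0, ki=0.1, anti_windup=False))
        for _ in range(100):
            pi.update(40.0)
        assert pi.integral == pytest.approx(45.0 * 0.2 * 100)


class TestFuzzy:
    def test_zero_error_zero_rate(self):
        assert fuzzy_eval(85.0, FuzzyConfig()) == 0.0

    def test_hand_centroid(self):
        # e = 7.5: mu_PS = mu_PM = 0.5 -> (0.5*0.8 + 0.5*1.6) / 1 = 1.2
        assert fuzzy_eval(77.5, FuzzyConfig()) == pytest.approx(1.2)

    def test_out_of_universe_input_returns_zero(self):
        cfg = FuzzyConfig(
            error_sets=(FuzzySet("PS", 0.0, 5.0, 10.0),),
            output_singletons={"PS": 0.8},
        )
        assert fuzzy_eval(120.0, cfg) == 0.0  # e = -35, no support

    def test_monotone_nonincreasing_in_mean_sap(self):
        cfg = FuzzyConfig()
        saps = np.linspace(30.0, 120.0, 181)
        outs = [fuzzy_eval(s, cfg) for s in saps]
        assert all(b <= a + 1e-12 for a, b in zip(outs, outs[1:]))

    def test_rate_changes_only_at_window_boundaries(self):
        ctl = FuzzyController(FuzzyConfig())
        raws = []
        for _ in range(299):
            ctl.update(70.0)
            raws.append(ctl.current_raw)
        assert set(raws) == {0.0}  # no update before the window completes
        ctl.update(70.0)  # 300th sample closes the window
        assert ctl.current_raw == pytest.approx(fuzzy_eval(70.0, FuzzyConfig()))

    def test_window_mean_is_arithmetic_mean(self, rng):
        cfg = FuzzyConfig()
        ctl = FuzzyController(cfg)
        samples = rng.uniform(50, 100, 300)
        for s in samples:
            ctl.update(s)
        assert ctl.current_raw == pytest.approx(
            fuzzy_eval(float(np.mean(samples)), cfg)
        )

    def test_clamp_follows_instantaneous_sap(self):
        ctl = FuzzyController(FuzzyConfig())
        for _ in range(300):
            ctl.update(40.0)  # raw -> 4.0 at deep hypotension
        assert ctl.current_raw == pytest.approx(4.0)
        # SAP recovers past 70 mid-window: the command must drop to 2.5
        assert ctl.update(75.0) == 2.5
        assert ctl.update(65.0) == 4.0


class TestCombined:
    def test_ne_locked_out_before_any_fluid(self):
        ctl = CombinedController(CombinedConfig())
        cmd = ctl.update(40.0, 0.0)
        assert cmd.ne_rate == 0.0  # ceiling = 0 / ratio: fluid leads

    def test_ratio_ceiling_arithmetic(self):
        ctl = CombinedController(CombinedConfig(ratio=10.0))
        ctl.cumulative_fluid = 5.0
        ctl.ne_held = 2.0
        cmd = ctl.update(85.0, 0.0)
        assert cmd.ne_rate == pytest.approx(0.5, rel=1e-3)

    def test_ratio_invariant_along_closed_loop_stream(self, rng):
        cfg = CombinedConfig()
        ctl = CombinedController(cfg)
        sap = 40.0
        for i in range(1200):  # 4 windows
            cmd = ctl.update(sap, i * 0.2)
            assert cmd.ne_rate * cfg.ratio <= ctl.cumulative_fluid + 1e-9
            assert cmd.fluid_rate >= 0.0 and cmd.ne_rate >= 0.0
            sap = min(95.0, sap + rng.uniform(0, 0.05))

    def test_ne_decays_above_band(self):
        cfg = CombinedConfig()
        ctl = CombinedController(cfg)
        ctl.cumulative_fluid = 50.0
        ctl.ne_held = 1.0
        for _ in range(300):
            ctl.update(95.0, 0.0)  # window mean above band_high
        assert ctl.ne_held == pytest.approx(1.0 * cfg.ne_decay_factor)


class TestManualFluid:
    def test_starts_below_threshold_at_fixed_rate(self):
        pol = ManualFluidPolicy(ManualFConfig())
        assert pol.update(78.0) == 2.0

    def test_hysteresis_stop(self):
        pol = ManualFluidPolicy(
            ManualFConfig(start_below=83.0, stop_at_or_above=85.0), dt=2.0
        )
        assert pol.update(78.0) == 2.0
        assert pol.update(86.0) == 0.0

    def test_one_oscillation_counts_two_interventions(self):
        pol = ManualFluidPolicy(ManualFConfig(), dt=2.0)
        for sap in (80.0, 80.0, 90.0, 90.0):
            pol.update(sap)
        assert pol.interventions == 2

    def test_decisions_only_at_ticks(self):
        pol = ManualFluidPolicy(ManualFConfig(decision_tick=2.0), dt=0.2)
        pol.update(70.0)  # tick: on
        assert pol.update(95.0) == 2.0  # between ticks: unchanged
        for _ in range(8):
            pol.update(95.0)
        assert pol.update(95.0) == 0.0  # next tick: off


class TestManualFNE:
    def test_first_ne_action_is_start_dose(self):
        pol = ManualFNEPolicy(ManualFNEConfig())
        cmd = pol.update(40.0, 0.0)
        assert cmd.ne_rate == pytest.approx(0.1)
        assert cmd.fluid_rate == 2.0  # first bolus starts immediately

    def test_escalation_doubles_through_schedule(self):
        cfg = ManualFNEConfig()
        pol = ManualFNEPolicy(cfg, dt=2.0)
        rates = []
        for i in range(int(4 * cfg.escalation_interval / 2.0) + 1):
            rates.append(pol.update(40.0, i * 2.0).ne_rate)
        assert set(np.round(sorted(set(rates)), 3)) == {0.1, 0.2, 0.4, 0.8, 1.6}

    def test_decrease_is_mean_of_last_two_steps(self):
        pol = ManualFNEPolicy(ManualFNEConfig())
        pol.ne = 1.5
        pol._ne_started = True
        pol._increments = [0.4, 0.8]
        pol._last_ne_change = -1e9
        cmd = pol.update(92.0, 0.0)
        assert cmd.ne_rate == pytest.approx(1.5 - 0.6)

    def test_total_bolus_volume_capped(self):
        cfg = ManualFNEConfig()
        pol = ManualFNEPolicy(cfg, dt=0.2)
        for i in range(round(3600 / 0.2)):  # a full hour, persistently low SAP
            cmd = pol.update(40.0, i * 0.2)
        assert pol.total_bolus_volume <= 30.0 + 1e-6
        assert pol.boluses_given <= 3
        assert cmd.fluid_rate == 0.0  # budget exhausted

    def test_bolus_stopped_when_target_reached(self):
        pol = ManualFNEPolicy(ManualFNEConfig(), dt=2.0)
        assert pol.update(40.0, 0.0).fluid_rate == 2.0
        assert pol.update(90.0, 2.0).fluid_rate == 0.0  # physician stops pump
        assert pol.bolus_delivered < 10.0

    def test_ne_piecewise_constant_between_ticks(self):
        pol = ManualFNEPolicy(ManualFNEConfig(decision_tick=2.0), dt=0.2)
        rates = {pol.update(40.0, i * 0.2).ne_rate for i in range(9)}
        assert len(rates) == 1


class TestCountAdjustments:
    def _cmds(self, rates):
        return [InfusionCommand(i * 0.2, r) for i, r in enumerate(rates)]

    def test_transition_count_example(self):
        assert count_adjustments(self._cmds([0, 2, 2, 0, 2])) == 3

    def test_constant_sequence(self):
        assert count_adjustments(self._cmds([1.0] * 10)) == 0

    def test_every_step_changes(self):
        assert count_adjustments(self._cmds(range(50))) == 49

    def test_empty_sequence(self):
        assert count_adjustments([]) == 0

    def test_ne_channel_counted(self):
        cmds = [
            InfusionCommand(0, 1.0, 0.0),
            InfusionCommand(1, 1.0, 0.1),
            InfusionCommand(2, 1.0, 0.1),
        ]
        assert count_adjustments(cmds, mode="manual") == 1

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            count_adjustments([], mode="robot")


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_no_controller_violates_rate_limits(seed):
    """Fluid limits hold for every policy over random SAP streams."""
    rng = np.random.default_rng(seed)
    saps = rng.uniform(20.0, 130.0, 400)
    policies = {
        "pi": PIController(PIConfig(kp=1.0, ki=0.05)),
        "fuzzy": FuzzyController(FuzzyConfig()),
        "manual": ManualFluidPolicy(ManualFConfig()),
        "fne": ManualFNEPolicy(ManualFNEConfig()),
        "combined": CombinedController(CombinedConfig()),
    }
    for i, sap in enumerate(saps):
        t = i * 0.2
        rates = [
            policies["pi"].update(sap),
            policies["fuzzy"].update(sap),
            policies["manual"].update(sap),
            policies["fne"].update(sap, t).fluid_rate,
            policies["combined"].update(sap, t).fluid_rate,
        ]
        for r in rates:
            assert 0.0 <= r <= 4.0
            if sap >= 70.0:
                assert r <= 2.5
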