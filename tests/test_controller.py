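"""Controller state machine: dosing rules, mode transitions, invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasoloop import (
    ControllerConfig,
    ControllerState,
    InvalidInputError,
    Mode,
    initial_bolus,
    quantize_rate,
    run_controller,
    step,
)
from vasoloop.controller import RatePolicy

from conftest import reading


class TestInitialBolus:
    @pytest.mark.parametrize("weight, expected", [
        (70.0, 0.1),    # 0.14 mg/kg dose capped at the 0.1 mg maximum
        (50.0, 0.1),    # exactly at the cap
        (40.0, 0.08),   # below the cap: 0.002 * 40
    ])
    def test_weight_based_dose_with_cap(self, weight, expected, config):
        assert initial_bolus(weight, config) == pytest.approx(expected)

    @pytest.mark.parametrize("weight", [0.0, -5.0, math.nan])
    def test_rejects_nonpositive_weight(self, weight, config):
        with pytest.raises(InvalidInputError):
            initial_bolus(weight, config)


class TestQuantizeRate:
    @pytest.mark.parametrize("rate, expected", [
        (0.7031, 0.705),  # nearest multiple of 0.005 mg/h (0.1 mL/h pump step)
        (0.0, 0.0),
        (5.0, 2.0),       # clipped at the 2 mg/h cap
    ])
    def test_pump_resolution_and_cap(self, rate, expected, config):
        assert quantize_rate(rate, config) == pytest.approx(expected)

    def test_rejects_negative_rate(self, config):
        with pytest.raises(InvalidInputError):
            quantize_rate(-0.1, config)


class TestStepTransitions:
    def test_entry_bolus_on_hypotension(self, config):
        state, action = step(ControllerState(), reading(0, 60), 70.0, config)
        assert state.mode is Mode.VASOPRESSOR
        assert state.boluses_given == 1
        assert action.bolus == pytest.approx(0.1)
        assert action.rate_setpoint == 0.0
        assert action.note == "entry-bolus"

    def test_idle_above_threshold(self, config):
        state, action = step(ControllerState(), reading(0, 80), 70.0, config)
        assert state == ControllerState()
        assert action.bolus == 0.0 and action.note == "none"

    def test_second_bolus_is_half_dose_and_starts_infusion(self, config):
        st1 = ControllerState(mode=Mode.VASOPRESSOR, boluses_given=1)
        state, action = step(st1, reading(2.5, 58), 70.0, config)
        assert action.bolus == pytest.approx(0.05)
        assert state.boluses_given == 2
        assert state.infusion_rate > 0
        assert action.rate_setpoint == state.infusion_rate

    def test_suspension_above_upper_threshold(self, config):
        infusing = ControllerState(mode=Mode.VASOPRESSOR, boluses_given=2,
                                   infusion_rate=0.7)
        state, action = step(infusing, reading(10.0, 90), 70.0, config)
        assert state.infusion_rate == 0.0
        assert state.suspended_since == 10.0
        assert state.pre_suspension_rate == pytest.approx(0.7)
        assert action.note == "suspend"

    def test_boundary_85_maintains_not_suspends(self, config):
        infusing = ControllerState(mode=Mode.VASOPRESSOR, boluses_given=2,
                                   infusion_rate=0.7)
        state, action = step(infusing, reading(10.0, 85), 70.0, config)
        assert state.infusion_rate > 0.0

    def test_boundary_65_is_not_hypotensive(self, config):
        state, action = step(ControllerState(), reading(0, 65), 70.0, config)
        assert state.mode is Mode.NORMAL and action.bolus == 0.0

    def test_resume_restores_remembered_rate(self, config):
        suspended = ControllerState(mode=Mode.VASOPRESSOR, boluses_given=2,
                                    infusion_rate=0.0, pre_suspension_rate=0.9,
                                    suspended_since=10.0)
        state, action = step(suspended, reading(12.5, 75), 70.0, config)
        assert action.note == "resume"
        assert state.infusion_rate == pytest.approx(0.9)
        assert state.suspended_since is None

    def test_exit_after_long_suspension(self, config):
        suspended = ControllerState(mode=Mode.VASOPRESSOR, boluses_given=2,
                                    infusion_rate=0.0, pre_suspension_rate=0.9,
                                    suspended_since=0.0)
        state, action = step(suspended, reading(17.5, 75), 70.0, config)
        assert state == ControllerState()
        assert action.note == "exit"

    def test_exactly_15_min_suspension_does_not_exit(self, config):
        suspended = ControllerState(mode=Mode.VASOPRESSOR, boluses_given=2,
                                    infusion_rate=0.0, pre_suspension_rate=0.9,
                                    suspended_since=0.0)
        state, _ = step(suspended, reading(15.0, 75), 70.0, config)
        assert state.mode is Mode.VASOPRESSOR

    def test_invalid_reading_freezes_any_state(self, config):
        for st0 in (ControllerState(),
                    ControllerState(mode=Mode.VASOPRESSOR, boluses_given=2,
                                    infusion_rate=0.5)):
            state, action = step(st0, reading(5.0, 0, valid=False), 70.0, config)
            assert state == st0
            assert action.note == "frozen"
            assert action.bolus == 0.0

    def test_step_up_under_persistent_hypotension(self, config):
        infusing = ControllerState(mode=Mode.VASOPRESSOR, boluses_given=2,
                                   infusion_rate=0.8)
        state, action = step(infusing, reading(10.0, 60), 70.0, config)
        assert state.infusion_rate == pytest.approx(1.0)  # 0.8 * 1.25
        assert action.note == "step-up"

    def test_step_down_in_upper_band_with_floor(self, config):
        infusing = ControllerState(mode=Mode.VASOPRESSOR, boluses_given=2,
                                   infusion_rate=0.5)
        state, action = step(infusing, reading(10.0, 80), 70.0, config)
        assert action.note == "step-down"
        assert state.infusion_rate == pytest.approx(0.4)  # 0.5 * 0.8
        # floor: repeated step-downs never go below 0.2 * r0 (r0 = 0.7 @ 70 kg)
        st_now = state
        for i in range(20):
            st_now, _ = step(st_now, reading(12.5 + 2.5 * i, 80), 70.0, config)
        assert st_now.infusion_rate == pytest.approx(0.14, abs=0.005)

    def test_step_is_pure(self, config):
        st0 = ControllerState(mode=Mode.VASOPRESSOR, boluses_given=2,
                              infusion_rate=0.8)
        r = reading(10.0, 60)
        assert step(st0, r, 70.0, config) == step(st0, r, 70.0, config)


class TestRunController:
    def test_no_drug_when_never_hypotensive(self, config):
        readings = [reading(2.5 * i, 70 + (i % 5)) for i in range(50)]
        actions, final = run_controller(readings, 70.0, config)
        assert sum(a.bolus for a in actions) == 0.0
        assert all(a.rate_setpoint == 0.0 for a in actions)
        assert final.mode is Mode.NORMAL

    def test_canonical_episode_sequence(self, config):
        mbps = [70, 60, 58, 70, 90, 90, 70]
        actions, final = run_controller(
            [reading(2.5 * i, m) for i, m in enumerate(mbps)], 70.0, config)
        assert [a.note for a in actions] == [
            "none", "entry-bolus", "second-bolus", "hold", "suspend",
            "suspend", "resume"]
        assert [round(a.bolus, 3) for a in actions[:3]] == [0.0, 0.1, 0.05]

    def test_rejects_unordered_times(self, config):
        readings = [reading(5.0, 70), reading(2.5, 70)]
        with pytest.raises(InvalidInputError):
            run_controller(readings, 70.0, config)

    def test_reentry_after_exit_gives_full_bolus(self, config):
        # hypotension -> suspension long enough to exit -> hypotension again
        mbps = [60, 58] + [90] * 8 + [60]
        actions, final = run_controller(
            [reading(2.5 * i, m) for i, m in enumerate(mbps)], 70.0, config)
        boluses = [a.bolus for a in actions if a.bolus > 0]
        assert boluses == pytest.approx([0.1, 0.05, 0.1])
        assert "exit" in [a.note for a in actions]
        assert final.mode is Mode.VASOPRESSOR


def random_trajectory_strategy():
    elem = st.tuples(
        st.floats(min_value=35.0, max_value=120.0),   # mbp
        st.booleans(),                                # valid
    )
    return st.lists(elem, min_size=1, max_size=60)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(traj=random_trajectory_strategy(),
       weight=st.floats(min_value=40.0, max_value=120.0))
def test_state_machine_invariants_on_random_trajectories(traj, weight):
    """Dose-safety invariants hold on arbitrary valid/invalid reading mixes."""
    config = ControllerConfig()
    readings = [reading(2.5 * i, mbp, valid=ok) for i, (mbp, ok) in enumerate(traj)]
    state = ControllerState()
    episode_boluses = 0
    for r in readings:
        prev = state
        state, action = step(state, r, weight, config)
        assert action.bolus <= config.bolus_cap + 1e-12
        assert 0.0 <= state.infusion_rate <= config.rate_cap
        if state.mode is Mode.NORMAL:
            assert state.infusion_rate == 0.0 and state.boluses_given == 0
        if not r.valid:
            assert state == prev
        if prev.mode is Mode.NORMAL and state.mode is Mode.VASOPRESSOR:
            episode_boluses = 0
        if action.bolus > 0:
            episode_boluses += 1
            assert episode_boluses <= 2


@settings(max_examples=100, deadline=None, derandomize=True)
@given(traj=st.lists(st.floats(min_value=65.0, max_value=120.0),
                     min_size=1, max_size=60))
def test_zero_drug_when_all_mbp_adequate(traj):
    """Lower-limit control delivers nothing if pressure never drops."""
    readings = [reading(2.5 * i, m) for i, m in enumerate(traj)]
    actions, _ = run_controller(readings, 70.0)
    assert sum(a.bolus for a in actions) == 0.0
    assert all(a.rate_setpoint == 0.0 for a in actions)


def test_replay_determinism(config):
    import numpy as np
    rng = np.random.default_rng(5)
    readings = [reading(2.5 * i, float(m), valid=bool(v))
                for i, (m, v) in enumerate(zip(
                    rng.uniform(45, 100, 80), rng.random(80) > 0.05))]
    a1, s1 = run_controller(readings, 62.0, config)
    a2, s2 = run_controller(readings, 62.0, config)
    assert a1 == a2 and s1 == s2
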