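"""Rule-based lower-limit controller for automated phenylephrine delivery.

The controller implements a threshold ("lower limit") control objective:
keep mean blood pressure (MBP) above a hypotension threshold rather than
track a set-point.  It is driven by intermittent noninvasive blood-pressure
(NIBP) readings taken every ~2.5 min and emits, per reading, a bolus dose
and/or a continuous-infusion rate set-point.

State machine summary
---------------------
The controller is in one of two modes:

* ``NORMAL`` — no drug is delivered.  A valid reading with MBP below the
  hypotension threshold triggers entry into vasopressor mode with a
  weight-based entry bolus (0.002 mg/kg, capped at 0.1 mg).
* ``VASOPRESSOR`` — active treatment.  Persistent hypotension after the
  entry bolus triggers a second bolus of half the entry dose and starts a
  continuous infusion; subsequent readings titrate the infusion rate.
  MBP above the suspension threshold (85 mmHg) suspends the infusion;
  a suspension lasting longer than the exit timeout (15 min) returns the
  controller to ``NORMAL`` and resets all counters.

Invalid (failed) cuff measurements never change the state: control is
frozen until the next valid reading.

All transitions are pure functions of ``(state, reading, weight, config)``,
so replaying a trajectory is deterministic and auditable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


class InvalidInputError(ValueError):
    """Raised when a reading, state or configuration violates its contract."""


class Mode(str, enum.Enum):
    NORMAL = "NORMAL"
    VASOPRESSOR = "VASOPRESSOR"


@dataclass(frozen=True)
class NIBPReading:
    """One cuff measurement.

    Parameters
    ----------
    t : float
        Time since evaluation start, minutes.
    sbp, mbp, dbp : float
        Systolic / mean / diastolic pressure, mmHg.  Ignored (may be NaN)
        when ``valid`` is False.
    valid : bool
        Measurement-success flag; False models a cuff failure.
    """

    t: float
    sbp: float
    mbp: float
    dbp: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.t < 0 or not math.isfinite(self.t):
            raise InvalidInputError(f"reading time must be finite and >= 0, got {self.t}")
        if self.valid:
            if not (0 < self.dbp <= self.mbp <= self.sbp < 300):
                raise InvalidInputError(
                    f"valid reading requires 0 < dbp <= mbp <= sbp < 300, "
                    f"got dbp={self.dbp}, mbp={self.mbp}, sbp={self.sbp}"
                )


@dataclass(frozen=True)
class RatePolicy:
    """Infusion-rate titration rule used while in vasopressor mode.

    The device protocol's exact formula is unpublished; this parametric
    stand-in starts the infusion at ``initial_per_kg`` mg/kg/h and adjusts
    it multiplicatively each epoch: step up under hypotension, hold in the
    low recovery band, step down in the upper band, suspend above the
    suspension threshold (remembering the rate for resumption).
    """

    initial_per_kg: float = 0.01   # mg/kg/h
    step_up: float = 1.25          # multiplier when MBP < t_low
    step_down: float = 0.8         # multiplier in [hold_upper, t_suspend]
    hold_upper: float = 75.0       # mmHg; below this (and >= t_low) hold rate
    floor_frac: float = 0.2        # step-down floor as fraction of initial rate

    def __post_init__(self) -> None:
        if self.initial_per_kg <= 0 or self.step_up <= 1 or not (0 < self.step_down < 1):
            raise InvalidInputError("rate policy requires initial>0, step_up>1, 0<step_down<1")
        if not (0 < self.floor_frac <= 1):
            raise InvalidInputError("floor_frac must be in (0, 1]")


@dataclass(frozen=True)
class ControllerConfig:
    """Thresholds, dose limits and pump parameters of the controller.

    Defaults mirror the clinical protocol: hypotension below 65 mmHg MBP,
    infusion suspension above 85 mmHg MBP, hypertension above 140 mmHg SBP,
    0.002 mg/kg entry bolus capped at 0.1 mg, 15-min exit timeout, 2.5-min
    NIBP epoch, 2 mg/h maximum continuous rate, 0.05 mg/mL solution.
    """

    t_low: float = 65.0
    t_suspend: float = 85.0
    t_hyper: float = 140.0
    bolus_per_kg: float = 0.002    # mg/kg
    bolus_cap: float = 0.1         # mg
    exit_timeout: float = 15.0     # min
    interval: float = 2.5          # min
    rate_cap: float = 2.0          # mg/h
    conc: float = 0.05             # mg/mL
    rate_policy: RatePolicy = field(default_factory=RatePolicy)

    def __post_init__(self) -> None:
        if min(self.t_low, self.t_suspend, self.t_hyper) <= 0:
            raise InvalidInputError("thresholds must be positive")
        if self.t_low >= self.t_suspend:
            raise InvalidInputError("t_low must be < t_suspend")
        if self.bolus_per_kg <= 0 or self.bolus_cap <= 0 or self.rate_cap <= 0:
            raise InvalidInputError("dose parameters must be positive")
        if self.exit_timeout <= 0 or self.interval <= 0 or self.conc <= 0:
            raise InvalidInputError("timing and concentration must be positive")

    @property
    def pump_step(self) -> float:
        """Pump rate resolution in mg/h (0.1 mL/h at the configured concentration)."""
        return self.conc * 0.1


@dataclass(frozen=True)
class ControllerState:
    """Complete memory of the state machine between readings."""

    mode: Mode = Mode.NORMAL
    boluses_given: int = 0
    infusion_rate: float = 0.0          # mg/h; 0 when suspended or NORMAL
    pre_suspension_rate: float = 0.0    # mg/h; rate restored on resumption
    suspended_since: float | None = None  # min; set while suspended in mode

    def __post_init__(self) -> None:
        if self.mode is Mode.NORMAL:
            if self.infusion_rate != 0 or self.boluses_given != 0 or self.suspended_since is not None:
                raise InvalidInputError("NORMAL mode requires zero rate, zero boluses, no clock")
        if self.infusion_rate < 0:
            raise InvalidInputError("infusion rate must be >= 0")
        if not 0 <= self.boluses_given <= 2:
            raise InvalidInputError("boluses_given must be 0, 1 or 2")
        if self.suspended_since is not None and self.infusion_rate != 0:
            raise InvalidInputError("suspension clock requires zero infusion rate")


@dataclass(frozen=True)
class DoseAction:
    """Dose commanded in response to one reading."""

    t: float
    bolus: float = 0.0           # mg
    rate_setpoint: float = 0.0   # mg/h after this reading
    note: str = "none"


def initial_bolus(weight: float, config: ControllerConfig = ControllerConfig()) -> float:
    """Entry bolus in mg: ``min(bolus_per_kg * weight, bolus_cap)``.

    >>> initial_bolus(70.0)
    0.1
    >>> initial_bolus(40.0)
    0.08
    """
    if weight <= 0 or not math.isfinite(weight):
        raise InvalidInputError(f"weight must be positive, got {weight}")
    return min(config.bolus_per_kg * weight, config.bolus_cap)


def quantize_rate(rate: float, config: ControllerConfig = ControllerConfig()) -> float:
    """Round a rate to the pump's 0.1 mL/h resolution and clip to [0, rate_cap]."""
    if rate < 0 or not math.isfinite(rate):
        raise InvalidInputError(f"rate must be finite and >= 0, got {rate}")
    step = config.pump_step
    quantized = round(rate / step) * step
    return min(max(quantized, 0.0), config.rate_cap)


def _initial_rate(weight: float, config: ControllerConfig) -> float:
    return quantize_rate(config.rate_policy.initial_per_kg * weight, config)


def step(
    state: ControllerState,
    reading: NIBPReading,
    weight: float,
    config: ControllerConfig = ControllerConfig(),
) -> tuple[ControllerState, DoseAction]:
    """Advance the state machine by one NIBP reading.

    Pure function: identical inputs always yield the identical
    ``(new_state, action)`` pair.  See the module docstring for the
    transition rules.
    """
    if weight <= 0:
        raise InvalidInputError(f"weight must be positive, got {weight}")
    t = reading.t

    if not reading.valid:
        # Measurement failure: control state is frozen until the next
        # valid reading; the running infusion continues at its set-point.
        return state, DoseAction(t=t, rate_setpoint=state.infusion_rate, note="frozen")

    mbp = reading.mbp
    policy = config.rate_policy

    if state.mode is Mode.NORMAL:
        if mbp < config.t_low:
            bolus = initial_bolus(weight, config)
            new = ControllerState(mode=Mode.VASOPRESSOR, boluses_given=1)
            return new, DoseAction(t=t, bolus=bolus, note="entry-bolus")
        return state, DoseAction(t=t, note="none")

    # VASOPRESSOR mode.  Exit check first: an interruption (zero-rate spell)
    # longer than the exit timeout ends the episode; the triggering reading
    # is consumed by the exit and delivers no dose.
    if state.suspended_since is not None and t - state.suspended_since > config.exit_timeout:
        return ControllerState(), DoseAction(t=t, note="exit")

    r0 = _initial_rate(weight, config)
    floor = quantize_rate(policy.floor_frac * r0, config)

    if mbp < config.t_low:
        if state.boluses_given == 1:
            # Persistent hypotension: half-dose second bolus, infusion on.
            bolus = initial_bolus(weight, config) / 2
            new = replace(state, boluses_given=2, infusion_rate=r0,
                          pre_suspension_rate=0.0, suspended_since=None)
            return new, DoseAction(t=t, bolus=bolus, rate_setpoint=r0, note="second-bolus")
        # Infusing (or suspended within the timeout): step up from the
        # running rate, or from the remembered rate on resumption.
        base = state.infusion_rate if state.suspended_since is None else state.pre_suspension_rate
        base = max(base, r0)  # never titrate from a dead-zero base
        rate = quantize_rate(base * policy.step_up, config)
        new = replace(state, infusion_rate=rate, pre_suspension_rate=0.0, suspended_since=None)
        return new, DoseAction(t=t, rate_setpoint=rate, note="step-up")

    if mbp > config.t_suspend:
        if state.suspended_since is not None:
            # Already suspended; keep the original clock running.
            return state, DoseAction(t=t, note="suspend")
        new = replace(state, infusion_rate=0.0,
                      pre_suspension_rate=state.infusion_rate, suspended_since=t)
        return new, DoseAction(t=t, rate_setpoint=0.0, note="suspend")

    # Recovery band t_low <= mbp <= t_suspend: maintain or resume the infusion.
    if state.boluses_given < 2:
        # Recovered after the entry bolus alone; no infusion was ever
        # started.  Treat the zero-rate spell as an interruption so the
        # episode can time out (clock starts at this reading).
        if state.suspended_since is None:
            state = replace(state, suspended_since=t)
        return state, DoseAction(t=t, note="hold")

    if state.suspended_since is not None:
        rate = quantize_rate(max(state.pre_suspension_rate, floor), config)
        new = replace(state, infusion_rate=rate, pre_suspension_rate=0.0, suspended_since=None)
        return new, DoseAction(t=t, rate_setpoint=rate, note="resume")

    if mbp < policy.hold_upper:
        return state, DoseAction(t=t, rate_setpoint=state.infusion_rate, note="hold")

    rate = quantize_rate(max(state.infusion_rate * policy.step_down, floor), config)
    new = replace(state, infusion_rate=rate)
    return new, DoseAction(t=t, rate_setpoint=rate, note="step-down")


def run_controller(
    readings: Iterable[NIBPReading],
    weight: float,
    config: ControllerConfig = ControllerConfig(),
    state: ControllerState | None = None,
) -> tuple[list[DoseAction], ControllerState]:
    """Replay the controller over a time-ordered trajectory.

    Returns one :class:`DoseAction` per reading plus the final state.
    Raises :class:`InvalidInputError` if reading times are not
    non-decreasing.
    """
    st = state if state is not None else ControllerState()
    actions: list[DoseAction] = []
    prev_t = -math.inf
    for reading in readings:
        if reading.t < prev_t:
            raise InvalidInputError(
                f"readings must be time-ordered: t={reading.t} after t={prev_t}"
            )
        prev_t = reading.t
        st, action = step(st, reading, weight, config)
        actions.append(action)
    return actions, st
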