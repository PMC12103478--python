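"""Seeded virtual-patient simulator for exercising the closed loop.

No patient model accompanies the clinical control algorithm — the
controller is deliberately model-free — so this module supplies an
explicitly synthetic test bed, not a physiological claim.  A virtual
patient is:

* a deterministic "true" mean-pressure signal: awake baseline, a
  first-order anesthetic depression, rectangular hypotensive disturbances,
  and a phenylephrine pressor effect;
* linear one-compartment pharmacokinetics (boluses and zero-order
  infusions, evaluated analytically — no ODE stepping) driving a
  saturating Emax effect;
* an NIBP measurement channel with Gaussian noise and i.i.d. cuff
  failures, from which SBP and DBP are derived via a pulse-pressure model.

Everything is driven by an explicit seed: the same seed, profile and
configuration reproduce every trajectory byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .controller import (
    ControllerConfig,
    ControllerState,
    DoseAction,
    InvalidInputError,
    NIBPReading,
    initial_bolus,
    step,
)

Arm = Literal["automated", "untreated", "manual-like"]


@dataclass(frozen=True)
class Disturbance:
    """One rectangular hypotensive event: MBP drops by `depth` during
    [onset, onset + duration)."""

    onset: float      # min
    depth: float      # mmHg
    duration: float   # min

    def active(self, t: float) -> bool:
        return self.onset <= t < self.onset + self.duration


@dataclass(frozen=True)
class PatientProfile:
    """Parameters of one virtual patient.

    PK/PD defaults are plausible placeholders for phenylephrine at
    NIBP-epoch time resolution (elimination half-life ~4.6 min, maximal
    pressor effect 30 mmHg, half-max at 0.05 mg effect-site amount); they
    are not clinically validated values.
    """

    weight: float = 65.0            # kg
    mbp_baseline: float = 95.0      # awake mean pressure, mmHg
    anesthetic_drop: float = 20.0   # steady-state depression, mmHg
    induction_tau: float = 5.0      # onset time constant of the drop, min
    disturbances: tuple[Disturbance, ...] = ()
    pp0: float = 25.0               # pulse-pressure intercept, mmHg
    pp1: float = 0.25               # pulse-pressure slope on MBP
    ke: float = 0.15                # elimination rate, 1/min
    emax: float = 30.0              # maximal pressor effect, mmHg
    c50: float = 0.05               # effect-site amount at half-max, mg
    noise_sd: float = 3.0           # NIBP measurement noise, mmHg
    fail_prob: float = 0.02         # cuff-failure probability per epoch
    mbp_floor: float = 30.0         # physiological floor on true MBP, mmHg
    duration: float = 180.0         # case length, min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise InvalidInputError("weight must be positive")
        if self.ke <= 0 or self.c50 <= 0 or self.emax < 0:
            raise InvalidInputError("ke > 0, c50 > 0, emax >= 0 required")
        if not 0 <= self.fail_prob < 1:
            raise InvalidInputError("fail_prob must be in [0, 1)")
        if self.noise_sd < 0 or self.duration <= 0:
            raise InvalidInputError("noise_sd >= 0 and duration > 0 required")


@dataclass
class DrugRecord:
    """Administered phenylephrine: bolus times/doses and infusion segments.

    ``infusion_segments`` are non-overlapping, time-ordered
    ``(start, end, rate)`` triples in minutes and mg/h; an open segment is
    represented with ``end = inf`` until closed.
    """

    boluses: list[tuple[float, float]] = field(default_factory=list)
    infusion_segments: list[tuple[float, float, float]] = field(default_factory=list)

    def add_bolus(self, t: float, dose: float) -> None:
        if dose < 0:
            raise InvalidInputError("bolus dose must be >= 0")
        if dose > 0:
            self.boluses.append((t, dose))

    def set_rate(self, t: float, rate: float) -> None:
        """Change the infusion rate at time t (closing any open segment)."""
        if rate < 0:
            raise InvalidInputError("infusion rate must be >= 0")
        if self.infusion_segments and math.isinf(self.infusion_segments[-1][1]):
            start, _, old = self.infusion_segments.pop()
            if old == rate:
                self.infusion_segments.append((start, math.inf, old))
                return
            if t > start:
                self.infusion_segments.append((start, t, old))
        if rate > 0:
            self.infusion_segments.append((t, math.inf, rate))

    def close(self, t: float) -> None:
        self.set_rate(t, 0.0)

    def total_dose(self) -> float:
        """Total drug delivered in mg (requires all segments closed)."""
        bolus = sum(d for _, d in self.boluses)
        inf = sum((e - s) * r / 60.0 for s, e, r in self.infusion_segments
                  if math.isfinite(e))
        return bolus + inf


def effect_site_amount(t: float, drug: DrugRecord, ke: float) -> float:
    """One-compartment drug amount (mg) at time t.

    Linear PK: each bolus contributes ``dose * exp(-ke * (t - t_b))``;
    each zero-order infusion segment accumulates to
    ``(rate/60)/ke * (1 - exp(-ke * dt))`` and decays after it ends.
    Superposition holds exactly.
    """
    amount = 0.0
    for t_b, dose in drug.boluses:
        if t >= t_b:
            amount += dose * math.exp(-ke * (t - t_b))
    for start, end, rate in drug.infusion_segments:
        if t <= start or rate == 0.0:
            continue
        k_inf = (rate / 60.0) / ke
        t_end = min(t, end)
        built = k_inf * (1.0 - math.exp(-ke * (t_end - start)))
        if t > t_end:
            built *= math.exp(-ke * (t - t_end))
        amount += built
    return amount


def drug_effect(amount: float, emax: float, c50: float) -> float:
    """Saturating pressor effect in mmHg: ``emax * C / (c50 + C)``."""
    if amount <= 0:
        return 0.0
    return emax * amount / (c50 + amount)


def true_mbp(t: float, profile: PatientProfile, drug: DrugRecord) -> float:
    """Noise-free mean pressure at time t (mmHg)."""
    if t < 0:
        raise InvalidInputError("t must be >= 0")
    drop = profile.anesthetic_drop
    if profile.induction_tau > 0:
        drop *= 1.0 - math.exp(-t / profile.induction_tau)
    disturbance = sum(d.depth for d in profile.disturbances if d.active(t))
    amount = effect_site_amount(t, drug, profile.ke)
    mbp = (profile.mbp_baseline - drop - disturbance
           + drug_effect(amount, profile.emax, profile.c50))
    # Severe-hypotension clamp: stacked disturbances are not allowed to
    # push the model below a survivable pressure.  max() preserves the
    # monotone-in-dose property.
    return max(mbp, profile.mbp_floor)


def pressures_from_mbp(mbp: float, profile: PatientProfile) -> tuple[float, float, float]:
    """Derive (sbp, mbp, dbp) from a mean pressure via the pulse-pressure
    model: sbp = mbp + pp0 + pp1*mbp, and dbp chosen so that
    mbp = dbp + (sbp - dbp)/3 holds."""
    sbp = mbp + profile.pp0 + profile.pp1 * mbp
    dbp = (3.0 * mbp - sbp) / 2.0
    return sbp, mbp, dbp


_INVALID = float("nan")


def measure(t: float, profile: PatientProfile, drug: DrugRecord,
            rng: np.random.Generator) -> NIBPReading:
    """Draw one NIBP reading: a cuff failure with probability ``fail_prob``,
    otherwise the true MBP plus Gaussian noise, resampled until the derived
    pressures are physiologically ordered and in range."""
    if rng.random() < profile.fail_prob:
        return NIBPReading(t=t, sbp=_INVALID, mbp=_INVALID, dbp=_INVALID, valid=False)
    truth = true_mbp(t, profile, drug)
    for _ in range(100):
        mbp = truth + rng.normal(0.0, profile.noise_sd) if profile.noise_sd > 0 else truth
        sbp, mbp, dbp = pressures_from_mbp(mbp, profile)
        if 0 < dbp <= mbp <= sbp < 300:
            return NIBPReading(t=t, sbp=sbp, mbp=mbp, dbp=dbp, valid=True)
    raise InvalidInputError(
        f"could not draw an in-range reading at t={t} (true MBP {truth:.1f})"
    )


def run_closed_loop(
    profile: PatientProfile,
    config: ControllerConfig = ControllerConfig(),
    duration: float | None = None,
    arm: Arm = "automated",
    manual_delay_prob: float = 0.5,
) -> tuple[list[NIBPReading], DrugRecord, list[DoseAction]]:
    """Simulate one case: measurements every ``config.interval`` min.

    Arms
    ----
    ``automated``
        Every reading is fed to the controller; its bolus and rate
        commands are applied to the drug record.
    ``untreated``
        No drug at all (negative control).
    ``manual-like``
        A caricature of manual treatment: each valid hypotensive reading
        earns one entry-sized bolus, delivered one epoch late with
        probability ``manual_delay_prob`` (the clinician is busy), and no
        continuous infusion is titrated.
    """
    if duration is None:
        duration = profile.duration
    if duration <= 0:
        raise InvalidInputError("duration must be positive")
    if arm not in ("automated", "untreated", "manual-like"):
        raise InvalidInputError(f"unknown arm {arm!r}")

    rng = np.random.default_rng(profile.seed)
    drug = DrugRecord()
    state = ControllerState()
    readings: list[NIBPReading] = []
    actions: list[DoseAction] = []
    pending_bolus = 0.0  # manual-like arm: dose deferred to the next epoch

    n_epochs = int(math.floor(duration / config.interval)) + 1
    for i in range(n_epochs):
        t = i * config.interval
        if pending_bolus > 0.0:
            drug.add_bolus(t, pending_bolus)
            pending_bolus = 0.0
        reading = measure(t, profile, drug, rng)
        readings.append(reading)

        if arm == "automated":
            state, action = step(state, reading, profile.weight, config)
            actions.append(action)
            if action.bolus > 0:
                drug.add_bolus(t, action.bolus)
            drug.set_rate(t, action.rate_setpoint)
        elif arm == "manual-like":
            if reading.valid and reading.mbp < config.t_low:
                dose = initial_bolus(profile.weight, config)
                if rng.random() < manual_delay_prob:
                    pending_bolus = dose
                else:
                    drug.add_bolus(t, dose)
        # untreated: nothing

    drug.close(n_epochs * config.interval)
    return readings, drug, actions


@dataclass(frozen=True)
class CohortSpec:
    """Distributional assumptions for drawing a synthetic cohort.

    Defaults: weight ~ Normal(65, 12) truncated above 40 kg, awake
    baseline ~ Normal(95, 10) mmHg, 1-5 hypotensive disturbances per case,
    case length ~ Uniform(90, 360) min.
    """

    weight_mean: float = 65.0
    weight_sd: float = 12.0
    weight_min: float = 40.0
    baseline_mean: float = 95.0
    baseline_sd: float = 10.0
    drop_mean: float = 20.0
    drop_sd: float = 4.0
    n_disturb_min: int = 1
    n_disturb_max: int = 5
    depth_range: tuple[float, float] = (8.0, 30.0)
    disturb_duration_range: tuple[float, float] = (5.0, 30.0)
    duration_range: tuple[float, float] = (90.0, 360.0)
    noise_sd: float = 3.0
    fail_prob: float = 0.02


def sample_cohort(n: int, seed: int, spec: CohortSpec = CohortSpec()) -> list[PatientProfile]:
    """Draw ``n`` reproducible virtual patients from the cohort spec."""
    if n <= 0:
        raise InvalidInputError("cohort size must be positive")
    rng = np.random.default_rng(seed)
    profiles: list[PatientProfile] = []
    for i in range(n):
        weight = 0.0
        while weight <= spec.weight_min:
            weight = rng.normal(spec.weight_mean, spec.weight_sd) if spec.weight_sd > 0 \
                else spec.weight_mean
            if spec.weight_sd == 0:
                weight = max(weight, spec.weight_min + 1e-9)
        baseline = rng.normal(spec.baseline_mean, spec.baseline_sd) if spec.baseline_sd > 0 \
            else spec.baseline_mean
        drop = max(rng.normal(spec.drop_mean, spec.drop_sd), 0.0) if spec.drop_sd > 0 \
            else spec.drop_mean
        duration = rng.uniform(*spec.duration_range)
        k = int(rng.integers(spec.n_disturb_min, spec.n_disturb_max + 1))
        disturbances = []
        for _ in range(k):
            onset = rng.uniform(10.0, max(duration - 10.0, 10.0))
            depth = rng.uniform(*spec.depth_range)
            d_dur = rng.uniform(*spec.disturb_duration_range)
            disturbances.append(Disturbance(onset=onset, depth=depth, duration=d_dur))
        disturbances.sort(key=lambda d: d.onset)
        profiles.append(PatientProfile(
            weight=weight,
            mbp_baseline=baseline,
            anesthetic_drop=drop,
            disturbances=tuple(disturbances),
            noise_sd=spec.noise_sd,
            fail_prob=spec.fail_prob,
            duration=duration,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return profiles
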