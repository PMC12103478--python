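# Methods

This note documents the models, parameter choices and known limitations
behind `vasoloop`.  It is the package's own account of its science; every
number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Controller

The controller is a deterministic state machine over intermittent NIBP
readings (one per 2.5-min epoch by default).  Modes are `NORMAL` and
`VASOPRESSOR`; the full state is `(mode, boluses_given, infusion_rate,
pre_suspension_rate, suspended_since)` and `step` is a pure function, so a
trajectory replays identically every time.

Thresholds and dose limits (all configurable in `ControllerConfig`):

| parameter | default | meaning |
|---|---|---|
| `t_low` | 65 mmHg MBP | hypotension threshold (strict: 65.0 is adequate) |
| `t_suspend` | 85 mmHg MBP | infusion suspension threshold (strict: 85.0 maintains) |
| `t_hyper` | 140 mmHg SBP | hypertension classification (strict) |
| `bolus_per_kg` / `bolus_cap` | 0.002 mg/kg / 0.1 mg | entry bolus; second bolus is half the entry dose |
| `exit_timeout` | 15 min | interruption length that ends an episode (strict >) |
| `rate_cap` | 2 mg/h | continuous infusion ceiling |
| `conc` | 0.05 mg/mL | solution concentration; pump resolution 0.1 mL/h ⇒ rates quantized to 0.005 mg/h |

### The infusion-rate policy

The in-device rate formula is not public, so the titration rule here is an
explicit, configurable stand-in (`RatePolicy`), not a reconstruction.  The
initial rate is `r0 = 0.01 mg/kg/h × weight` (quantized, capped) — about
0.7 mg/h for a 70-kg adult, the same order as hourly doses observed under
automated delivery in practice.  Per epoch while infusing:

* MBP < 65: rate ×1.25 (step-up),
* 65 ≤ MBP < 75: hold,
* 75 ≤ MBP ≤ 85: rate ×0.8, floored at 0.2·r0 (step-down),
* MBP > 85: suspend; the pre-suspension rate is remembered and restored on
  resumption.

### Decisions where the protocol is silent

* **Recovery after the entry bolus alone.**  If MBP recovers before the
  second bolus, there is no infusion to maintain or resume.  The
  implementation treats the zero-rate spell as an interruption: the
  15-min exit clock starts at that reading, so an episode that needed
  only one bolus eventually times out and exits.
* **The exit reading delivers no dose.**  When an interruption exceeds
  15 min, that reading performs the exit and counter reset; if the
  patient is simultaneously hypotensive, the *next* reading re-enters the
  mode with a full entry bolus.  This costs at most one epoch of delay
  and keeps the transition table unambiguous.
* **Re-entry within a case re-boluses in full.**  Each episode is
  self-contained; nothing carries over after an exit.
* **Spurious values self-correct.**  Every reading recomputes the rate,
  so an aberrant (but valid) measurement perturbs dosing for one epoch
  only; no outlier rejection is applied.

## Virtual patient

The controller is model-free by design, so no patient model exists to
copy; the simulator is a labeled synthetic test bed built from the
simplest components that produce realistic onset/offset behavior.

**True pressure.**
`MBP(t) = baseline − drop·(1 − e^(−t/τ)) − Σ active disturbances +
Emax·C(t)/(C50 + C(t))`, clamped below at `mbp_floor` (default 30 mmHg) so
stacked disturbances cannot produce unsurvivable pressures (the clamp is a
`max`, preserving monotonicity in dose).  Disturbances are rectangular
(onset, depth, duration) events.

**Pharmacokinetics.**  One linear compartment, evaluated in closed form
at measurement instants — no ODE stepping.  A bolus contributes
`dose·e^(−ke·Δt)`; a zero-order infusion builds to `(rate/60)/ke` and
decays after it stops.  Superposition is exact, which the tests verify to
1e−9 relative error against the analytic solutions.

**Defaults** (placeholders, not clinically validated PD): `ke = 0.15/min`
(≈4.6-min half-life), `Emax = 30 mmHg`, `C50 = 0.05 mg`.  With these, one
0.1 mg bolus raises MBP ≈20 mmHg transiently and a 0.7 mg/h infusion
sustains ≈19 mmHg — enough to exercise every controller branch.

**Measurement.**  Gaussian noise (σ = 3 mmHg) on the true MBP, i.i.d.
cuff failure with probability 0.02 per epoch (no failure correlation),
SBP derived as `mbp + 25 + 0.25·mbp` and DBP fixed by the standard
`MBP = DBP + (SBP − DBP)/3` identity; draws violating the pressure
ordering are resampled.

**Cohort.**  `sample_cohort` draws weight ~ N(65, 12) truncated above
40 kg, awake baseline ~ N(95, 10) mmHg, anesthetic drop ~ N(20, 4) mmHg,
1–5 disturbances per case (depth U(8, 30) mmHg, duration U(5, 30) min),
case length U(90, 360) min.  All randomness flows from a single seed;
the same seed reproduces every output byte.

**What the simulator does not model** — and hence what passing tests do
not show about real patients: baroreflex and heart-rate compensation,
cardiac output, drug tolerance, correlated measurement failures,
inter-individual PK variability, and surgeon/anesthesiologist
interventions.  The closed-loop benefit demonstrated on this cohort is a
directional statement about the controller's reaction speed, not a
clinical effect size.

## Metrics

"Percentage of time" means percentage of *valid* epochs: one cuff reading
represents one 2.5-min epoch, failed measurements are `MISSING` and leave
every denominator.  The adequate-time percentage uses the subtraction
identity `100 − pct(hypotensive ∪ hypertensive)`, so an epoch that is
both counts once in the union but contributes to both individual
percentages.  Consecutive-hypotension runs are maximal blocks of the
hypotensive indicator; `MISSING` epochs break runs by default (a run must
be observed to be consecutive) — configurable.  Published-style shares
are rounded half-up; exact fractions are always available.

Varvel indices (MDPE, MDAPE, wobble, divergence = least-squares slope of
|PE| on time) are included deliberately: they are set-point accuracy
measures, and two trajectories with identical lower-limit compliance can
have very different MDAPE.  That mismatch is why threshold control is
scored with time-in-range metrics instead.

## Statistics

All inference is the classical pooled-variance two-sample t
(`df = n1 + n2 − 2`).  Pooled (not Welch) is a deliberate choice: it is
the variant that reproduces the published endpoint inferences exactly
(verified in the acceptance tests; Welch does not).  Computing from
`(n, mean, SD)` summaries or from raw per-patient lists is algebraically
identical, which the suite checks against `scipy.stats.ttest_ind` on
random samples.

Non-inferiority shifts the null by the margin in the unfavorable
direction (`t = (diff + Δ)/se` for higher-is-better endpoints) and tests
one-sided at α = 0.025 — equivalently, the one-sided 97.5% confidence
limit must not cross the margin.  The conclusion flag is computed from
the CI criterion and agrees with `p < 0.025` in every random case tested.
Degenerate zero-variance inputs take the limiting t → ±∞.

The sample-size helper is a normal-approximation planning aid
(`n = (z₁₋α + z_power)²·2σ²/(Δ + δ)²`, inflated for dropout) and is
explicitly not a reconstruction of any published enrolment figure, whose
assumed SD is unpublished.

## Problem sizes and numerical choices

* Controller property checks run over 1,000 randomized trajectories of
  20–80 epochs; metric oracles over 1,000 random label sequences.
* Type-I-error calibration simulates 30,000 boundary trials (n = 11 vs 9,
  σ = 12%), enough to resolve the nominal 0.025 rate to ±0.003 at 3
  Monte-Carlo SDs.
* The closed-loop comparison uses 200 synthetic patients per arm — large
  enough that the automated-vs-untreated ordering is stable across seeds.
* Rates are quantized half-to-even via `round()` at the pump step; all
  percentage identities hold to 1e−9 without rescue tolerances.
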