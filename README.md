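# vasoloop

Closed-loop, lower-limit phenylephrine delivery for intraoperative
hypotension — a testable software reconstruction of a rule-based
vasopressor controller driven by intermittent noninvasive blood-pressure
(NIBP) readings, together with the virtual patients, time-in-range
endpoints and non-inferiority statistics needed to evaluate it.

## The problem

Intraoperative hypotension (mean blood pressure, MBP, below 65 mmHg) is
associated with postoperative organ injury, yet in routine practice blood
pressure is only measured by an arm cuff every 2.5 min and vasopressor
dosing depends on how quickly a busy anesthesiologist reacts.  A
*lower-limit* controller automates the reaction: it does not track a
set-point, it only acts to keep MBP above the threshold.

The control algorithm, per NIBP reading:

1. **Entry** — if MBP < 65 mmHg in normal mode, enter vasopressor mode and
   give a bolus of 0.002 mg/kg phenylephrine (capped at 0.1 mg).
2. **Persistence** — if the next valid reading is still hypotensive, give
   half the entry dose again and start a continuous infusion.
3. **Titration** — while hypotensive, step the infusion rate up
   (×1.25 per epoch); in the upper recovery band (75–85 mmHg) step it
   down (×0.8, floored); in between, hold.
4. **Suspension** — if MBP exceeds 85 mmHg, suspend the infusion and
   remember the rate; resume it if MBP returns below 85 mmHg.
5. **Exit** — if the infusion stays interrupted for more than 15 min, exit
   vasopressor mode and reset.

Failed cuff measurements never change controller state, rates are
quantized to the syringe pump's 0.1 mL/h resolution (0.05 mg/mL solution),
and the continuous rate is capped at 2 mg/h.

Endpoints are percentages of valid 2.5-min epochs: the *adequate blood
pressure time percentage* (MBP > 65 and SBP < 140 mmHg), hypotension- and
hypertension-time percentages, consecutive-hypotension run tabulations,
and the Varvel set-point indices (MDPE, MDAPE, wobble, divergence) for
contrast with threshold control.  Arms are compared with a pooled-variance
two-sample *t* non-inferiority test (margin Δ, one-sided α = 0.025):

    t = (x̄_test − x̄_ref + Δ) / (s_p · √(1/n₁ + 1/n₂)),   df = n₁ + n₂ − 2

## Worked example

Non-inferiority of an automated arm (n=11, adequate time 84.53 ± 11.05 %)
against a manual arm (n=9, 72.45 ± 14.93 %) at a 10-point margin, straight
from the summary statistics:

```bash
$ vasoloop stats --test 11,84.53,11.05 --reference 9,72.45,14.93 --margin 10
difference +12.08%  se 5.807  df 18
95% CI (-0.12, 24.28)  one-sided limit -0.12
t = 3.802, one-sided p = 0.0006521 -> non-inferior at margin 10%
```

The one-sided 97.5% lower confidence limit of the difference is −0.12%,
above the −10% margin, so the automated arm is non-inferior (p < 0.001).

A fully synthetic trial — simulate a seeded cohort through the closed
loop, score each patient, compare the arms:

```bash
vasoloop simulate --n 10 --arms automated,untreated --seed 42 --outdir simout
vasoloop evaluate simout/automated_patient*_trajectory.csv --out auto.json
vasoloop evaluate simout/untreated_patient*_trajectory.csv --out untr.json
vasoloop trial auto.json untr.json --margin 10 --out report.json
```

which prints, for this seed:

```
endpoint           test mean(SD)      ref mean(SD)    diff    p(NI)  conclusion
adequate_pct       88.08( 7.06)     71.12(22.57)   16.96   0.0010  non-inferior
hypo_pct            7.84( 5.04)     27.89(22.74)  -20.06   0.0004  non-inferior
hyper_pct           4.08( 4.50)      0.98( 1.17)    3.10   0.0001  non-inferior
```

The automated arm reacts every epoch, so its hypotension-time percentage
(7.84%) is a fraction of the untreated arm's (27.89%).  Every file the
pipeline writes is reproducible byte-for-byte from the seed recorded in
`simout/manifest.json`.

## Library surface

- `vasoloop.controller` — the state machine (`step`, `run_controller`,
  `initial_bolus`, `quantize_rate`).
- `vasoloop.virtual_patient` — seeded synthetic patients: one-compartment
  PK with a saturating pressor effect, hypotensive disturbances, noisy
  cuff measurements (`run_closed_loop`, `sample_cohort`).
- `vasoloop.metrics` — epoch classification, endpoint percentages, run
  tabulation, Varvel indices, lower-limit compliance.
- `vasoloop.stats` — pooled-variance CIs, non-inferiority tests from
  summaries or raw per-patient lists, sample-size planning aid.
- `vasoloop.cli` — `simulate`, `replay`, `evaluate`, `trial`, `stats`.

See `docs/methods.md` for the model details, parameter defaults and
limitations.

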