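"""Time-in-range endpoints, episode tabulation and Varvel control indices.

Endpoints are computed over intermittent NIBP epochs (one cuff reading ==
one 2.5-min epoch).  "Percentage of time" is operationalized as a
percentage of *valid* epochs: failed measurements are flagged MISSING and
excluded from every denominator — there is no interpolation between cuff
readings.

Classification thresholds (strict inequalities):

* hypotensive  — MBP < 65 mmHg
* hypertensive — SBP > 140 mmHg
* both may hold in the same epoch; such an epoch counts once in the
  union used for the adequate-time percentage but contributes to each
  individual percentage.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .controller import InvalidInputError, NIBPReading


class UndefinedEndpointError(ValueError):
    """Raised when an endpoint has an empty denominator (no valid epochs)."""


class Label(str, enum.Enum):
    ADEQUATE = "ADEQUATE"
    HYPOTENSIVE = "HYPOTENSIVE"
    HYPERTENSIVE = "HYPERTENSIVE"
    BOTH = "BOTH"
    MISSING = "MISSING"

    @property
    def is_hypotensive(self) -> bool:
        return self in (Label.HYPOTENSIVE, Label.BOTH)

    @property
    def is_hypertensive(self) -> bool:
        return self in (Label.HYPERTENSIVE, Label.BOTH)


@dataclass(frozen=True)
class EndpointPercentages:
    """Per-patient endpoint percentages over valid epochs in the window."""

    adequate_pct: float
    hypo_pct: float
    hyper_pct: float
    n_valid: int
    n_missing: int


@dataclass(frozen=True)
class RunTabulation:
    """Maximal consecutive hypotensive-epoch runs, grouped 1 / 2 / 3 / >=4."""

    counts: dict[int, int]          # exact run-length -> number of runs
    total_hypotensive: int

    @property
    def n_runs(self) -> int:
        return sum(self.counts.values())

    def grouped(self) -> dict[str, int]:
        g = {"1": 0, "2": 0, "3": 0, ">=4": 0}
        for length, k in self.counts.items():
            g["1" if length == 1 else "2" if length == 2 else
              "3" if length == 3 else ">=4"] += k
        return g

    def shares(self) -> dict[str, float]:
        """Exact percentage share of runs in each length class."""
        n = self.n_runs
        if n == 0:
            return {k: 0.0 for k in self.grouped()}
        return {k: 100.0 * v / n for k, v in self.grouped().items()}

    def shares_rounded(self) -> dict[str, int]:
        """Round-half-up integer shares, as reported in trial write-ups."""
        return {k: int(Decimal(v).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
                for k, v in self.shares().items()}


def classify(
    readings: Sequence[NIBPReading],
    t_low: float = 65.0,
    t_hyper: float = 140.0,
) -> list[Label]:
    """Label each reading; invalid readings become MISSING."""
    labels: list[Label] = []
    prev_t = -math.inf
    for r in readings:
        if r.t < prev_t:
            raise InvalidInputError("readings must be time-ordered")
        prev_t = r.t
        if not r.valid:
            labels.append(Label.MISSING)
            continue
        hypo = r.mbp < t_low
        hyper = r.sbp > t_hyper
        labels.append(Label.BOTH if (hypo and hyper)
                      else Label.HYPOTENSIVE if hypo
                      else Label.HYPERTENSIVE if hyper
                      else Label.ADEQUATE)
    return labels


def endpoint_percentages(
    labels: Sequence[Label],
    window: tuple[int, int] | None = None,
) -> EndpointPercentages:
    """Endpoint percentages over valid epochs.

    ``window`` is an optional half-open index range ``[start, stop)``
    bounding the evaluation period (e.g. opioid start to anesthetic stop);
    by default the whole sequence is the evaluation period.

    The adequate percentage uses the subtraction identity
    ``100 - pct(hypotensive OR hypertensive)`` so an epoch that is both
    counts only once in the union.
    """
    if window is not None:
        labels = labels[window[0]:window[1]]
    valid = [lab for lab in labels if lab is not Label.MISSING]
    n_missing = len(labels) - len(valid)
    if not valid:
        raise UndefinedEndpointError("no valid epochs in the evaluation window")
    n = len(valid)
    hypo = sum(lab.is_hypotensive for lab in valid)
    hyper = sum(lab.is_hypertensive for lab in valid)
    abnormal = sum(lab is not Label.ADEQUATE for lab in valid)
    return EndpointPercentages(
        adequate_pct=100.0 * (n - abnormal) / n,
        hypo_pct=100.0 * hypo / n,
        hyper_pct=100.0 * hyper / n,
        n_valid=n,
        n_missing=n_missing,
    )


def tabulate_runs(
    labels: Sequence[Label],
    missing_breaks_runs: bool = True,
) -> RunTabulation:
    """Decompose the hypotensive indicator into maximal consecutive runs.

    A run must be observed to be consecutive, so MISSING epochs break runs
    by default (set ``missing_breaks_runs=False`` to bridge them instead).
    """
    counts: dict[int, int] = {}
    total = 0
    run = 0
    for lab in labels:
        if lab is Label.MISSING and not missing_breaks_runs:
            continue
        if lab is not Label.MISSING and lab.is_hypotensive:
            run += 1
            total += 1
        else:
            if run:
                counts[run] = counts.get(run, 0) + 1
            run = 0
    if run:
        counts[run] = counts.get(run, 0) + 1
    return RunTabulation(counts=counts, total_hypotensive=total)


def run_tabulation_from_counts(counts: dict[int, int]) -> RunTabulation:
    """Build a tabulation directly from run-length counts (e.g. a published
    table) so share arithmetic can be applied to reported figures."""
    total = sum(length * k for length, k in counts.items())
    return RunTabulation(counts=dict(counts), total_hypotensive=total)


def varvel_indices(
    measured: Sequence[float],
    target: float,
    times: Sequence[float],
) -> tuple[float, float, float, float]:
    """Varvel performance indices for set-point control accuracy.

    With percentage performance error ``PE_i = 100 * (measured_i - target)
    / target``:

    * MDPE  (bias)        = median(PE)
    * MDAPE (inaccuracy)  = median(|PE|)
    * wobble (variability) = median(|PE_i - MDPE|)
    * divergence (trend)  = least-squares slope of |PE_i| on time, %/min

    These are set-point indices: two trajectories with identical
    lower-limit compliance can have very different MDAPE, which is why
    threshold control is evaluated with time-in-range metrics instead.
    """
    if target <= 0:
        raise InvalidInputError("target must be positive")
    measured = np.asarray(measured, dtype=float)
    times = np.asarray(times, dtype=float)
    if measured.size < 2 or measured.size != times.size:
        raise InvalidInputError("need >= 2 paired (measured, time) samples")
    pe = 100.0 * (measured - target) / target
    mdpe = float(np.median(pe))
    mdape = float(np.median(np.abs(pe)))
    wobble = float(np.median(np.abs(pe - mdpe)))
    slope = np.polyfit(times, np.abs(pe), 1)[0]
    return mdpe, mdape, wobble, float(slope)


def lower_limit_compliance(labels: Sequence[Label]) -> float:
    """Percentage of valid epochs meeting the lower-limit condition
    (not hypotensive); identically ``100 - hypo_pct``."""
    valid = [lab for lab in labels if lab is not Label.MISSING]
    if not valid:
        raise UndefinedEndpointError("no valid epochs")
    ok = sum(not lab.is_hypotensive for lab in valid)
    return 100.0 * ok / len(valid)
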