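"""Non-inferiority statistics for per-patient percentage endpoints.

All inference is the classical two-sample pooled-variance Student t
(df = n1 + n2 - 2), which can be computed either from raw per-patient
endpoint lists or directly from (n, mean, SD) group summaries — the two
routes are algebraically identical, so published summary tables are a
sufficient input.

Non-inferiority shifts the null by the margin in the unfavorable
direction and tests one-sided at alpha = 0.025; equivalently, the test
arm is non-inferior when the one-sided 97.5% confidence limit of the
mean difference stays on the favorable side of the margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .controller import InvalidInputError

Direction = Literal["higher-is-better", "lower-is-better"]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one arm's per-patient endpoint (%)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError("group must have n >= 2")
        if self.sd < 0:
            raise InvalidInputError("sd must be >= 0")

    @classmethod
    def from_samples(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise InvalidInputError("need >= 2 per-patient values")
        return cls(n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


@dataclass(frozen=True)
class NoninferiorityResult:
    difference: float       # test mean - reference mean (%)
    se: float               # pooled standard error (%)
    df: int
    t_stat: float           # margin-shifted t statistic
    p_one_sided: float
    ci_lower: float         # two-sided CI on the raw difference
    ci_upper: float
    one_sided_limit: float  # the CI bound facing the margin
    margin: float
    direction: Direction
    non_inferior: bool


def pooled_t_ci(
    a: GroupSummary,
    b: GroupSummary,
    level: float = 0.95,
) -> tuple[float, float, int, float, float]:
    """Pooled-variance t confidence interval for ``a.mean - b.mean``.

    Returns ``(diff, se, df, ci_lower, ci_upper)`` with
    ``sp^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2)`` and
    ``CI = diff +/- t_{(1+level)/2, df} * sp * sqrt(1/n1 + 1/n2)``.
    """
    if not 0 < level < 1:
        raise InvalidInputError("confidence level must be in (0, 1)")
    diff = a.mean - b.mean
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = math.sqrt(sp2) * math.sqrt(1.0 / a.n + 1.0 / b.n)
    tcrit = sps.t.ppf(0.5 + level / 2.0, df)
    return diff, se, df, diff - tcrit * se, diff + tcrit * se


def noninferiority_test(
    test: GroupSummary,
    reference: GroupSummary,
    margin: float,
    direction: Direction = "higher-is-better",
    alpha: float = 0.025,
) -> NoninferiorityResult:
    """One-sided non-inferiority t-test from group summaries.

    For a higher-is-better endpoint the null is
    ``mean_test - mean_ref <= -margin`` and
    ``t = (diff + margin) / se``; for lower-is-better the null is
    ``diff >= margin`` and ``t = (diff - margin) / se``.  The two-sided
    ``1 - 2*alpha`` CI is reported alongside, whose relevant bound gives
    the equivalent criterion (e.g. one-sided 97.5% lower limit > -margin).
    """
    if margin <= 0:
        raise InvalidInputError("margin must be positive")
    if direction not in ("higher-is-better", "lower-is-better"):
        raise InvalidInputError(f"unknown direction {direction!r}")
    if not 0 < alpha < 0.5:
        raise InvalidInputError("alpha must be in (0, 0.5)")

    level = 1.0 - 2.0 * alpha
    diff, se, df, lo, hi = pooled_t_ci(test, reference, level)
    if direction == "higher-is-better":
        shifted = diff + margin
        # zero-variance degenerate limit: the t statistic diverges
        t_stat = shifted / se if se > 0 else math.copysign(math.inf, shifted) \
            if shifted != 0 else 0.0
        p = float(sps.t.sf(t_stat, df))
        limit = lo
        non_inferior = limit > -margin
    else:
        shifted = diff - margin
        t_stat = shifted / se if se > 0 else math.copysign(math.inf, shifted) \
            if shifted != 0 else 0.0
        p = float(sps.t.cdf(t_stat, df))
        limit = hi
        non_inferior = limit < margin
    return NoninferiorityResult(
        difference=diff, se=se, df=df, t_stat=t_stat, p_one_sided=p,
        ci_lower=lo, ci_upper=hi, one_sided_limit=limit,
        margin=margin, direction=direction, non_inferior=non_inferior,
    )


def cumulative_probability(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical cumulative-probability coordinates (x sorted, p = i/n)
    for the distribution plots used to compare arms."""
    x = np.sort(np.asarray(values, dtype=float))
    p = np.arange(1, x.size + 1) / x.size
    return x, p


def endpoint_compare(
    test_values: Sequence[float],
    reference_values: Sequence[float],
    margin: float,
    direction: Direction = "higher-is-better",
) -> dict:
    """Compare two arms from raw per-patient endpoint percentages.

    Summarizes each arm, delegates to :func:`noninferiority_test`, and
    returns cumulative-probability coordinates for plotting.
    """
    a = GroupSummary.from_samples(test_values)
    b = GroupSummary.from_samples(reference_values)
    result = noninferiority_test(a, b, margin, direction)
    xt, pt = cumulative_probability(test_values)
    xr, pr = cumulative_probability(reference_values)
    return {
        "test_summary": a,
        "reference_summary": b,
        "result": result,
        "cumprob_test": (xt, pt),
        "cumprob_reference": (xr, pr),
    }


def sample_size_note(
    power: float,
    margin: float,
    dropout: float,
    assumed_sd: float,
    true_difference: float = 0.0,
    alpha: float = 0.025,
) -> dict:
    """Normal-approximation per-arm n for a two-sample non-inferiority test.

    ``n = (z_{1-alpha} + z_{power})^2 * 2 * sd^2 / (margin + true_difference)^2``
    (higher-is-better convention: a positive ``true_difference`` favors the
    test arm), then inflated by ``1 / (1 - dropout)`` and rounded up.

    This is a documented calculation aid only: it does NOT reproduce any
    particular trial's enrolment figure, whose assumed SD and expected
    difference are typically unpublished.
    """
    if not 0 < power < 1:
        raise InvalidInputError("power must be in (0, 1)")
    if margin <= 0 or assumed_sd <= 0:
        raise InvalidInputError("margin and assumed_sd must be positive")
    if not 0 <= dropout < 1:
        raise InvalidInputError("dropout must be in [0, 1)")
    effect = margin + true_difference
    if effect <= 0:
        raise InvalidInputError("margin + true_difference must be positive")
    z_a = sps.norm.ppf(1.0 - alpha)
    z_b = sps.norm.ppf(power)
    n_exact = (z_a + z_b) ** 2 * 2.0 * assumed_sd**2 / effect**2
    n_per_arm = math.ceil(n_exact)
    n_inflated = math.ceil(n_exact / (1.0 - dropout))
    return {
        "n_exact": n_exact,
        "n_per_arm": n_per_arm,
        "n_per_arm_with_dropout": n_inflated,
        "assumptions": {
            "power": power, "margin": margin, "dropout": dropout,
            "assumed_sd": assumed_sd, "true_difference": true_difference,
            "alpha_one_sided": alpha,
        },
        "note": ("Normal-approximation planning value only; does not "
                 "reconstruct any published enrolment target."),
    }
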