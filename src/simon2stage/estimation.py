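"""Point estimation and UMVUE-ordering exact confidence intervals.

The MLE ``s / n`` ignores the sequential stopping rule and is biased.  The
UMVUE conditions on the complete sufficient statistic (M, S_M): for a
stage-2 total ``s`` it is the ratio of two sums of binomial-coefficient
products, evaluated here in exact integer arithmetic.  When the realized
stage-2 size differs (non-informatively) from plan, the same formula holds
with the actual size substituted.

The UMVUE also induces an ordering of the sample space, which yields exact
confidence limits: the lower (upper) limit is the rate at which the
probability of an ordering statistic at least as large as the observed one
equals alpha/2 (1 - alpha/2).  That tail probability is nondecreasing in
the rate, so each limit is a unique root found by bracketed root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .design import SimonDesign, TrialOutcome, enumerate_paths, support_paths
from .exceptions import InvalidOutcomeError

__all__ = [
    "Estimate",
    "ConfidenceInterval",
    "mle",
    "umvue",
    "umvue_fraction",
    "umvue_order_ci",
    "exact_estimator_bias",
]

_ROOT_TOL = 1e-9


@dataclass(frozen=True)
class Estimate:
    """A point estimate of the response rate."""

    value: float
    method: str
    outcome: TrialOutcome | None = None
    exact: Fraction | None = None


@dataclass(frozen=True)
class ConfidenceInterval:
    """A two-sided confidence interval for the response rate."""

    lower: float
    upper: float
    level: float
    method: str
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError(f"invalid interval ({self.lower}, {self.upper})")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, pi: float) -> bool:
        return self.lower <= pi <= self.upper


def mle(outcome: TrialOutcome, design: SimonDesign) -> Estimate:
    """Maximum-likelihood estimate ``s / n`` at the stopping stage."""
    outcome.validate(design)
    n = outcome.n_enrolled(design)
    frac = Fraction(outcome.s, n)
    return Estimate(value=float(frac), method="MLE", outcome=outcome, exact=frac)


@lru_cache(maxsize=65536)
def _umvue_fraction(n1: int, r1: int, n2: int, m: int, s: int) -> Fraction:
    if m == 1:
        return Fraction(s, n1)
    lo = max(r1 + 1, s - n2)
    hi = min(s, n1)
    num = sum(math.comb(n1 - 1, x - 1) * math.comb(n2, s - x) for x in range(lo, hi + 1))
    den = sum(math.comb(n1, x) * math.comb(n2, s - x) for x in range(lo, hi + 1))
    return Fraction(num, den)


def umvue_fraction(outcome: TrialOutcome, design: SimonDesign) -> Fraction:
    """The UMVUE as an exact rational number."""
    outcome.validate(design)
    n2 = design.n2 if outcome.m == 1 else outcome.n2_actual
    return _umvue_fraction(design.n1, design.r1, n2, outcome.m, outcome.s)


def umvue(outcome: TrialOutcome, design: SimonDesign) -> Estimate:
    """Uniformly minimum-variance unbiased estimate of the response rate.

    Stage-1 stops give ``x1 / n1``; stage-2 outcomes give the exact
    integer-arithmetic ratio with the actual stage-2 size in place of the
    planned one.
    """
    frac = umvue_fraction(outcome, design)
    return Estimate(value=float(frac), method="UMVUE", outcome=outcome, exact=frac)


@lru_cache(maxsize=512)
def _support_umvues(design: SimonDesign, n2_actual: int) -> tuple[tuple[tuple[int, int], Fraction], ...]:
    return tuple(
        ((m, s), _umvue_fraction(design.n1, design.r1, n2_actual, m, s))
        for m, s in support_paths(design, n2_actual)
    )


def _ordering_tail(design: SimonDesign, n2_actual: int, obs_frac: Fraction,
                   pi: float, strict: bool = False) -> float:
    """P(UMVUE(M, S_M) >= observed UMVUE | pi), ties included.

    With ``strict=True`` the event excludes ties (used only where the
    tie-inclusive equation degenerates, see :func:`umvue_order_ci`).
    """
    dist = enumerate_paths(design, n2_actual, pi)
    if strict:
        mask = np.array([f > obs_frac for _, f in _support_umvues(design, n2_actual)])
    else:
        mask = np.array([f >= obs_frac for _, f in _support_umvues(design, n2_actual)])
    return float(dist.probabilities[mask].sum())


def umvue_order_ci(outcome: TrialOutcome, design: SimonDesign, level: float = 0.90) -> ConfidenceInterval:
    """Exact confidence interval from the UMVUE ordering of the sample space.

    If the observed path is the minimum of the ordering the lower limit is
    0; if it is the maximum the upper limit is 1.  Otherwise each limit is
    the unique root of the ordering-tail equation.  For the minimum path
    the tie-inclusive upper-tail event is the whole sample space and its
    equation has no root; there the strict-inequality event is used
    instead, which for a stage-1 zero count reproduces the familiar exact
    binomial (Clopper-Pearson) upper limit.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    outcome.validate(design)
    alpha = 1.0 - level
    n2_actual = design.n2 if outcome.m == 1 else outcome.n2_actual
    obs = umvue_fraction(outcome, design)
    all_fracs = [f for _, f in _support_umvues(design, n2_actual)]
    warnings: list[str] = []
    is_min = obs <= min(all_fracs)

    def tail(pi: float, strict: bool = False) -> float:
        return _ordering_tail(design, n2_actual, obs, pi, strict=strict)

    if is_min:
        lower = 0.0
    else:
        lower = float(brentq(lambda p: tail(p) - alpha / 2.0, 0.0, 1.0, xtol=_ROOT_TOL))
    if obs >= max(all_fracs):
        upper = 1.0
    else:
        upper = float(brentq(lambda p: tail(p, strict=is_min) - (1.0 - alpha / 2.0),
                             0.0, 1.0, xtol=_ROOT_TOL))
    lower = min(max(lower, 0.0), 1.0)
    upper = min(max(upper, 0.0), 1.0)
    if lower > upper:  # numerically pathological; should not happen
        warnings.append("crossed endpoints clipped")
        lower, upper = upper, lower
    return ConfidenceInterval(lower=lower, upper=upper, level=level,
                              method="UMVUE-ordering", warnings=tuple(warnings))


def exact_estimator_bias(design: SimonDesign, n2_actual: int, pi: float,
                         estimator: str = "UMVUE") -> float:
    """Exact bias E[estimate] - pi by full enumeration of the support."""
    if estimator not in ("MLE", "UMVUE"):
        raise ValueError(f"estimator must be 'MLE' or 'UMVUE', got {estimator!r}")
    dist = enumerate_paths(design, n2_actual, pi)
    vals = []
    for m, s in dist.paths:
        if estimator == "UMVUE":
            vals.append(float(_umvue_fraction(design.n1, design.r1, n2_actual, m, s)))
        else:
            n = design.n1 if m == 1 else design.n1 + n2_actual
            vals.append(s / n)
    return float(np.dot(dist.probabilities, np.asarray(vals)) - pi)
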