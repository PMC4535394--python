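"""Koyama-Chen conditional inference for a deviated second stage.

The planned design fixes, for each continuing stage-1 count ``x``, a
conditional rejection rate ``A(x, n2, pi) = P_pi[X2 > rt - x | n2]``.
When the realized stage-2 size differs from plan, the observed stage-2
tail probability is mapped back onto the planned design: first solve

    A(x1, n2, pi*) = P_pi0[X2 >= x2 | n2_actual]

for ``pi*``, then accumulate the p-value over stage-1 counts,
``sum_x P_pi0[X1 = x | n1] A(x, n2, pi*)``.

Replacing the null rate by a generic rate in both roles turns the same
procedure into a p-value function ``g``; its median inversion
``g(pi) = 0.5`` gives the point estimate, and ``g = alpha/2`` /
``g = 1 - alpha/2`` give the confidence limits.

Two outcomes defeat the procedure and are surfaced explicitly: a stage-1
count already above the final boundary (``A`` is identically 1, no
``pi*`` exists — an error), and zero stage-2 responders (``pi* = 1`` and
the p-value collapses to ``P_pi0[X1 > r1]``, independent of both ``x1``
and the realized stage-2 size — returned with a warning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import betainc, betaincinv
from scipy.stats import binom

from .design import SimonDesign, TrialOutcome
from .estimation import ConfidenceInterval, Estimate
from .exceptions import KCUndefinedError, Simon2StageError

__all__ = [
    "KCResult",
    "conditional_rejection_rate",
    "stage1_pvalue",
    "kc_pvalue",
    "kc_pvalue_function",
    "kc_estimate",
    "kc_ci",
]

_ROOT_TOL = 1e-9
_EPS = 1e-10


@dataclass(frozen=True)
class KCResult:
    """Outcome of the conditional p-value computation."""

    p_value: float
    pi_star: float
    pi0: float
    estimate: float | None = None
    ci: ConfidenceInterval | None = None
    degenerate_flag: str = "none"
    warnings: tuple[str, ...] = ()


def conditional_rejection_rate(x: int, n2: int, pi: float, design: SimonDesign) -> float:
    """A(x, n2, pi): chance stage 2 pushes the total past the boundary.

    Identically 1 once the stage-1 count already exceeds the final
    boundary.  Only defined for counts that continue past the interim.
    """
    if x <= design.r1:
        raise ValueError(
            f"conditional rejection rate needs x > r1 ({design.r1}); "
            f"x={x} stops at stage 1"
        )
    if x > design.n1:
        raise ValueError(f"x={x} exceeds n1={design.n1}")
    if not (0.0 <= pi <= 1.0):
        raise ValueError(f"pi must lie in [0, 1], got {pi}")
    k = design.rt - x
    if k < 0:
        return 1.0
    return float(binom.sf(k, n2, pi))


def stage1_pvalue(x1: int, n1: int, pi0: float) -> float:
    """Exact binomial upper-tail p-value for a stage-1 stop, P[X1 >= x1]."""
    if not (0 <= x1 <= n1):
        raise ValueError(f"need 0 <= x1 <= n1, got x1={x1}, n1={n1}")
    return float(binom.sf(x1 - 1, n1, pi0))


def _upper_tail(x2: int, n2_actual: int, pi: float) -> float:
    """P_pi[X2 >= x2 | n2_actual] via the regularized incomplete beta."""
    if x2 <= 0:
        return 1.0
    return float(betainc(x2, n2_actual - x2 + 1, pi))


def _solve_pi_star(x1: int, design: SimonDesign, target: float) -> float:
    """Invert A(x1, n2, .) = target in closed form.

    ``A(x1, n2, pi) = I_pi(k + 1, n2 - k)`` with ``k = rt - x1``, so the
    inverse is the incomplete-beta quantile.
    """
    k = design.rt - x1
    n2 = design.n2
    if k < 0:
        raise KCUndefinedError(
            f"x1={x1} exceeds rt={design.rt}: A(x1, n2, pi) is identically 1 "
            "and pi* cannot be determined",
            flag="x1_exceeds_rt",
        )
    if k >= n2:
        raise KCUndefinedError(
            f"rt - x1 = {k} >= n2 = {n2}: A(x1, n2, pi) is identically 0 "
            "and pi* cannot be determined",
            flag="a_identically_zero",
        )
    if target >= 1.0:
        return 1.0
    if target <= 0.0:
        return 0.0
    pi_star = float(betaincinv(k + 1, n2 - k, target))
    if not np.isfinite(pi_star):
        # betaincinv loses the thread for extremely small targets; there
        # A(x1, n2, pi) ~ C(n2, k+1) pi^(k+1), which inverts in log space
        log_c = math.lgamma(n2 + 1) - math.lgamma(k + 2) - math.lgamma(n2 - k)
        pi_star = math.exp((math.log(target) - log_c) / (k + 1))
    return min(max(pi_star, 0.0), 1.0)


def _step_b(design: SimonDesign, pi_weights: float, pi_star: float) -> float:
    """Sum over continuing stage-1 counts of P[X1=x] A(x, n2, pi*)."""
    xs = np.arange(design.r1 + 1, design.n1 + 1)
    a = np.where(design.rt - xs < 0, 1.0, binom.sf(design.rt - xs, design.n2, pi_star))
    return float(np.sum(binom.pmf(xs, design.n1, pi_weights) * a))


def kc_pvalue(outcome: TrialOutcome, design: SimonDesign, pi0: float) -> KCResult:
    """Conditional p-value for a stage-2 outcome with any stage-2 size.

    Raises :class:`KCUndefinedError` when ``x1 > rt``.  When ``x2 = 0``
    the p-value degenerates to ``P_pi0[X1 > r1]`` (with ``pi* = 1``) and
    a warning records that it ignores both ``x1`` and the stage-2 size.
    """
    if not (0.0 < pi0 < 1.0):
        raise ValueError(f"pi0 must lie strictly inside (0, 1), got {pi0}")
    outcome.validate(design)
    if outcome.m == 1:
        raise ValueError("stage-1 stop: use stage1_pvalue(x1, n1, pi0) instead")
    if outcome.x1 > design.rt:
        raise KCUndefinedError(
            f"x1={outcome.x1} exceeds rt={design.rt}: the conditional method "
            "breaks down (A is identically 1)",
            flag="x1_exceeds_rt",
        )
    if outcome.x2 == 0:
        p = float(binom.sf(design.r1, design.n1, pi0))
        return KCResult(
            p_value=p, pi_star=1.0, pi0=pi0, degenerate_flag="x2_zero",
            warnings=(
                "x2=0: p-value equals P[X1 > r1] and ignores x1 and the "
                "actual stage-2 size",
            ),
        )
    target = _upper_tail(outcome.x2, outcome.n2_actual, pi0)
    pi_star = _solve_pi_star(outcome.x1, design, target)
    p = _step_b(design, pi0, pi_star)
    return KCResult(p_value=p, pi_star=pi_star, pi0=pi0)


def kc_pvalue_function(outcome: TrialOutcome, design: SimonDesign, pi: float) -> float:
    """The p-value procedure evaluated with ``pi`` in both null roles.

    ``g(pi)`` is nondecreasing in ``pi`` and runs from 0 to 1, so it can
    be inverted for estimation and confidence limits.
    """
    if not (0.0 < pi < 1.0):
        raise ValueError(f"pi must lie strictly inside (0, 1), got {pi}")
    outcome.validate(design)
    if outcome.m == 1:
        return stage1_pvalue(outcome.x1, design.n1, pi)
    if outcome.x1 > design.rt:
        raise KCUndefinedError(
            f"x1={outcome.x1} exceeds rt={design.rt}: the conditional method "
            "breaks down (A is identically 1)",
            flag="x1_exceeds_rt",
        )
    if outcome.x2 == 0:
        return float(binom.sf(design.r1, design.n1, pi))
    target = _upper_tail(outcome.x2, outcome.n2_actual, pi)
    pi_star = _solve_pi_star(outcome.x1, design, target)
    return _step_b(design, pi, pi_star)


def _check_monotone(g, label: str) -> None:
    """Coarse-grid guard that the p-value function is nondecreasing."""
    grid = np.linspace(0.02, 0.98, 25)
    vals = np.array([g(p) for p in grid])
    if np.any(np.diff(vals) < -1e-8):
        raise Simon2StageError(
            f"{label}: p-value function is not nondecreasing on a coarse "
            "grid; refusing to invert"
        )


def _invert(g, q: float) -> float:
    """Root of g(pi) = q for a nondecreasing g on (0, 1), clipped to [0, 1]."""
    lo, hi = _EPS, 1.0 - _EPS
    glo, ghi = g(lo), g(hi)
    if glo >= q:
        return 0.0
    if ghi <= q:
        return 1.0
    return float(brentq(lambda p: g(p) - q, lo, hi, xtol=_ROOT_TOL))


def kc_estimate(outcome: TrialOutcome, design: SimonDesign) -> Estimate:
    """Median-unbiased estimate: the rate where the p-value function is 1/2.

    Stage-1 stops fall back to the unbiased ``x1 / n1``.
    """
    outcome.validate(design)
    if outcome.m == 1:
        return Estimate(value=outcome.x1 / design.n1, method="KC", outcome=outcome)
    g = lambda p: kc_pvalue_function(outcome, design, p)
    _check_monotone(g, "kc_estimate")
    return Estimate(value=_invert(g, 0.5), method="KC", outcome=outcome)


def kc_ci(outcome: TrialOutcome, design: SimonDesign, level: float = 0.90) -> ConfidenceInterval:
    """Confidence limits by inverting the p-value function at the tails.

    The lower limit solves ``g = alpha/2`` and the upper ``g = 1 -
    alpha/2``.  Stage-1 stops use the exact (Clopper-Pearson) binomial
    tail inversion, whose lower equation is the same stage-1 p-value
    condition ``P[X1 >= x1] = alpha/2``.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    outcome.validate(design)
    alpha = 1.0 - level
    if outcome.m == 1:
        x1, n1 = outcome.x1, design.n1
        lower = 0.0 if x1 == 0 else float(betaincinv(x1, n1 - x1 + 1, alpha / 2.0))
        upper = 1.0 if x1 == n1 else float(betaincinv(x1 + 1, n1 - x1, 1.0 - alpha / 2.0))
        return ConfidenceInterval(lower=lower, upper=upper, level=level, method="KC")
    g = lambda p: kc_pvalue_function(outcome, design, p)
    _check_monotone(g, "kc_ci")
    lower = _invert(g, alpha / 2.0)
    upper = _invert(g, 1.0 - alpha / 2.0)
    return ConfidenceInterval(lower=lower, upper=upper, level=level, method="KC")
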