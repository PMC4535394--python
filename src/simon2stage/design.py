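"""Simon two-stage designs, their sample space and operating characteristics.

A Simon two-stage design enrolls ``n1`` patients; if the number of
responders ``X1`` is at most the futility boundary ``r1`` the trial stops,
otherwise a further ``n2 = nt - n1`` patients are enrolled and the drug is
declared active when the total responder count exceeds ``rt``.  There is no
early stop for efficacy.

Because of the interim stop, the pair (stopping stage ``M``, cumulative
responders ``S_M``) is complete and sufficient for the response rate, and
all exact inference in this package runs over the enumerated support of
``(M, S_M)``.  When the trial's second stage actually enrolled
``n2_actual != n2`` patients for reasons unrelated to the observed
responses, the same distribution applies with ``n2_actual`` substituted for
``n2`` (conditional likelihood given the realized stage-2 size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterator

import numpy as np
from scipy.stats import binom

from .exceptions import (
    ConfigurationError,
    InfeasibleDesignError,
    InvalidOutcomeError,
    SupportError,
)

__all__ = [
    "SimonDesign",
    "TrialOutcome",
    "PathDistribution",
    "OperatingCharacteristics",
    "pmf",
    "pmf_or_zero",
    "log_pmf_coefficient",
    "enumerate_paths",
    "support_paths",
    "reject_h0",
    "operating_characteristics",
    "search_design",
]


@dataclass(frozen=True)
class SimonDesign:
    """A Simon two-stage design with optional planning rates.

    Parameters
    ----------
    r1, n1 : int
        Stage-1 futility boundary and sample size; stop when ``X1 <= r1``.
    rt, nt : int
        Final futility boundary and planned total sample size; reject the
        null when the final responder total exceeds ``rt``.
    pi0, pi1 : float, optional
        Null and alternative response rates used at the planning stage.
    alpha, beta : float, optional
        Nominal one-sided type I and type II error rates of the plan.
    """

    r1: int
    n1: int
    rt: int
    nt: int
    pi0: float | None = None
    pi1: float | None = None
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        for name in ("r1", "n1", "rt", "nt"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if not (0 <= self.r1 < self.n1):
            raise ValueError(f"need 0 <= r1 < n1, got r1={self.r1}, n1={self.n1}")
        if not (self.r1 <= self.rt < self.nt):
            raise ValueError(f"need r1 <= rt < nt, got rt={self.rt}, nt={self.nt}")
        if not (self.n1 < self.nt):
            raise ValueError(f"need n1 < nt, got n1={self.n1}, nt={self.nt}")
        if self.pi0 is not None and self.pi1 is not None:
            if not (0 < self.pi0 < self.pi1 <= 1):
                raise ValueError(
                    f"need 0 < pi0 < pi1 <= 1, got pi0={self.pi0}, pi1={self.pi1}"
                )

    @property
    def n2(self) -> int:
        """Planned stage-2 sample size, ``nt - n1``."""
        return self.nt - self.n1

    def with_rates(self, pi0: float | None = None, pi1: float | None = None) -> "SimonDesign":
        return replace(self, pi0=pi0 if pi0 is not None else self.pi0,
                       pi1=pi1 if pi1 is not None else self.pi1)

    def to_dict(self) -> dict:
        out = {"r1": self.r1, "n1": self.n1, "rt": self.rt, "nt": self.nt}
        for k in ("pi0", "pi1", "alpha", "beta"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SimonDesign":
        known = {k: d[k] for k in ("r1", "n1", "rt", "nt", "pi0", "pi1", "alpha", "beta") if k in d}
        return cls(**known)


@dataclass(frozen=True)
class TrialOutcome:
    """An observed sample path of a two-stage trial.

    ``m`` is the stopping stage.  When ``m == 1`` the trial stopped at the
    interim with ``x1`` responders; ``x2`` and ``n2_actual`` are absent.
    When ``m == 2`` the second stage enrolled ``n2_actual`` patients (which
    may differ from the planned ``n2``) and observed ``x2`` responders.
    """

    m: int
    x1: int
    x2: int | None = None
    n2_actual: int | None = None

    def __post_init__(self) -> None:
        if self.m not in (1, 2):
            raise InvalidOutcomeError(f"stopping stage m must be 1 or 2, got {self.m}")
        if self.m == 1:
            if self.x2 is not None or self.n2_actual is not None:
                raise InvalidOutcomeError("stage-1 stop must not carry x2 or n2_actual")
        else:
            if self.x2 is None or self.n2_actual is None:
                raise InvalidOutcomeError("stage-2 outcome requires x2 and n2_actual")
            if self.n2_actual < 1:
                raise InvalidOutcomeError("n2_actual must be a positive integer")
            if not (0 <= self.x2 <= self.n2_actual):
                raise InvalidOutcomeError(
                    f"need 0 <= x2 <= n2_actual, got x2={self.x2}, n2_actual={self.n2_actual}"
                )
        if self.x1 < 0:
            raise InvalidOutcomeError("x1 must be nonnegative")

    @property
    def s(self) -> int:
        """Cumulative responders at the stopping stage."""
        return self.x1 if self.m == 1 else self.x1 + self.x2

    @property
    def n_total(self) -> int:
        """Total enrolled at the stopping stage (requires n1 for m=1)."""
        raise AttributeError("use n_enrolled(design) — n_total depends on n1")

    def n_enrolled(self, design: SimonDesign) -> int:
        return design.n1 if self.m == 1 else design.n1 + self.n2_actual

    def validate(self, design: SimonDesign) -> None:
        """Check consistency with the design's stopping rule."""
        if self.m == 1:
            if self.x1 > design.r1:
                raise InvalidOutcomeError(
                    f"m=1 requires x1 <= r1 ({design.r1}), got x1={self.x1}"
                )
        else:
            if self.x1 <= design.r1:
                raise InvalidOutcomeError(
                    f"m=2 requires x1 > r1 ({design.r1}), got x1={self.x1}"
                )
        if self.x1 > design.n1:
            raise InvalidOutcomeError(f"x1={self.x1} exceeds n1={design.n1}")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Exact frequentist properties of a planned design at one rate."""

    reject_prob: float
    pet: float
    expected_n: float


@dataclass
class PathDistribution:
    """The enumerated support of (M, S_M) with probabilities at one rate."""

    design: SimonDesign
    n2_actual: int
    pi: float
    paths: list[tuple[int, int]]
    probabilities: np.ndarray = field(repr=False)

    def __iter__(self) -> Iterator[tuple[int, int, float]]:
        for (m, s), p in zip(self.paths, self.probabilities):
            yield m, s, float(p)

    def __len__(self) -> int:
        return len(self.paths)

    def total(self) -> float:
        return float(self.probabilities.sum())


def support_paths(design: SimonDesign, n2_actual: int) -> list[tuple[int, int]]:
    """All reachable (m, s) paths: stage-1 stops then stage-2 completions."""
    if n2_actual < 1:
        raise ValueError("n2_actual must be a positive integer")
    stage1 = [(1, s) for s in range(0, design.r1 + 1)]
    stage2 = [(2, s) for s in range(design.r1 + 1, design.n1 + n2_actual + 1)]
    return stage1 + stage2


@lru_cache(maxsize=4096)
def _stage2_coefficient(n1: int, r1: int, n2: int, s: int) -> int:
    """Exact integer path count for a stage-2 total of ``s`` responders.

    Sums C(n1, x1) C(n2, s - x1) over stage-1 counts x1 compatible with
    continuing past the interim, i.e. x1 from max(r1+1, s-n2) to min(s, n1).
    """
    lo = max(r1 + 1, s - n2)
    hi = min(s, n1)
    return sum(math.comb(n1, x1) * math.comb(n2, s - x1) for x1 in range(lo, hi + 1))


def log_pmf_coefficient(design: SimonDesign, n2_actual: int, m: int, s: int) -> float:
    """log of the integer combinatorial coefficient of the path (m, s)."""
    if m == 1:
        return math.lgamma(design.n1 + 1) - math.lgamma(s + 1) - math.lgamma(design.n1 - s + 1)
    return math.log(_stage2_coefficient(design.n1, design.r1, n2_actual, s))


def _check_support(design: SimonDesign, n2_actual: int, m: int, s: int) -> None:
    if m == 1:
        if not (0 <= s <= design.r1):
            raise SupportError(f"m=1 requires 0 <= s <= r1 ({design.r1}), got s={s}")
    elif m == 2:
        if not (design.r1 + 1 <= s <= design.n1 + n2_actual):
            raise SupportError(
                f"m=2 requires r1+1 ({design.r1 + 1}) <= s <= n1+n2_actual "
                f"({design.n1 + n2_actual}), got s={s}"
            )
    else:
        raise SupportError(f"stage m must be 1 or 2, got {m}")


def pmf(design: SimonDesign, n2_actual: int, m: int, s: int, pi: float) -> float:
    """Probability of stopping at stage ``m`` with ``s`` total responders.

    For ``m == 1`` this is the Binomial(n1, pi) mass at ``s``; for
    ``m == 2`` it sums over the compatible stage-1 counts, with the actual
    stage-2 size in place of the planned one.  Raises ``SupportError``
    outside the sample space (use :func:`pmf_or_zero` to get 0 instead).
    """
    _check_support(design, n2_actual, m, s)
    if not (0.0 <= pi <= 1.0):
        raise ValueError(f"pi must lie in [0, 1], got {pi}")
    n = design.n1 if m == 1 else design.n1 + n2_actual
    if pi == 0.0:
        return 1.0 if s == 0 else 0.0
    if pi == 1.0:
        return 1.0 if (m == 2 and s == n) or (m == 1 and s == n) else 0.0
    logp = (
        log_pmf_coefficient(design, n2_actual, m, s)
        + s * math.log(pi)
        + (n - s) * math.log1p(-pi)
    )
    return math.exp(logp)


def pmf_or_zero(design: SimonDesign, n2_actual: int, m: int, s: int, pi: float) -> float:
    """Totalized pmf: returns 0 for paths outside the support."""
    try:
        return pmf(design, n2_actual, m, s, pi)
    except SupportError:
        return 0.0


def enumerate_paths(design: SimonDesign, n2_actual: int, pi: float) -> PathDistribution:
    """Materialize the full support with probabilities at rate ``pi``."""
    paths = support_paths(design, n2_actual)
    probs = np.array([pmf(design, n2_actual, m, s, pi) for m, s in paths])
    return PathDistribution(design=design, n2_actual=n2_actual, pi=pi,
                            paths=paths, probabilities=probs)


def reject_h0(design: SimonDesign, outcome: TrialOutcome, pi0: float | None = None) -> bool:
    """Final efficacy decision for an observed outcome.

    Stage-1 stops never reject.  With the planned stage-2 size the rule is
    the design's threshold ``s > rt``.  With a deviated stage-2 size the
    planned conditional rejection rate ``A(x1, n2, pi0)`` is kept as the
    conditional critical value: reject when the observed conditional tail
    ``P_pi0[X2 >= x2 | n2_actual]`` does not exceed it.
    """
    outcome.validate(design)
    if outcome.m == 1:
        return False
    if outcome.n2_actual == design.n2:
        return outcome.s > design.rt
    pi0 = pi0 if pi0 is not None else design.pi0
    if pi0 is None:
        raise ConfigurationError("reject_h0 with a deviated stage-2 size requires pi0")
    k = design.rt - outcome.x1
    a = 1.0 if k < 0 else float(binom.sf(k, design.n2, pi0))
    tail = float(binom.sf(outcome.x2 - 1, outcome.n2_actual, pi0))
    return tail <= a


def operating_characteristics(design: SimonDesign, pi: float) -> OperatingCharacteristics:
    """Exact rejection probability, PET and expected sample size at ``pi``.

    The rejection probability sums, over stage-1 counts that continue,
    the chance that stage 2 pushes the total past the final boundary.
    """
    if not (0.0 <= pi <= 1.0):
        raise ValueError(f"pi must lie in [0, 1], got {pi}")
    xs = np.arange(design.r1 + 1, design.n1 + 1)
    reject = float(np.sum(binom.pmf(xs, design.n1, pi) * binom.sf(design.rt - xs, design.n2, pi)))
    pet = float(binom.cdf(design.r1, design.n1, pi))
    expected_n = design.n1 + (1.0 - pet) * design.n2
    return OperatingCharacteristics(reject_prob=reject, pet=pet, expected_n=expected_n)


def _feasible_designs(pi0: float, pi1: float, alpha: float, beta: float,
                      n_max: int) -> Iterator[tuple[float, SimonDesign]]:
    """Yield (expected_n_at_pi0, design) for every feasible design, nt <= n_max.

    Vectorized over (r1, rt) for each (n1, nt) pair: the rejection
    probability for all boundaries comes from one outer-product table.
    """
    for nt in range(2, n_max + 1):
        for n1 in range(1, nt):
            n2 = nt - n1
            x = np.arange(0, n1 + 1)
            b0 = binom.pmf(x, n1, pi0)
            b1 = binom.pmf(x, n1, pi1)
            # sf_k[j] = P[X2 > j] at j = -1 .. nt ; index shift of n2+1 keeps j >= -n2-1 valid
            js = np.arange(-(n1 + 1), nt + 1)
            sf0 = binom.sf(js, n2, pi0)
            sf1 = binom.sf(js, n2, pi1)
            off = n1 + 1
            for rt in range(0, nt):
                # contribution of each stage-1 count x to rejection: P[X1=x] P[X2 > rt-x]
                c0 = b0 * sf0[off + rt - x]
                c1 = b1 * sf1[off + rt - x]
                # suffix sums over x > r1
                r0 = np.cumsum(c0[::-1])[::-1]
                r1max = min(n1 - 1, rt)
                for r1v in range(0, r1max + 1):
                    if r0[r1v + 1] > alpha:
                        continue
                    p1 = np.sum(c1[r1v + 1:])
                    if p1 < 1.0 - beta:
                        continue
                    pet0 = binom.cdf(r1v, n1, pi0)
                    en = n1 + (1.0 - pet0) * n2
                    yield en, SimonDesign(r1=r1v, n1=n1, rt=rt, nt=nt,
                                          pi0=pi0, pi1=pi1, alpha=alpha, beta=beta)


def search_design(pi0: float, pi1: float, alpha: float, beta: float,
                  criterion: str = "optimal", n_max: int = 55) -> SimonDesign:
    """Search all designs with nt <= n_max meeting the error constraints.

    ``optimal`` minimizes the expected sample size under the null;
    ``minimax`` minimizes the maximum sample size nt, breaking ties by
    expected size.  Remaining ties break deterministically by smaller nt,
    then smaller n1, then smaller r1.
    """
    if not (0 < pi0 < pi1 < 1):
        raise ValueError("need 0 < pi0 < pi1 < 1")
    if criterion not in ("optimal", "minimax"):
        raise ValueError(f"criterion must be 'optimal' or 'minimax', got {criterion!r}")
    best_key: tuple | None = None
    best: SimonDesign | None = None
    for en, d in _feasible_designs(pi0, pi1, alpha, beta, n_max):
        if criterion == "optimal":
            key = (en, d.nt, d.n1, d.r1)
        else:
            key = (d.nt, en, d.n1, d.r1)
        if best_key is None or key < best_key:
            best_key, best = key, d
    if best is None:
        raise InfeasibleDesignError(
            f"no design with nt <= {n_max} attains alpha={alpha}, beta={beta} "
            f"for pi0={pi0}, pi1={pi1}"
        )
    return best
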