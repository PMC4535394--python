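"""Likelihood-ratio ordering of the two-stage sample space: mid-p values
and acceptance-region confidence intervals.

Each path (m, s) is ranked by the likelihood ratio of the hypothesized
rate against the path's own MLE; larger ratios are more extreme evidence
against the null.  The mid-p value sums the null probability of strictly
more extreme paths plus half the probability of the observed path, which
corrects the conservatism the discreteness of the binomial sample space
would otherwise cause.  Inverting the acceptance region
``{pi0 : p(pi0) >= alpha}`` gives a confidence interval.

Unlike the conditional (Koyama-Chen) approach, this ordering is defined on
every path — including a stage-1 count already above the final boundary,
and a second stage with zero responders.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .design import SimonDesign, TrialOutcome, log_pmf_coefficient, support_paths
from .estimation import ConfidenceInterval
from .exceptions import Simon2StageError

__all__ = ["LRPValue", "lr_statistic", "lr_pvalue", "lr_ci", "lr_reject", "lr_ci_table"]

#: relative tolerance for declaring two log-likelihood-ratios tied
_TIE_RTOL = 1e-12
_GRID_SIZE = 2001
_EPS = 1e-10
_ROOT_TOL = 1e-9


@dataclass(frozen=True)
class LRPValue:
    """A mid-p value under the likelihood-ratio ordering."""

    value: float
    pi0: float
    t_observed: float
    n_strict: int
    warnings: tuple[str, ...] = ()


@lru_cache(maxsize=512)
class _Support:
    """Vectorized arrays over the (M, S_M) support at one stage-2 size."""

    def __init__(self, design: SimonDesign, n2_actual: int):
        self.design = design
        self.n2_actual = n2_actual
        self.paths = support_paths(design, n2_actual)
        self.index = {p: i for i, p in enumerate(self.paths)}
        self.m = np.array([m for m, _ in self.paths])
        self.s = np.array([s for _, s in self.paths], dtype=float)
        self.n = np.where(self.m == 1, design.n1, design.n1 + n2_actual).astype(float)
        self.logc = np.array(
            [log_pmf_coefficient(design, n2_actual, m, s) for m, s in self.paths]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ph = self.s / self.n
            self.loglik_hat = np.where(self.s > 0, self.s * np.log(ph), 0.0) + np.where(
                self.n - self.s > 0, (self.n - self.s) * np.log1p(-ph), 0.0
            )

    def log_pmf(self, pi0):
        """log f(m, s | pi0); pi0 may be a scalar or a grid (broadcast)."""
        pi0 = np.asarray(pi0, dtype=float)
        s = self.s[:, None] if pi0.ndim else self.s
        n = self.n[:, None] if pi0.ndim else self.n
        logc = self.logc[:, None] if pi0.ndim else self.logc
        return logc + s * np.log(pi0) + (n - s) * np.log1p(-pi0)

    def log_t(self, pi0):
        """log T(m, s, pi0): observed-MLE log-likelihood minus null's."""
        pi0 = np.asarray(pi0, dtype=float)
        s = self.s[:, None] if pi0.ndim else self.s
        n = self.n[:, None] if pi0.ndim else self.n
        llhat = self.loglik_hat[:, None] if pi0.ndim else self.loglik_hat
        return llhat - (s * np.log(pi0) + (n - s) * np.log1p(-pi0))


def _check_pi0(pi0: float) -> None:
    if not (0.0 < pi0 < 1.0):
        raise ValueError(f"pi0 must lie strictly inside (0, 1), got {pi0}")


def lr_statistic(m: int, s: int, n_total: int, pi0: float) -> float:
    """Likelihood ratio T of the path's MLE against the null rate.

    Computed in log space; T >= 1 always, with T = 1 exactly when the
    path's MLE equals the null rate.  The 0^0 = 1 convention applies at
    the boundaries s = 0 and s = n.
    """
    _check_pi0(pi0)
    if not (0 <= s <= n_total):
        raise ValueError(f"need 0 <= s <= n_total, got s={s}, n_total={n_total}")
    return float(np.exp(_log_lr(s, n_total, pi0)))


def _log_lr(s: int, n: int, pi0: float) -> float:
    ph = s / n
    llhat = (s * np.log(ph) if s else 0.0) + ((n - s) * np.log1p(-ph) if n - s else 0.0)
    return llhat - (s * np.log(pi0) + (n - s) * np.log1p(-pi0))


def _tie_tol(log_t_obs: float) -> float:
    return _TIE_RTOL * max(1.0, abs(log_t_obs))


def lr_pvalue(outcome: TrialOutcome, design: SimonDesign, pi0: float,
              symmetric_ties: bool = False, n2_actual: int | None = None) -> LRPValue:
    """Mid-p value of the observed path under the LR ordering.

    Sums the null probability of paths with strictly larger likelihood
    ratio plus half the observed path's probability.  With
    ``symmetric_ties=True``, non-observed paths whose ratio ties the
    observed one (to relative log-space tolerance 1e-12) also contribute
    half their mass; by default they contribute nothing.

    For a stage-1 stop the stage-2 part of the support is enumerated at
    the planned size unless ``n2_actual`` overrides it; for stage-2
    outcomes the realized size of the outcome is always used.
    """
    _check_pi0(pi0)
    outcome.validate(design)
    if outcome.m == 2:
        n2_actual = outcome.n2_actual
    elif n2_actual is None:
        n2_actual = design.n2
    sup = _Support(design, n2_actual)
    obs = sup.index[(outcome.m, outcome.s)]
    log_t = sup.log_t(pi0)
    f = np.exp(sup.log_pmf(pi0))
    tol = _tie_tol(log_t[obs])
    strict = log_t > log_t[obs] + tol
    strict[obs] = False
    value = float(f[strict].sum() + 0.5 * f[obs])
    warn: tuple[str, ...] = ()
    if symmetric_ties:
        tied = np.abs(log_t - log_t[obs]) <= tol
        tied[obs] = False
        if tied.any():
            value += 0.5 * float(f[tied].sum())
            warn = ("symmetric mid-p: non-observed tied paths given half mass",)
    return LRPValue(value=value, pi0=pi0, t_observed=float(np.exp(log_t[obs])),
                    n_strict=int(strict.sum()), warnings=warn)


def lr_reject(outcome: TrialOutcome, design: SimonDesign, pi0: float, alpha: float) -> bool:
    """Reject the null when the mid-p value is at most ``alpha``."""
    return lr_pvalue(outcome, design, pi0).value <= alpha


def _pvalue_grid(sup: _Support, grid: np.ndarray) -> np.ndarray:
    """Mid-p values for every path at every grid rate: (paths, grid)."""
    log_t = sup.log_t(grid)            # (P, G)
    f = np.exp(sup.log_pmf(grid))      # (P, G)
    tol = _TIE_RTOL * np.maximum(1.0, np.abs(log_t))
    strict = log_t[:, None, :] > (log_t + tol)[None, :, :]   # (path, obs, grid)
    p = np.einsum("pg,pog->og", f, strict) + 0.5 * f
    return p


def _refine_boundary(pfun, lo: float, hi: float, alpha: float) -> float:
    """Bisection for the acceptance-region edge bracketed in [lo, hi]."""
    flo = pfun(lo) - alpha
    fhi = pfun(hi) - alpha
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:   # no sign change at grid resolution; keep inner edge
        return hi if flo < 0 else lo
    return float(brentq(lambda q: pfun(q) - alpha, lo, hi, xtol=_ROOT_TOL))


def _region_to_ci(grid: np.ndarray, pvals: np.ndarray, alpha: float, level: float,
                  pfun) -> ConfidenceInterval:
    inside = np.flatnonzero(pvals >= alpha)
    if inside.size == 0:
        raise Simon2StageError("empty acceptance region — this indicates a bug")
    warnings: list[str] = []
    runs = np.flatnonzero(np.diff(inside) > 1)
    if runs.size:
        warnings.append("non-contiguous acceptance region; convex hull returned")
    i0, i1 = inside[0], inside[-1]
    if i0 == 0:
        lower = 0.0
    else:
        lower = _refine_boundary(pfun, grid[i0 - 1], grid[i0], alpha)
    if i1 == grid.size - 1:
        upper = 1.0
    else:
        upper = _refine_boundary(pfun, grid[i1], grid[i1 + 1], alpha)
    return ConfidenceInterval(lower=min(max(lower, 0.0), 1.0),
                              upper=min(max(upper, 0.0), 1.0),
                              level=level, method="LR-acceptance",
                              warnings=tuple(warnings))


def _scan_grid(extra: float | None = None) -> np.ndarray:
    grid = np.linspace(_EPS, 1.0 - _EPS, _GRID_SIZE)
    if extra is not None and 0.0 < extra < 1.0:
        grid = np.unique(np.concatenate([grid, [extra]]))
    return grid


def lr_ci(outcome: TrialOutcome, design: SimonDesign, level: float = 0.90,
          symmetric_ties: bool = False, n2_actual: int | None = None) -> ConfidenceInterval:
    """Confidence interval by inverting the mid-p acceptance region.

    The region ``{pi0 : p(pi0) >= 1 - level}`` is bracketed on a uniform
    grid of 2001 null rates and each edge refined by bisection.  If the
    region is non-contiguous (rare), its convex hull is returned with a
    warning attached.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    outcome.validate(design)
    alpha = 1.0 - level
    if outcome.m == 2:
        n2_actual = outcome.n2_actual
    elif n2_actual is None:
        n2_actual = design.n2
    sup = _Support(design, n2_actual)
    obs = sup.index[(outcome.m, outcome.s)]
    mle = outcome.s / outcome.n_enrolled(design)
    grid = _scan_grid(extra=mle)
    with np.errstate(divide="ignore"):
        pvals = _pvalue_grid(sup, grid)[obs]

    def pfun(pi0: float) -> float:
        return lr_pvalue(outcome, design, pi0, symmetric_ties=symmetric_ties,
                         n2_actual=n2_actual).value

    return _region_to_ci(grid, pvals, alpha, level, pfun)


def lr_pvalue_table(design: SimonDesign, n2_actual: int, pi0: float
                    ) -> dict[tuple[int, int], float]:
    """Mid-p values for every support path at one null rate (vectorized)."""
    _check_pi0(pi0)
    sup = _Support(design, n2_actual)
    log_t = sup.log_t(pi0)
    f = np.exp(sup.log_pmf(pi0))
    out: dict[tuple[int, int], float] = {}
    for i, path in enumerate(sup.paths):
        tol = _tie_tol(log_t[i])
        strict = log_t > log_t[i] + tol
        strict[i] = False
        out[path] = float(f[strict].sum() + 0.5 * f[i])
    return out


def lr_ci_table(design: SimonDesign, n2_actual: int, level: float = 0.90
                ) -> dict[tuple[int, int], ConfidenceInterval]:
    """Acceptance-region CIs for every support path at one stage-2 size.

    The grid stage is shared across paths (one vectorized pass), which
    makes repeated use in simulation loops cheap.
    """
    alpha = 1.0 - level
    sup = _Support(design, n2_actual)
    grid = _scan_grid()
    with np.errstate(divide="ignore"):
        pmat = _pvalue_grid(sup, grid)
    out: dict[tuple[int, int], ConfidenceInterval] = {}
    for i, (m, s) in enumerate(sup.paths):
        def pfun(pi0: float, _i=i) -> float:
            lt = sup.log_t(pi0)
            f = np.exp(sup.log_pmf(pi0))
            tol = _tie_tol(lt[_i])
            strict = lt > lt[_i] + tol
            strict[_i] = False
            return float(f[strict].sum() + 0.5 * f[_i])

        out[(m, s)] = _region_to_ci(grid, pmat[i], alpha, level, pfun)
    return out
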