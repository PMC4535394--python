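"""Monte Carlo study of the inference methods under stage-2 size deviation.

Trials are simulated under a Simon design at a chosen true response rate.
Trials that pass the interim draw their realized stage-2 size uniformly
from a window around the planned size (by default every integer from
``ceil(n2/3)`` to ``floor(1.5 * n2)``), emulating non-informative
extension or shortening, and then draw stage-2 responses at that size.

For each (true rate, method) cell the study reports the mean confidence
interval width among trials that reached stage 2, coverage and bias over
all trials, and the rejection rate ("actual power") at the design's null
rate.  All per-outcome inference is cached, so the cost scales with the
number of distinct observed outcomes rather than the replicate count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimation, kc, lr
from .design import SimonDesign, TrialOutcome, enumerate_paths, pmf, reject_h0
from .exceptions import ConfigurationError, KCUndefinedError

__all__ = [
    "SimulationConfig",
    "default_n2_support",
    "draw_n2_actual",
    "draw_trial",
    "run_study",
    "export_tables",
    "exact_lr_coverage",
]

_COLUMNS = [
    "design_id", "pi_true", "method", "width", "coverage_pct", "power_pct",
    "abs_bias", "n_stage2", "n_kc_failures", "signed_bias", "n_trials",
]


def default_n2_support(design: SimonDesign) -> list[int]:
    """Integers from ceil(n2/3) to floor(1.5 n2) inclusive."""
    lo = math.ceil(design.n2 / 3)
    hi = math.floor(1.5 * design.n2)
    return list(range(lo, hi + 1))


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one design's Monte Carlo study."""

    design: SimonDesign
    pi_grid: tuple[float, ...]
    reps: int = 5000
    level: float = 0.90
    alpha_test: float = 0.05
    n2_support: tuple[int, ...] | None = None
    seed: int = 0
    methods: tuple[str, ...] = ("LR", "KC")
    kc_power_rule: str = "conditional"   # or "pvalue"
    design_id: str | None = None

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")
        if not self.pi_grid or not all(0.0 <= p <= 1.0 for p in self.pi_grid):
            raise ConfigurationError("pi_grid must be nonempty with rates in [0, 1]")
        if self.n2_support is not None and len(self.n2_support) == 0:
            raise ConfigurationError("n2_support must be nonempty")
        if self.kc_power_rule not in ("conditional", "pvalue"):
            raise ConfigurationError("kc_power_rule must be 'conditional' or 'pvalue'")
        for m in self.methods:
            if m not in ("LR", "KC", "UMVUE-ordering"):
                raise ConfigurationError(f"unknown method {m!r}")

    def resolved_support(self) -> list[int]:
        if self.n2_support is not None:
            sup = sorted(set(int(v) for v in self.n2_support))
            if any(v < 1 for v in sup):
                raise ConfigurationError("n2_support entries must be positive")
            return sup
        return default_n2_support(self.design)

    def label(self) -> str:
        d = self.design
        return self.design_id or f"({d.r1},{d.n1},{d.rt},{d.nt})"


def draw_n2_actual(design: SimonDesign, rng: np.random.Generator,
                   n2_support: list[int] | None = None) -> int:
    """Uniform draw of the realized stage-2 size."""
    support = n2_support if n2_support is not None else default_n2_support(design)
    if not support:
        raise ConfigurationError("empty n2 support")
    return int(support[rng.integers(0, len(support))])


def draw_trial(design: SimonDesign, pi: float, rng: np.random.Generator,
               n2_support: list[int] | None = None) -> TrialOutcome:
    """Simulate one trial: interim stop or a stage-2 completion."""
    x1 = int(rng.binomial(design.n1, pi))
    if x1 <= design.r1:
        return TrialOutcome(m=1, x1=x1)
    n2_actual = draw_n2_actual(design, rng, n2_support)
    x2 = int(rng.binomial(n2_actual, pi))
    return TrialOutcome(m=2, x1=x1, x2=x2, n2_actual=n2_actual)


class _MethodCache:
    """Per-design lazy caches of estimate/CI/p-value for distinct outcomes."""

    def __init__(self, design: SimonDesign, level: float, pi0: float | None,
                 alpha: float, kc_power_rule: str):
        self.design = design
        self.level = level
        self.pi0 = pi0
        self.alpha = alpha
        self.kc_power_rule = kc_power_rule
        self._lr_ci: dict[int, dict] = {}
        self._lr_p: dict[int, dict] = {}
        self._uo_ci: dict[tuple[int, int, int], object] = {}
        self._kc: dict[tuple, tuple] = {}

    # ---- LR ----------------------------------------------------------
    def lr_ci(self, outcome: TrialOutcome):
        n2s = self.design.n2 if outcome.m == 1 else outcome.n2_actual
        tab = self._lr_ci.get(n2s)
        if tab is None:
            tab = lr.lr_ci_table(self.design, n2s, self.level)
            self._lr_ci[n2s] = tab
        return tab[(outcome.m, outcome.s)]

    def lr_rejects(self, outcome: TrialOutcome) -> bool:
        if self.pi0 is None:
            raise ConfigurationError("power computation requires pi0")
        n2s = self.design.n2 if outcome.m == 1 else outcome.n2_actual
        tab = self._lr_p.get(n2s)
        if tab is None:
            tab = lr.lr_pvalue_table(self.design, n2s, self.pi0)
            self._lr_p[n2s] = tab
        return tab[(outcome.m, outcome.s)] <= self.alpha

    # ---- UMVUE ordering ---------------------------------------------
    def umvue_ci(self, outcome: TrialOutcome):
        n2s = self.design.n2 if outcome.m == 1 else outcome.n2_actual
        key = (outcome.m, outcome.s, n2s)
        ci = self._uo_ci.get(key)
        if ci is None:
            ci = estimation.umvue_order_ci(outcome, self.design, self.level)
            self._uo_ci[key] = ci
        return ci

    def umvue_ordering_rejects(self, outcome: TrialOutcome) -> bool:
        """One-sided ordering tail P(UMVUE >= observed | pi0) <= alpha."""
        if self.pi0 is None:
            raise ConfigurationError("power computation requires pi0")
        n2s = self.design.n2 if outcome.m == 1 else outcome.n2_actual
        obs = estimation.umvue_fraction(outcome, self.design)
        return estimation._ordering_tail(self.design, n2s, obs, self.pi0) <= self.alpha

    # ---- KC ----------------------------------------------------------
    def kc_fit(self, outcome: TrialOutcome):
        """(estimate, ci) or None when the method is undefined (x1 > rt)."""
        key = (outcome.m, outcome.x1, outcome.x2, outcome.n2_actual)
        if key not in self._kc:
            try:
                est = kc.kc_estimate(outcome, self.design).value
                ci = kc.kc_ci(outcome, self.design, self.level)
                self._kc[key] = (est, ci)
            except KCUndefinedError:
                self._kc[key] = None
        return self._kc[key]

    def kc_rejects(self, outcome: TrialOutcome) -> bool:
        if self.pi0 is None:
            raise ConfigurationError("power computation requires pi0")
        if self.kc_power_rule == "conditional":
            return reject_h0(self.design, outcome, self.pi0)
        if outcome.m == 1:
            return kc.stage1_pvalue(outcome.x1, self.design.n1, self.pi0) <= self.alpha
        try:
            return kc.kc_pvalue(outcome, self.design, self.pi0).p_value <= self.alpha
        except KCUndefinedError:
            # x1 > rt guarantees s > rt: the design's own rule rejects
            return True


def _summarize_method(method: str, outcomes: list[TrialOutcome], pi: float,
                      cache: _MethodCache, estimates_umvue: list[float]) -> dict:
    design = cache.design
    ests: list[float] = []
    covered: list[bool] = []
    widths: list[float] = []
    rejects = 0
    n_fail = 0
    for i, o in enumerate(outcomes):
        if method == "KC":
            if o.m == 1:
                est = o.x1 / design.n1
                ci = kc.kc_ci(o, design, cache.level)
            else:
                fit = cache.kc_fit(o)
                if fit is None:
                    n_fail += 1
                    if cache.kc_rejects(o):
                        rejects += 1
                    continue
                est, ci = fit
            if cache.kc_rejects(o):
                rejects += 1
        else:
            est = estimates_umvue[i]
            if method == "LR":
                ci = cache.lr_ci(o)
                if cache.lr_rejects(o):
                    rejects += 1
            else:  # UMVUE-ordering
                ci = cache.umvue_ci(o)
                if cache.umvue_ordering_rejects(o):
                    rejects += 1
        ests.append(est)
        covered.append(ci.contains(pi))
        if o.m == 2:
            widths.append(ci.width)
    n_eval = len(ests)
    signed = (float(np.mean(ests)) - pi) if n_eval else float("nan")
    return {
        "method": method,
        "width": float(np.mean(widths)) if widths else float("nan"),
        "coverage_pct": 100.0 * float(np.mean(covered)) if covered else float("nan"),
        "power_pct": 100.0 * rejects / len(outcomes),
        "abs_bias": abs(signed),
        "signed_bias": signed,
        "n_stage2": sum(1 for o in outcomes if o.m == 2),
        "n_kc_failures": n_fail,
        "n_trials": len(outcomes),
    }


def run_study(config: SimulationConfig) -> pd.DataFrame:
    """Run the Monte Carlo study for one design over its rate grid.

    Returns one row per (true rate, method).  All methods see the same
    simulated trials; results are deterministic given the seed.
    """
    design = config.design
    support = config.resolved_support()
    pi0 = design.pi0
    rows = []
    for i_pi, pi in enumerate(config.pi_grid):
        rng = np.random.default_rng([config.seed, i_pi])
        x1s = rng.binomial(design.n1, pi, size=config.reps)
        outcomes: list[TrialOutcome] = []
        for x1 in x1s:
            if x1 <= design.r1:
                outcomes.append(TrialOutcome(m=1, x1=int(x1)))
            else:
                n2s = int(support[rng.integers(0, len(support))])
                x2 = int(rng.binomial(n2s, pi))
                outcomes.append(TrialOutcome(m=2, x1=int(x1), x2=x2, n2_actual=n2s))
        cache = _MethodCache(design, config.level, pi0, config.alpha_test,
                             config.kc_power_rule)
        umvues = [float(estimation.umvue_fraction(o, design)) for o in outcomes]
        for method in config.methods:
            row = _summarize_method(method, outcomes, pi, cache, umvues)
            row["design_id"] = config.label()
            row["pi_true"] = pi
            rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS)


def export_tables(summaries: pd.DataFrame, destination: str | Path,
                  stem: str = "simulation") -> list[Path]:
    """Write the summary table as CSV and JSON; returns the paths."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    csv_path = dest / f"{stem}.csv"
    json_path = dest / f"{stem}.json"
    df = summaries[_COLUMNS] if all(c in summaries.columns for c in _COLUMNS) else summaries
    df.to_csv(csv_path, index=False)
    df.to_json(json_path, orient="records", indent=1)
    return [csv_path, json_path]


def exact_lr_coverage(design: SimonDesign, pi: float, level: float = 0.90,
                      n2_support: list[int] | None = None) -> float:
    """Exact coverage of the LR acceptance-region CI, by full enumeration.

    Averages, over the uniform stage-2-size distribution and every sample
    path, the indicator that the path's CI contains the true rate.  The
    stage-1 part of the support does not depend on the realized stage-2
    size, so it is evaluated once at the planned size.
    """
    support = n2_support if n2_support is not None else default_n2_support(design)
    cov = 0.0
    planned_tab = lr.lr_ci_table(design, design.n2, level)
    for s in range(0, design.r1 + 1):
        cov += pmf(design, design.n2, 1, s, pi) * planned_tab[(1, s)].contains(pi)
    w = 1.0 / len(support)
    for n2s in support:
        tab = lr.lr_ci_table(design, n2s, level)
        dist = enumerate_paths(design, n2s, pi)
        for (m, s), prob in zip(dist.paths, dist.probabilities):
            if m == 2:
                cov += w * float(prob) * tab[(m, s)].contains(pi)
    return cov
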