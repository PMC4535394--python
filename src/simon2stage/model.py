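"""Model/Results facade over the exact-inference routines.

``TwoStageModel`` pairs a Simon two-stage design with one observed trial;
``fit`` runs the requested inference methods and returns a
``TwoStageResults`` object carrying the point estimates, confidence
intervals, p-values and diagnostics, with a ``summary()`` table in the
style of statsmodels results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import pandas as pd

from . import estimation, kc, lr
from .design import SimonDesign, TrialOutcome, reject_h0
from .exceptions import ConfigurationError, KCUndefinedError

__all__ = ["TwoStageModel", "TwoStageResults"]

_METHOD_ALIASES = {
    "umvue": "UMVUE-ordering", "umvue-ordering": "UMVUE-ordering",
    "lr": "LR", "kc": "KC", "mle": "MLE",
}


@dataclass(frozen=True)
class MethodRecord:
    """One method's inference output for one trial."""

    method: str
    estimate: float | None
    ci_lower: float | None
    ci_upper: float | None
    level: float
    p_value: float | None
    pi0: float | None
    pi_star: float | None = None
    degenerate_flag: str = "none"
    error: str | None = None
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method, "estimate": self.estimate,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "level": self.level, "p_value": self.p_value, "pi0": self.pi0,
            "pi_star": self.pi_star, "degenerate_flag": self.degenerate_flag,
            "error": self.error, "warnings": list(self.warnings),
        }


class TwoStageModel:
    """Exact inference for one Simon two-stage trial outcome.

    Parameters
    ----------
    design : SimonDesign
        The planned design (boundaries and planned sizes).
    outcome : TrialOutcome
        The observed sample path, carrying the realized stage-2 size.

    Examples
    --------
    >>> design = SimonDesign(r1=3, n1=19, rt=8, nt=39, pi0=0.15)
    >>> model = TwoStageModel.from_counts(design, x1=8, x2=4, n2_actual=6)
    >>> res = model.fit(level=0.90)
    >>> round(res.estimates["UMVUE-ordering"], 2)
    0.48
    """

    def __init__(self, design: SimonDesign, outcome: TrialOutcome):
        outcome.validate(design)
        self.design = design
        self.outcome = outcome

    @classmethod
    def from_counts(cls, design: SimonDesign, x1: int, x2: int | None = None,
                    n2_actual: int | None = None) -> "TwoStageModel":
        """Build from raw counts; infers the stopping stage from ``x1``."""
        if x1 <= design.r1:
            if x2 is not None:
                raise ConfigurationError(
                    f"x1={x1} <= r1={design.r1} stops at stage 1; x2 must be absent"
                )
            outcome = TrialOutcome(m=1, x1=x1)
        else:
            if x2 is None:
                raise ConfigurationError(
                    f"x1={x1} > r1={design.r1} continues to stage 2; x2 is required"
                )
            outcome = TrialOutcome(m=2, x1=x1, x2=x2,
                                   n2_actual=n2_actual if n2_actual is not None else design.n2)
        return cls(design, outcome)

    def fit(self, pi0: float | None = None, level: float = 0.90,
            methods: Sequence[str] = ("umvue", "lr", "kc")) -> "TwoStageResults":
        """Run the requested inference methods.

        ``pi0`` defaults to the design's planning null rate; it is needed
        for p-values but not for estimates or confidence intervals.
        """
        pi0 = pi0 if pi0 is not None else self.design.pi0
        records: list[MethodRecord] = []
        for raw in methods:
            name = _METHOD_ALIASES.get(raw.lower())
            if name is None:
                raise ValueError(f"unknown method {raw!r}")
            records.append(self._fit_one(name, pi0, level))
        return TwoStageResults(self, pi0, level, tuple(records))

    def _fit_one(self, name: str, pi0: float | None, level: float) -> MethodRecord:
        design, outcome = self.design, self.outcome
        if name == "MLE":
            est = estimation.mle(outcome, design)
            return MethodRecord(name, est.value, None, None, level, None, pi0)
        if name == "UMVUE-ordering":
            est = estimation.umvue(outcome, design)
            ci = estimation.umvue_order_ci(outcome, design, level)
            return MethodRecord(name, est.value, ci.lower, ci.upper, level,
                                None, pi0, warnings=ci.warnings)
        if name == "LR":
            est = estimation.umvue(outcome, design)
            ci = lr.lr_ci(outcome, design, level)
            p = None
            if pi0 is not None:
                if outcome.m == 1:
                    p = kc.stage1_pvalue(outcome.x1, design.n1, pi0)
                else:
                    p = lr.lr_pvalue(outcome, design, pi0).value
            return MethodRecord(name, est.value, ci.lower, ci.upper, level,
                                p, pi0, warnings=ci.warnings)
        # KC
        try:
            est = kc.kc_estimate(outcome, design)
            ci = kc.kc_ci(outcome, design, level)
        except KCUndefinedError as exc:
            return MethodRecord(name, None, None, None, level, None, pi0,
                                degenerate_flag=exc.flag, error=str(exc))
        p = pi_star = None
        flag = "none"
        warn: tuple[str, ...] = ()
        if pi0 is not None:
            if outcome.m == 1:
                p = kc.stage1_pvalue(outcome.x1, design.n1, pi0)
            else:
                r = kc.kc_pvalue(outcome, design, pi0)
                p, pi_star, flag, warn = r.p_value, r.pi_star, r.degenerate_flag, r.warnings
        return MethodRecord(name, est.value, ci.lower, ci.upper, level, p, pi0,
                            pi_star=pi_star, degenerate_flag=flag, warnings=warn)


class TwoStageResults:
    """Inference results for one trial across one or more methods."""

    def __init__(self, model: TwoStageModel, pi0: float | None, level: float,
                 records: tuple[MethodRecord, ...]):
        self.model = model
        self.design = model.design
        self.outcome = model.outcome
        self.pi0 = pi0
        self.level = level
        self.records = records

    @property
    def estimates(self) -> dict[str, float | None]:
        return {r.method: r.estimate for r in self.records}

    @property
    def pvalues(self) -> dict[str, float | None]:
        return {r.method: r.p_value for r in self.records}

    def conf_int(self, method: str | None = None) -> dict[str, tuple[float | None, float | None]]:
        out = {r.method: (r.ci_lower, r.ci_upper) for r in self.records}
        if method is not None:
            key = _METHOD_ALIASES.get(method.lower(), method)
            return {key: out[key]}
        return out

    @property
    def rejects_h0(self) -> bool | None:
        """The design's own final decision rule (threshold / conditional)."""
        if self.pi0 is None and self.outcome.m == 2 and \
                self.outcome.n2_actual != self.design.n2:
            return None
        return reject_h0(self.design, self.outcome, self.pi0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.records])

    def summary(self) -> str:
        d, o = self.design, self.outcome
        lines = [
            "Simon two-stage exact inference",
            "=" * 64,
            f"Design: r1/n1 = {d.r1}/{d.n1}, rt/nt = {d.rt}/{d.nt} "
            f"(planned n2 = {d.n2})",
        ]
        if o.m == 1:
            lines.append(f"Outcome: stopped at stage 1 with x1 = {o.x1}")
        else:
            lines.append(
                f"Outcome: x1 = {o.x1}, x2 = {o.x2}, actual n2 = {o.n2_actual} "
                f"(s = {o.s}, n = {o.n_enrolled(d)})"
            )
        if self.pi0 is not None:
            lines.append(f"Null rate pi0 = {self.pi0}")
        lines.append("-" * 64)
        hdr = f"{'method':<16}{'estimate':>10}{'  CI':>14}{'p-value':>12}"
        lines.append(hdr + f"   ({self.level:.0%} CI)")
        for r in self.records:
            if r.error is not None:
                lines.append(f"{r.method:<16}{'—':>10}  undefined: {r.degenerate_flag}")
                continue
            ci = (f"({r.ci_lower:.3f}, {r.ci_upper:.3f})"
                  if r.ci_lower is not None else "—")
            pv = f"{r.p_value:.4g}" if r.p_value is not None else "—"
            est = f"{r.estimate:.3f}" if r.estimate is not None else "—"
            lines.append(f"{r.method:<16}{est:>10}{ci:>18}{pv:>12}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<TwoStageResults: {len(self.records)} methods>"
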