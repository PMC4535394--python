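"""Exception hierarchy for design, outcome and method-domain errors."""


class Simon2StageError(Exception):
    """Base class for all package-specific errors."""


class SupportError(Simon2StageError, ValueError):
    """A path (m, s) lies outside the sample space of the design."""


class InvalidOutcomeError(Simon2StageError, ValueError):
    """An observed outcome violates the design's sampling rules."""


class ConfigurationError(Simon2StageError, ValueError):
    """Missing or inconsistent configuration (e.g. no null rate supplied)."""


class InfeasibleDesignError(Simon2StageError, ValueError):
    """No design satisfies the requested error constraints."""


class KCUndefinedError(Simon2StageError, RuntimeError):
    """The Koyama-Chen procedure has no solution for this outcome.

    This happens when the stage-1 count already exceeds the final
    boundary (x1 > rt): the conditional rejection rate is identically 1,
    so the calibration equation for pi* has no root.
    """

    def __init__(self, message: str, flag: str = "x1_exceeds_rt"):
        super().__init__(message)
        self.flag = flag
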