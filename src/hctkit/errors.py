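"""Exception hierarchy for hctkit.

All input-contract violations are ValueError subclasses so callers that only
care about "bad input" can catch one type.
"""


class HctkitError(Exception):
    """Base class for all hctkit errors."""


class InvalidSpecificationError(HctkitError, ValueError):
    """A panel/noise/scenario specification violates its invariants."""


class DomainError(HctkitError, ValueError):
    """A numeric argument is outside the mathematical domain (e.g. HCT >= 100)."""


class ModelDomainError(HctkitError, ValueError):
    """The bias model evaluates outside its usable range (deviation >= 100%)."""


class InvalidCurveError(HctkitError, ValueError):
    """A standard curve is unusable for inversion (non-positive slope)."""


class DegenerateDesignError(HctkitError, ValueError):
    """The data cannot identify the requested fit (e.g. all x identical)."""


class ConvergenceError(HctkitError, RuntimeError):
    """Nonlinear fit failed to converge within the iteration budget."""

    def __init__(self, message: str, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class ConfigError(HctkitError, ValueError):
    """A scenario configuration is malformed or unrecognized."""


class StageFailure(HctkitError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
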