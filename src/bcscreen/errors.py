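"""Exception hierarchy for the model."""


class BcScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BcScreenError):
    """A configuration document is missing a required key or cannot be parsed."""


class ValidationError(BcScreenError, ValueError):
    """A parameter value violates its invariant (range, sign, ordering)."""


class DomainError(BcScreenError, ValueError):
    """An age, time or grid argument lies outside the model's domain."""


class ConsistencyError(BcScreenError, RuntimeError):
    """An internal state-occupancy invariant (mass, non-negativity) was violated."""


class DegenerateDistributionError(BcScreenError, ValueError):
    """A stage distribution cannot be formed (e.g. no symptomatic presentations)."""


class ConvergenceError(BcScreenError, RuntimeError):
    """Calibration failed to reach the requested tolerance."""

    def __init__(self, message: str, best_residual: float, best_probs=None):
        super().__init__(message)
        self.best_residual = best_residual
        self.best_probs = best_probs


class FitError(BcScreenError, RuntimeError):
    """A parametric distribution could not be matched to the requested quantiles."""

    def __init__(self, message: str, achieved_quantiles=None):
        super().__init__(message)
        self.achieved_quantiles = achieved_quantiles
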