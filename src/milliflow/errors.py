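"""Exception hierarchy shared across the pipeline stages."""


class MilliflowError(Exception):
    """Base class for all milliflow errors."""


class InvalidInputError(MilliflowError, ValueError):
    """An argument violates a precondition (non-positive size, bad flag...)."""


class DomainError(MilliflowError, ValueError):
    """A position falls outside the channel cross-section."""


class OcclusionError(MilliflowError, ValueError):
    """An effective-geometry reduction leaves no open channel."""


class IdentifiabilityError(MilliflowError):
    """The sampling design cannot constrain the requested free parameters."""


class FitConvergenceError(MilliflowError):
    """Nonlinear least squares failed to converge; carries the best iterate."""

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class FitWindowError(MilliflowError):
    """Too few usable points inside the requested fit window."""


class CalibrationError(MilliflowError, ValueError):
    """A calibration input is unusable (e.g. no quenching, non-monotone table)."""


class ThresholdUndefinedError(MilliflowError):
    """Threshold estimation needs both colonized and non-colonized records."""


class SchemaError(MilliflowError, ValueError):
    """A table does not match its declared column schema."""
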