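"""Exception hierarchy shared across the package."""


class NeutralCloneError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NeutralCloneError, ValueError):
    """Model parameters outside their admissible range (e.g. delta >= 1)."""


class DomainError(NeutralCloneError, ValueError):
    """A function argument outside the domain of the formula."""


class NumericalError(NeutralCloneError, RuntimeError):
    """Quadrature or other numerical procedure failed to converge."""


class SchemaError(NeutralCloneError, ValueError):
    """An input table is missing required columns."""


class InsufficientDataError(NeutralCloneError, ValueError):
    """Too few data points for the requested fit."""


class DegenerateFitError(NeutralCloneError, ValueError):
    """The design matrix of the fit has no variation."""


class EmptyCurveError(NeutralCloneError, ValueError):
    """No mutations inside the fitting window."""


class NoValidDeltaError(NeutralCloneError, ValueError):
    """The fitted spectrum coefficient is incompatible with delta in [0, 1)."""
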