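"""Exception hierarchy shared by all modules."""


class SoftjamError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SoftjamError, ValueError):
    """A physical parameter violates its domain (non-positive radius, ...)."""


class OutOfDomainError(SoftjamError, ValueError):
    """An evaluation point lies outside the model's domain (e.g. P = 0)."""


class SchemaError(SoftjamError, ValueError):
    """A data table does not match the expected column schema."""


class InsufficientDataError(SoftjamError, ValueError):
    """Too few usable points for the requested fit."""


class UnidentifiableError(SoftjamError, ValueError):
    """The design does not constrain the requested parameter (e.g. all
    concentrations far below the dissociation constant)."""


class FitConvergenceError(SoftjamError, RuntimeError):
    """A fit failed to converge after multi-start."""
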