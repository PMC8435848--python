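"""Exception hierarchy shared across the package."""


class DiadinoError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(DiadinoError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(DiadinoError):
    """Too few usable observations for the requested estimate."""


class FitFailureError(DiadinoError):
    """A numerical fit did not converge; carries diagnostics in ``args``."""


class UndefinedRatioError(DiadinoError):
    """A ratio index is undefined (zero denominator); callers may flag
    the index missing rather than propagate."""


class UndefinedInteractionError(DiadinoError):
    """An interaction coefficient is unidentifiable from the data
    (e.g. the partner species is absent at every usable time point)."""


class SchemaError(DiadinoError):
    """An input table or configuration violates the published schema."""
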