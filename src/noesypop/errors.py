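"""Exception hierarchy.

Every error raised by noesypop derives from :class:`NoesypopError` so callers
can catch the package's failures without masking programming errors.
"""


class NoesypopError(Exception):
    """Base class for all noesypop errors."""


class ParseError(NoesypopError):
    """A structure or table file could not be parsed; message names the line."""


class LookupLabelError(NoesypopError, KeyError):
    """An atom label or pair id is not present in the container."""


class DegenerateGeometryError(NoesypopError):
    """A geometric quantity is undefined for the given coordinates."""


class DomainError(NoesypopError, ValueError):
    """A numeric argument is outside the physically meaningful domain."""


class UnclassifiedConformerError(NoesypopError):
    """A conformer falls in the dead zone of a classification rule."""


class ConfigError(NoesypopError):
    """An analysis configuration is inconsistent or incomplete."""


class InsufficientDataError(NoesypopError):
    """Too few usable points remain for a fit."""

    def __init__(self, message: str, qc_flags: frozenset[str] = frozenset()):
        super().__init__(message)
        self.qc_flags = set(qc_flags)


class FitDegenerateError(NoesypopError):
    """The fit problem has no information (all points identical)."""


class MappingError(NoesypopError):
    """An atom map pairs incompatible atoms."""


class UnderdeterminedError(NoesypopError):
    """Too few (or collinear) mapped atoms for a rigid superposition."""


class UncertaintyUndefinedError(NoesypopError):
    """Every Monte-Carlo draw was infeasible; no spread can be reported."""
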