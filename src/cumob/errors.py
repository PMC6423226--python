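"""Exception hierarchy.

Every hard failure in the pipeline raises a subclass of :class:`CumobError`
so callers (and the CLI) can distinguish user-input problems from bugs.
"""


class CumobError(Exception):
    """Base class for all package errors."""


class SchemaError(CumobError):
    """Input table is missing a required column or is otherwise malformed."""


class ValidationError(CumobError):
    """Data violates a structural invariant (e.g. duplicate depths)."""


class UnitError(CumobError):
    """Unknown unit string or incompatible units in an operation."""


class ExtrapolationError(CumobError):
    """A depth outside the measured grid was requested."""


class CensoringError(CumobError):
    """An operation needs a quantified value at a censored point."""


class ZonationError(CumobError):
    """Zone detection failed (no epilimnetic points, empty zone, ...)."""


class ParameterError(CumobError):
    """A physical parameter is out of its valid domain."""


class WindowError(CumobError):
    """A regression window contains too few usable points."""


class SampleSizeError(CumobError):
    """Too few replicates for the requested statistic."""


class ConfigurationError(CumobError):
    """Inconsistent or incomplete run configuration."""


class CurveError(CumobError):
    """qPCR standard curve is invalid (e.g. non-negative slope)."""


class MappingError(CumobError):
    """A taxonomic group has no copy-number entry."""


class MissingInputError(CumobError):
    """A required pipeline input is absent."""
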