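"""Exception hierarchy.

Everything raised on bad *data* derives from :class:`ValidationError`
(CLI exit code 1); bad *configuration* derives from
:class:`ConfigurationError`.  Both share :class:`SynscavError`.
"""


class SynscavError(Exception):
    """Base class for all package errors."""


class ValidationError(SynscavError):
    """Input data violates a documented precondition."""


class ConfigurationError(SynscavError):
    """Unknown option value or inconsistent configuration."""


class BlankAbsorbanceError(ValidationError):
    """Blank (or denominator) absorbance is zero or negative."""


class ConsistencyError(ValidationError):
    """Readings that must share assay/concentration/role do not."""


class TableParseError(ValidationError):
    """Malformed dose-response or abundance table."""


class DegenerateDesignError(ValidationError):
    """All concentrations identical; a line cannot be fitted."""


class NoPositiveCrossingError(ValidationError):
    """Fitted line never crosses 50% at a positive concentration."""


class InsufficientDataError(ValidationError):
    """Too few points for the requested inference (no residual df)."""


class RatioError(ValidationError):
    """Mixture fractions do not form a valid interior composition."""


class EnvelopeUndefinedError(ValidationError):
    """Isobole confidence envelope cannot be built (infinite CI bound)."""


class NormalizationError(ValidationError):
    """A sample column cannot be normalized (all-zero)."""


class MissingPhylumError(ValidationError):
    """Required phylum row absent from the abundance table."""


class UndefinedCorrelationError(ValidationError):
    """Correlation undefined (constant input vector)."""


class JoinError(ValidationError):
    """Tables share too few samples to be correlated."""
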