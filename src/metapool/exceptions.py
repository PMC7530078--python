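"""Exception hierarchy for metapool.

Everything raised by the package derives from :class:`MetaPoolError`, so
callers (in particular the CLI) can catch one type and print a diagnostic.
"""


class MetaPoolError(Exception):
    """Base class for all metapool errors."""


class SchemaError(MetaPoolError):
    """An input table is missing a required column or is not parseable."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class RecordValidationError(MetaPoolError):
    """A single study row violates a domain invariant."""

    def __init__(self, message: str, study_id: str | None = None):
        super().__init__(message)
        self.study_id = study_id


class DegenerateIntervalError(MetaPoolError):
    """A confidence interval with zero width cannot yield a variance."""


class EmptyEvidenceError(MetaPoolError):
    """A pooling operation received no studies."""


class InsufficientStudiesError(MetaPoolError):
    """An operation needs more studies than were supplied (e.g. tau^2 with k<2)."""


class TruncationError(MetaPoolError):
    """Too much tau posterior mass sits at the grid's upper edge.

    Raised with a suggestion to enlarge ``tau_max``; also the propriety
    guard for the improper Jeffreys prior with very few studies.
    """


class ConfigError(MetaPoolError):
    """A simulation or scenario configuration is invalid."""
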