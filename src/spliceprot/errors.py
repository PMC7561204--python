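"""Exception types raised across the pipeline."""


class SpliceprotError(Exception):
    """Base class for all package errors."""


class ValidationError(SpliceprotError, ValueError):
    """An input table or value violates its declared schema."""


class SchemaError(ValidationError):
    """A tissue, group or unit is not part of the active tissue schema."""


class UndeterminedSidesError(SpliceprotError):
    """Main/alternative cannot be assigned because both sides have zero evidence."""


class InsufficientGroupsError(SpliceprotError):
    """Standardisation across tissue groups needs at least two groups."""


class UndefinedSupportError(SpliceprotError):
    """Percent support is undefined because the side total is zero."""


class UndefinedCorrelationError(SpliceprotError):
    """Correlation is undefined (constant vector or too few points)."""


class IncompleteInputError(SpliceprotError):
    """A required region or table for this event kind was not supplied."""


class ConfigError(SpliceprotError, ValueError):
    """Simulation or pipeline configuration is invalid."""
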