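"""Exception hierarchy for cohort validation, chart lookups and model fitting."""


class MetsprogError(Exception):
    """Base class for all package errors."""


class SchemaError(MetsprogError):
    """A table is missing mandatory columns or has the wrong layout."""


class IntegrityError(MetsprogError):
    """Duplicate or unpaired subject rows."""


class ValidationError(MetsprogError):
    """Row-level value violations (negative measurements, Tanner/stage mismatch...)."""


class CoverageError(MetsprogError, LookupError):
    """A chart lookup fell outside the configured sex/age/height coverage."""


class DomainError(MetsprogError, ValueError):
    """An argument is outside its mathematical domain."""


class ParameterError(MetsprogError, ValueError):
    """Invalid generator or cross-validation configuration."""


class NoAnalyzableSubjectsError(MetsprogError):
    """Every subject was removed by the exclusion filters."""


class DegenerateTestError(MetsprogError):
    """A statistical test cannot be computed (zero variance, single class...)."""


class StratificationError(MetsprogError):
    """Stratified folds cannot guarantee a positive case in every fold."""
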