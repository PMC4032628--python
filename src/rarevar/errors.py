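"""Exception hierarchy shared across the pipeline."""


class RarevarError(Exception):
    """Base class for all package errors."""


class SchemaError(RarevarError):
    """A required column is missing or mis-typed in an input table."""


class RowParseError(RarevarError):
    """A data row failed to parse; carries the offending 0-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class DuplicateRecordError(RarevarError):
    """Two records share the same (subject_id, pos, alt) identity."""


class LookupMissingError(RarevarError):
    """A variant is absent from a required lookup (e.g. allele counts)."""


class AnnotationError(RarevarError):
    """A conservation score is non-finite or otherwise unusable."""


class DomainError(RarevarError):
    """An argument is outside the operation's mathematical domain."""


class ConfigurationError(RarevarError):
    """An unknown profile, stage or configuration key was requested."""
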