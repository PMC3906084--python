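"""Exception hierarchy for snvcalib.

All package-specific failures derive from :class:`SnvCalibError` so callers
can catch one base class at pipeline boundaries.
"""


class SnvCalibError(Exception):
    """Base class for all snvcalib errors."""


class UsageError(SnvCalibError):
    """Invalid argument combination or unknown identifier (CLI exit code 2)."""


class ParseError(SnvCalibError):
    """A VCF or tabular input could not be parsed."""


class SchemaError(SnvCalibError):
    """A tabular input is missing a required column or role mapping."""


class TableValidationError(SnvCalibError):
    """Rows of a variant table violate record invariants.

    Carries the offending 1-based row numbers (header excluded) in
    ``self.rows``.
    """

    def __init__(self, rows, messages=None):
        self.rows = list(rows)
        self.messages = list(messages or [])
        detail = "; ".join(self.messages[:5])
        super().__init__(
            f"{len(self.rows)} row(s) violate record invariants "
            f"(rows {self.rows[:10]}{'...' if len(self.rows) > 10 else ''}): {detail}"
        )


class UndefinedMetricError(SnvCalibError):
    """A per-variant metric is undefined for the given record.

    Raised e.g. when the alternate-forward percentage is requested for a
    record with zero alternate-supporting reads, or a strand-bias value for
    a record lacking the caller-appropriate evidence.
    """


class EmptyProfileError(SnvCalibError):
    """No record in the input defines the requested metric."""


class DuplicateSiteError(SnvCalibError):
    """The same (chrom, pos, ref, alt) key appears twice within one call set."""

    def __init__(self, keys):
        self.keys = list(keys)
        super().__init__(f"duplicate variant keys within one call set: {self.keys[:10]}")


class InsufficientDataError(SnvCalibError):
    """A statistical check was requested on too small a cohort."""
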