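"""Exception hierarchy.

``ConfigError`` and ``DataError`` are the two top-level families the CLI
maps to distinct exit codes (2 and 3 respectively).
"""


class RadmutError(Exception):
    """Base class for all package errors."""


class ConfigError(RadmutError):
    """Invalid configuration (bad keys, out-of-range thresholds)."""


class DataError(RadmutError):
    """Invalid or inconsistent input data."""


class VcfParseError(DataError):
    """Malformed VCF content; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class OrphanBreakendError(DataError):
    """A breakend record whose MATEID partner is missing."""


class UnsupportedCategoryError(DataError):
    """A change with no category in the eight-way scheme (e.g. net insertion >= 100 bp)."""


class DegenerateFitError(DataError):
    """Survival data that cannot constrain the dose-response model."""
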