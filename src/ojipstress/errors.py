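"""Typed exceptions for the OJIP analysis pipeline.

Batch stages catch :class:`SampleError` subclasses per sample so that one
degenerate trace is skipped (and reported) instead of poisoning a whole run
with NaNs.
"""


class OjipError(Exception):
    """Base class for all pipeline errors."""


class TableFormatError(OjipError, ValueError):
    """An input table is missing a required column or is malformed."""


class TableParseError(OjipError, ValueError):
    """A cell could not be parsed; carries the offending 1-based row number."""

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
        self.row = row


class EmptyInputError(OjipError, ValueError):
    """An input table contains no data rows."""


class SampleError(OjipError, ValueError):
    """Base for per-sample failures that batch stages may skip."""


class CoverageError(SampleError):
    """The sampled time grid does not bracket a required marker time."""


class DegenerateTransientError(SampleError):
    """Markers admit no JIP analysis (e.g. F_m <= F_O or F_J <= F_O)."""


class InvalidMeasurementError(SampleError):
    """A quenching or assay measurement is physically impossible."""


class NormalizationError(OjipError, ValueError):
    """A control mean of zero makes control-relative scaling undefined."""


class InsufficientReplicatesError(OjipError, ValueError):
    """A significance test needs at least two replicates per group."""


class ConfigurationError(OjipError, ValueError):
    """The run configuration or preset collection is inconsistent."""


class InfeasibleTargetsError(OjipError, ValueError):
    """Requested JIP parameter targets admit no valid marker set."""
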