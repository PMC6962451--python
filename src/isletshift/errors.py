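"""Exception families shared across the package.

Each family maps to a distinct CLI exit code so shell callers can
discriminate bad input files from bad configuration from stage failures.
"""

from __future__ import annotations


class IsletShiftError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParseError(IsletShiftError):
    """A delimited file could not be parsed (non-numeric cell, bad extension...)."""

    exit_code = 3


class StructuralError(IsletShiftError):
    """Structurally invalid table: duplicate identifiers, missing columns."""

    exit_code = 4


class ValidationError(IsletShiftError):
    """Values violate a domain invariant (non-positive abundance, bad counts)."""

    exit_code = 5


class VocabularyError(IsletShiftError):
    """A label falls outside a closed vocabulary (condition names, formats)."""

    exit_code = 6


class ConsistencyError(IsletShiftError):
    """Two inputs that must agree do not (matrix vs annotation, deps vs contrast)."""

    exit_code = 7


class ConfigurationError(IsletShiftError):
    """A run or simulation configuration is invalid or infeasible."""

    exit_code = 8


class PipelineError(IsletShiftError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    exit_code = 9

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


class ReportingError(IsletShiftError):
    """A report was requested from an incomplete result bundle."""

    exit_code = 10
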