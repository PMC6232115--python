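"""Typed exceptions raised across the package.

Validation is total: malformed input raises one of these, never a silent
drop or a NaN propagated downstream.
"""


class MemtraceError(Exception):
    """Base class for all package errors."""


class SchemaError(MemtraceError):
    """A table is missing a required column or contains an unknown token."""


class IntegrityError(MemtraceError):
    """Cross-reference or internal-consistency violation in a study table."""


class VocabularyError(MemtraceError):
    """A content feature is not part of the declared feature vocabulary."""


class CalibrationError(MemtraceError):
    """A generator calibration target is outside the feasible range."""


class DegenerateInputError(MemtraceError):
    """Statistically degenerate input (e.g. zero variance in a t-test)."""


class ConfigurationError(MemtraceError):
    """An analysis was requested on data the study does not contain."""
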