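"""Exception hierarchy.

All package errors derive from :class:`AdrCauseError` so callers can catch one
type; concrete subclasses also derive from ``ValueError`` because they signal
bad inputs or parameters.
"""


class AdrCauseError(Exception):
    """Base class for all errors raised by adrcause."""


class InvalidInputError(AdrCauseError, ValueError):
    """Malformed data or invalid parameter values."""


class SegmentationError(AdrCauseError, ValueError):
    """Entity spans cannot be reconciled with token boundaries."""


class PatternError(AdrCauseError, ValueError):
    """Invalid skip-gram pattern or unparseable serialized pattern."""


class TrainingError(AdrCauseError, ValueError):
    """Degenerate training input (e.g. a single class)."""


class GenerationError(AdrCauseError, ValueError):
    """Synthetic corpus generation cannot satisfy its constraints."""


class ModelFormatError(AdrCauseError, ValueError):
    """Model file is corrupt or inconsistent."""
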