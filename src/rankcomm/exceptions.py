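"""Exception hierarchy for rankcomm.

Every user-facing failure mode raises a distinct, named error so callers
(and the CLI) can report the failing stage precisely.
"""


class RankCommError(Exception):
    """Base class for all rankcomm errors."""


class MissingFileError(RankCommError, FileNotFoundError):
    """A required input file or directory does not exist."""


class NegativeEntryError(RankCommError, ValueError):
    """A count matrix contains a negative entry."""


class NonIntegerEntryError(RankCommError, ValueError):
    """A count matrix contains a non-integral entry."""


class DuplicateGeneError(RankCommError, ValueError):
    """A count matrix declares the same gene identifier twice."""


class DuplicateBarcodeError(RankCommError, ValueError):
    """A barcode occurs more than once (counts or annotation)."""


class MalformedRowError(RankCommError, ValueError):
    """A delimited input row cannot be parsed; message carries the line number."""


class EmptyResultError(RankCommError, ValueError):
    """An operation produced an empty result where data is required."""


class NormalizationError(RankCommError, ValueError):
    """Normalization preconditions violated (e.g. single cell, zero library)."""


class ConfigError(RankCommError, ValueError):
    """A run configuration value is missing or out of range."""
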