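"""Exception hierarchy used across the package."""


class DroughtlightError(Exception):
    """Base class for all package errors."""


class ValidationError(DroughtlightError, ValueError):
    """Invalid parameter or malformed in-memory input."""


class CoverageError(DroughtlightError, ValueError):
    """A transient or curve does not span a required time range."""


class DegenerateTransientError(DroughtlightError, ValueError):
    """Fluorescence trace carries no variable fluorescence (FM <= F0)."""


class UndefinedParameterError(DroughtlightError, ValueError):
    """A JIP-test parameter is undefined for the given landmarks."""


class MemeParseError(DroughtlightError, ValueError):
    """Malformed MEME minimal motif file; message carries the line number."""


class FormatError(DroughtlightError, ValueError):
    """Malformed record in a tabular or sequence file."""
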