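"""Exception hierarchy shared across the toolkit.

Format-level problems (bad magic, CRC mismatch, truncation) are kept
distinct from usage-level problems (bad coordinates, unknown reference)
so the CLI can map them onto different exit codes.
"""


class AlnkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(AlnkitError):
    """The input bytes/text do not conform to the expected file format."""


class TruncationError(FormatError):
    """The input ended in the middle of a structure."""


class CorruptionError(FormatError):
    """Checksums or size fields disagree with the data."""


class ParseError(FormatError):
    """A text record could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class RangeError(AlnkitError, ValueError):
    """A numeric argument is outside its documented domain."""


class LookupMiss(AlnkitError, KeyError):
    """A reference/sequence name or id is unknown."""


class ValidationError(AlnkitError):
    """A record failed validation on a strict write path."""


class SortOrderError(AlnkitError):
    """Input that must be coordinate-sorted is not."""
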