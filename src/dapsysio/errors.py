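"""Typed error hierarchy.

Parsing is strict and fail-fast: every malformed input maps to a specific
:class:`FormatError` subclass, never to a partially populated structure.
"""


class DapsysError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(DapsysError):
    """A byte stream does not conform to the reference dialect."""


class BadMagic(FormatError):
    """The 4-byte magic tag at the start of the file is wrong."""


class TruncatedFile(FormatError):
    """The byte stream ended inside a structure."""


class UnknownPageKind(FormatError):
    """A page carries a kind tag that is neither waveform nor text."""


class EncodingError(FormatError):
    """A string cannot be encoded/decoded with the dialect codec (Latin-1)."""


class LengthMismatch(FormatError):
    """An irregular waveform page has differing timestamp/amplitude counts."""


class DanglingPageRef(FormatError):
    """A stream or page reference names a page id that does not exist."""


class DuplicateId(FormatError):
    """Two pages (or two ToC entries) share the same id."""


class TrailingData(FormatError):
    """Bytes remain after the footer; the file is longer than its structure."""


class InvariantViolation(DapsysError):
    """An in-memory structure violates a model invariant (write-side check)."""


class NotFound(DapsysError, LookupError):
    """A ToC path does not resolve to any entry."""


class AmbiguousPath(DapsysError):
    """A ToC path matches more than one entry (duplicate sibling names)."""


class NotRegular(DapsysError):
    """Regular-sampling operation applied to an irregularly sampled page."""


class KindMismatch(DapsysError):
    """A stream's type does not match the kind of its pages or the operation."""


class InvalidSpec(DapsysError, ValueError):
    """A synthetic session specification violates its invariants."""


class RowCountMismatch(DapsysError):
    """CSV row count differs from the number of binary samples compared."""


class CsvParseError(DapsysError):
    """A CSV row does not parse under the export dialect."""


class IOFailure(DapsysError):
    """An export could not be written to disk."""
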