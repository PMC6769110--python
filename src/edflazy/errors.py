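"""Exception hierarchy for the edflazy package."""


class EdfError(Exception):
    """Base class for all edflazy errors."""


class TruncatedHeaderError(EdfError):
    """Input ends before the declared header is complete."""


class FieldFormatError(EdfError):
    """A numeric header field does not parse as a number."""


class HeaderConsistencyError(EdfError):
    """Header fields contradict each other (e.g. header_bytes vs num_signals)."""


class StreamingFileError(EdfError):
    """num_records == -1: an unfinished streaming recording, unsupported."""


class FieldOverflowError(EdfError):
    """A text field does not fit its fixed byte width."""


class NonAsciiFieldError(EdfError):
    """A header field contains non-ASCII content."""


class EmptyRangeError(EdfError):
    """A time range is empty after clipping to the recording bounds."""


class ShortReadError(EdfError):
    """A loading strategy returned fewer bytes than requested."""


class RangeNotSupportedError(EdfError):
    """The HTTP server ignored the Range header and sent a full body."""


class StrategyError(EdfError):
    """A loading strategy failed to read."""


class TableFormatError(EdfError):
    """A harmonization table file is malformed or self-contradictory."""


class MappingConflictError(EdfError):
    """A pseudonym mapping import contradicts the existing store."""


class PseudonymCollisionError(EdfError):
    """Could not generate a fresh pseudonym within the retry budget."""


class EventError(EdfError):
    """Invalid event data or edit operation."""
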