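"""Exception hierarchy for speechgraph."""


class SpeechGraphError(Exception):
    """Base class for all speechgraph errors."""


class EmptyTranscriptError(SpeechGraphError):
    """Raised when a transcript or raw report contains no elements/words."""


class MarkupError(SpeechGraphError):
    """Raised on unbalanced or nested deviation-span markers."""


class InvalidLexemeError(SpeechGraphError):
    """Raised when a lexeme mapping produces an empty or malformed lexeme."""


class DuplicateSubjectError(SpeechGraphError):
    """Raised when a corpus metadata table repeats a subject id."""


class InvalidGroupError(SpeechGraphError):
    """Raised on a group label that cannot be interpreted."""


class MissingTranscriptError(SpeechGraphError):
    """Raised when a metadata row has no matching transcript file."""


class InvalidWordCountError(SpeechGraphError):
    """Raised when a word count is zero or negative."""


class InsufficientDataError(SpeechGraphError):
    """Raised when a classifier is trained with fewer than 2 rows per class."""


class UnknownFeatureError(SpeechGraphError):
    """Raised when a requested feature column is absent from a measure table."""
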