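"""Reading, validating and lexemizing annotated speech transcripts.

A transcript is a plain-text file holding the pre-parsed grammatical
elements of one interview report, in utterance order, separated by "/"
and/or whitespace.  Spans where the speaker deviated from the anchor
topic (e.g. commenting on waking life during a dream report) are wrapped
in square brackets::

    I / walked / I / found / I / hugged / [ I / woke ]

Every element is tagged either ``anchor`` or ``deviation``; the tagging
is binary and exhaustive.  Elements are canonical word forms (lexemes);
lexemization is table-driven via :func:`apply_lexeme_map` because the
node identity of the downstream graph is the lexeme, not the surface
form.  The raw word count of the original report is carried separately
from the element count: elements are parsed lexemes, words are raw
tokens, and the two routinely differ on real interviews.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import (
    DuplicateSubjectError,
    EmptyTranscriptError,
    InvalidGroupError,
    InvalidLexemeError,
    InvalidWordCountError,
    MarkupError,
    MissingTranscriptError,
)

__all__ = [
    "Segment",
    "Group",
    "Element",
    "Transcript",
    "SubjectRecord",
    "MarkupConfig",
    "parse_transcript",
    "serialize_transcript",
    "apply_lexeme_map",
    "count_words",
    "load_corpus",
]


class Segment(str, Enum):
    """Whether an element belongs to the anchor topic or deviates from it."""

    ANCHOR = "anchor"
    DEVIATION = "deviation"


class Group(str, Enum):
    """Diagnostic group of a subject."""

    SCHIZOPHRENIC = "schizophrenic"
    MANIC = "manic"
    CONTROL = "control"
    UNLABELED = "unlabeled"


_GROUP_ALIASES = {
    "schizophrenic": Group.SCHIZOPHRENIC,
    "schizophrenia": Group.SCHIZOPHRENIC,
    "s": Group.SCHIZOPHRENIC,
    "manic": Group.MANIC,
    "mania": Group.MANIC,
    "m": Group.MANIC,
    "control": Group.CONTROL,
    "c": Group.CONTROL,
    "unlabeled": Group.UNLABELED,
    "": Group.UNLABELED,
}


def parse_group(label: str, strict: bool = True) -> Group:
    """Map a free-form group label to a :class:`Group`.

    With ``strict=True`` an unrecognized label raises
    :class:`InvalidGroupError`; otherwise it is coerced to
    ``Group.UNLABELED`` so corpora from other study designs remain usable
    (group-wise statistics then simply ignore those subjects).
    """
    key = str(label).strip().lower()
    if key in ("nan", "none"):
        key = ""
    if key in _GROUP_ALIASES:
        return _GROUP_ALIASES[key]
    if strict:
        raise InvalidGroupError(f"unknown group label: {label!r}")
    return Group.UNLABELED


@dataclass(frozen=True)
class Element:
    """One parsed grammatical element (lexeme occurrence) of a transcript."""

    lexeme: str
    segment: Segment
    position: int

    def __post_init__(self) -> None:
        if not self.lexeme:
            raise InvalidLexemeError("lexeme must be a non-empty string")
        if any(ch.isspace() for ch in self.lexeme):
            raise InvalidLexemeError(f"lexeme contains whitespace: {self.lexeme!r}")


@dataclass
class Transcript:
    """An ordered element sequence plus subject metadata."""

    subject_id: str
    group: Group
    elements: list[Element]
    word_count: int

    def __post_init__(self) -> None:
        if not self.elements:
            raise EmptyTranscriptError("transcript has no elements")
        if self.word_count < 1:
            raise InvalidWordCountError(
                f"word_count must be >= 1, got {self.word_count}"
            )
        for expected, el in enumerate(self.elements):
            if el.position != expected:
                raise ValueError(
                    f"element positions must be consecutive from 0; "
                    f"got {el.position} at index {expected}"
                )

    @property
    def lexemes(self) -> list[str]:
        return [el.lexeme for el in self.elements]


@dataclass
class SubjectRecord:
    """One row of corpus metadata."""

    subject_id: str
    group: Group
    word_count: int
    bprs_total: Optional[float] = None
    panss_total: Optional[float] = None


@dataclass(frozen=True)
class MarkupConfig:
    """Markup conventions of the transcript file format.

    ``separator`` splits elements in addition to whitespace; deviation
    spans are delimited by ``open_marker``/``close_marker``.  Markers may
    stand alone or be glued to an element ("[I woke]" and "[ I woke ]"
    are equivalent).
    """

    open_marker: str = "["
    close_marker: str = "]"
    separator: str = "/"


DEFAULT_MARKUP = MarkupConfig()


def count_words(raw_report: str, config: MarkupConfig = DEFAULT_MARKUP) -> int:
    """Number of whitespace-delimited tokens in a raw report.

    Markup characters (span markers, element separators) are ignored, so
    the count is stable whether or not the report is annotated.
    """
    if raw_report is None or not raw_report.strip():
        raise EmptyTranscriptError("raw report is empty")
    cleaned = raw_report
    for ch in (config.open_marker, config.close_marker, config.separator):
        cleaned = cleaned.replace(ch, " ")
    tokens = cleaned.split()
    if not tokens:
        raise EmptyTranscriptError("raw report contains only markup")
    return len(tokens)


def _tokenize(text: str, config: MarkupConfig) -> list[str]:
    """Split on whitespace and the separator; detach glued markers."""
    spaced = text.replace(config.separator, " ")
    spaced = spaced.replace(config.open_marker, f" {config.open_marker} ")
    spaced = spaced.replace(config.close_marker, f" {config.close_marker} ")
    return spaced.split()


def parse_transcript(
    text: str,
    config: MarkupConfig = DEFAULT_MARKUP,
    subject_id: str = "",
    group: Group = Group.UNLABELED,
    word_count: Optional[int] = None,
) -> Transcript:
    """Parse an annotated element string into a :class:`Transcript`.

    Elements inside a marker span get ``segment=deviation``, all others
    ``anchor``.  Nested or unclosed markers raise :class:`MarkupError`;
    empty elements between separators are skipped with a warning.  If
    ``word_count`` is not supplied it is computed from ``text`` via
    :func:`count_words` (metadata-supplied counts take precedence in
    :func:`load_corpus`).
    """
    if text is None or not text.strip():
        raise EmptyTranscriptError("transcript text is empty")

    elements: list[Element] = []
    in_deviation = False
    position = 0
    for token in _tokenize(text, config):
        if token == config.open_marker:
            if in_deviation:
                raise MarkupError("nested deviation markers are not allowed")
            in_deviation = True
            continue
        if token == config.close_marker:
            if not in_deviation:
                raise MarkupError("close marker without matching open marker")
            in_deviation = False
            continue
        if not token:
            warnings.warn("skipping empty element between separators")
            continue
        segment = Segment.DEVIATION if in_deviation else Segment.ANCHOR
        elements.append(Element(lexeme=token, segment=segment, position=position))
        position += 1
    if in_deviation:
        raise MarkupError("unclosed deviation marker")
    if not elements:
        raise EmptyTranscriptError("transcript contains no elements")

    if word_count is None:
        word_count = count_words(text, config)
    return Transcript(
        subject_id=subject_id, group=group, elements=elements, word_count=word_count
    )


def serialize_transcript(t: Transcript, config: MarkupConfig = DEFAULT_MARKUP) -> str:
    """Render a transcript back to the annotated text format.

    Inverse of :func:`parse_transcript` on element sequences and segment
    labels (round-trip property).
    """
    parts: list[str] = []
    in_deviation = False
    for el in t.elements:
        if el.segment is Segment.DEVIATION and not in_deviation:
            parts.append(config.open_marker)
            in_deviation = True
        elif el.segment is Segment.ANCHOR and in_deviation:
            parts.append(config.close_marker)
            in_deviation = False
        parts.append(el.lexeme)
    if in_deviation:
        parts.append(config.close_marker)
    return _join_with_separators(parts, config)


def _join_with_separators(parts: Sequence[str], config: MarkupConfig) -> str:
    """Join serialized tokens, placing separators only between lexemes."""
    pieces: list[str] = []
    prev_was_lexeme = False
    for part in parts:
        is_marker = part in (config.open_marker, config.close_marker)
        if pieces:
            if prev_was_lexeme and not is_marker:
                pieces.append(config.separator)
            elif prev_was_lexeme and part == config.open_marker:
                pieces.append(config.separator)
        pieces.append(part)
        prev_was_lexeme = not is_marker
    return " ".join(pieces)


def apply_lexeme_map(t: Transcript, mapping: Mapping[str, str]) -> Transcript:
    """Replace each element's surface form by its canonical lexeme.

    Surfaces are lowercased first; unmapped surfaces pass through (so an
    empty map is identity up to lowercasing).  Element count, order and
    segment labels are unchanged.
    """
    lowered = {str(k).lower(): v for k, v in mapping.items()}
    new_elements: list[Element] = []
    for el in t.elements:
        surface = el.lexeme.lower()
        lexeme = lowered.get(surface, surface)
        if not lexeme:
            raise InvalidLexemeError(
                f"lexeme map sends {el.lexeme!r} to an empty string"
            )
        new_elements.append(replace(el, lexeme=lexeme))
    return Transcript(
        subject_id=t.subject_id,
        group=t.group,
        elements=new_elements,
        word_count=t.word_count,
    )


def _optional_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def load_corpus(
    transcript_dir: str | Path,
    metadata_csv: str | Path,
    config: MarkupConfig = DEFAULT_MARKUP,
    lexeme_map: Optional[Mapping[str, str]] = None,
    strict_groups: bool = True,
) -> list[tuple[Transcript, SubjectRecord]]:
    """Load transcripts and join them with a metadata table.

    The CSV must have a ``subject_id`` and ``group`` column; ``word_count``,
    ``bprs`` and ``panss`` are optional.  One file ``<subject_id>.txt`` is
    expected per row.  A metadata-supplied word count wins over the count
    computed from the file; rows come back in CSV order.
    """
    transcript_dir = Path(transcript_dir)
    meta = pd.read_csv(metadata_csv, dtype={"subject_id": str})
    if "subject_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError("metadata CSV needs 'subject_id' and 'group' columns")
    if meta["subject_id"].duplicated().any():
        dupes = meta.loc[meta["subject_id"].duplicated(), "subject_id"].tolist()
        raise DuplicateSubjectError(f"duplicate subject ids: {dupes}")

    corpus: list[tuple[Transcript, SubjectRecord]] = []
    for _, row in meta.iterrows():
        sid = str(row["subject_id"])
        group = parse_group(row["group"], strict=strict_groups)
        path = transcript_dir / f"{sid}.txt"
        if not path.is_file():
            raise MissingTranscriptError(f"no transcript file for subject {sid!r}")
        text = path.read_text(encoding="utf-8")
        wc = None
        if "word_count" in meta.columns:
            wc = _optional_float(row.get("word_count"))
        word_count = int(wc) if wc is not None else count_words(text, config)
        t = parse_transcript(
            text, config=config, subject_id=sid, group=group, word_count=word_count
        )
        if lexeme_map:
            t = apply_lexeme_map(t, lexeme_map)
        record = SubjectRecord(
            subject_id=sid,
            group=group,
            word_count=word_count,
            bprs_total=_optional_float(row.get("bprs")) if "bprs" in meta.columns else None,
            panss_total=_optional_float(row.get("panss")) if "panss" in meta.columns else None,
        )
        corpus.append((t, record))
    return corpus
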