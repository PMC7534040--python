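"""Annotated speech transcripts and pre-analysis editing.

Connected-speech transcripts arrive with inline span annotations marking
material that is removed before coherence is computed: false starts and
aborted utterances (``<fs>...</fs>``), immediate perseverations of words or
phrases (``<rep>...</rep>``), and comments about the task or the speaker's
own language problems (``<com>...</com>``).  Spans may not nest or overlap.
Non-lexical fillers (umm, ah) are simply absent from transcripts.

Editing is annotation-driven: the spans encode human judgments and no
automatic disfluency detection is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

from .semantic_space import tokenize

__all__ = [
    "Transcript",
    "LengthEligibility",
    "TranscriptParseError",
    "parse_transcript",
    "serialize_transcript",
    "apply_edits",
    "check_length",
]

KEEP = "keep"
TAGS = {"fs": "false_start", "rep": "perseveration", "com": "task_comment"}
_TAG_FOR_LABEL = {v: k for k, v in TAGS.items()}
_MARKER_RE = re.compile(r"</?\s*([a-zA-Z]+)\s*>")


class TranscriptParseError(ValueError):
    """Malformed transcript markup; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class Transcript:
    """A single response: ordered tokens, each tagged keep/removal-reason."""

    participant_id: str = ""
    prompt_id: str = ""
    group: str = ""
    raw_tokens: list[tuple[str, str]] = field(default_factory=list)
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError("duration_s must be positive when present")

    @property
    def clean_tokens(self) -> list[str]:
        return [tok for tok, tag in self.raw_tokens if tag == KEEP]

    @property
    def removed_fraction(self) -> Fraction:
        """Exact fraction of tokens removed by editing (0 for empty input)."""
        n = len(self.raw_tokens)
        if n == 0:
            return Fraction(0)
        return Fraction(n - len(self.clean_tokens), n)

    @property
    def is_empty_response(self) -> bool:
        return len(self.clean_tokens) == 0

    @property
    def speech_rate_wpm(self) -> float | None:
        """Clean words per minute, when a duration is recorded."""
        if self.duration_s is None:
            return None
        return len(self.clean_tokens) / (self.duration_s / 60.0)


def parse_transcript(
    text: str,
    participant_id: str = "",
    prompt_id: str = "",
    group: str = "",
    duration_s: float | None = None,
) -> Transcript:
    """Parse annotated plain text into a tagged token sequence.

    Raises :class:`TranscriptParseError` (with a line number) on unknown
    tags, nested spans, mismatched closers, or an unclosed span.
    """
    raw_tokens: list[tuple[str, str]] = []
    open_tag: str | None = None
    pos = 0
    for match in list(_MARKER_RE.finditer(text)) + [None]:
        if match is None:
            segment, marker = text[pos:], None
        else:
            segment, marker = text[pos : match.start()], match.group()
            pos = match.end()
        current = KEEP if open_tag is None else TAGS[open_tag]
        raw_tokens.extend((tok, current) for tok in tokenize(segment))
        if match is None:
            break
        line = text.count("\n", 0, match.start()) + 1
        name = match.group(1).lower()
        closing = marker.startswith("</")
        if name not in TAGS:
            raise TranscriptParseError(f"unknown tag <{name}>", line)
        if closing:
            if open_tag is None:
                raise TranscriptParseError(f"</{name}> without opener", line)
            if open_tag != name:
                raise TranscriptParseError(
                    f"</{name}> closes <{open_tag}>", line
                )
            open_tag = None
        else:
            if open_tag is not None:
                raise TranscriptParseError(
                    f"<{name}> opened inside <{open_tag}> (spans may not nest)",
                    line,
                )
            open_tag = name
    if open_tag is not None:
        raise TranscriptParseError(
            f"<{open_tag}> never closed", text.count("\n") + 1
        )
    return Transcript(
        participant_id=participant_id,
        prompt_id=prompt_id,
        group=group,
        raw_tokens=raw_tokens,
        duration_s=duration_s,
    )


def serialize_transcript(t: Transcript) -> str:
    """Canonical text form; ``parse_transcript`` round-trips it exactly."""
    parts: list[str] = []
    open_tag: str | None = None
    for tok, tag in t.raw_tokens:
        wanted = None if tag == KEEP else _TAG_FOR_LABEL[tag]
        if wanted != open_tag:
            if open_tag is not None:
                parts.append(f"</{open_tag}>")
            if wanted is not None:
                parts.append(f"<{wanted}>")
            open_tag = wanted
        parts.append(tok)
    if open_tag is not None:
        parts.append(f"</{open_tag}>")
    return " ".join(parts)


def apply_edits(t: Transcript) -> tuple[list[str], Fraction]:
    """Drop annotated spans; report the exact removed fraction.

    Kept tokens preserve their original order.  The fraction is exact
    rational arithmetic (rounding, if any, happens at the report layer).
    """
    return t.clean_tokens, t.removed_fraction


@dataclass(frozen=True)
class LengthEligibility:
    """Which coherence measures a response is long enough to support."""

    n_clean_tokens: int
    window: int
    gc_eligible: bool
    lc_eligible: bool
    reason: str


def check_length(t: Transcript, w: int = 20) -> LengthEligibility:
    """A response supports GC with >= w clean tokens and LC with >= 2w.

    GC needs at least one full window; LC additionally needs a disjoint
    preceding window for at least one position.
    """
    n = len(t.clean_tokens)
    gc = n >= w
    lc = n >= 2 * w
    if gc and lc:
        reason = "eligible"
    elif gc:
        reason = f"only {n} clean tokens: too short for LC (needs {2 * w})"
    else:
        reason = f"only {n} clean tokens: too short for GC (needs {w})"
    return LengthEligibility(
        n_clean_tokens=n, window=w, gc_eligible=gc, lc_eligible=lc, reason=reason
    )


def pooled_removed_fraction(transcripts: Iterable[Transcript]) -> Fraction:
    """Group-level removed fraction pooled over all tokens."""
    total = 0
    removed = 0
    for t in transcripts:
        total += len(t.raw_tokens)
        removed += len(t.raw_tokens) - len(t.clean_tokens)
    if total == 0:
        return Fraction(0)
    return Fraction(removed, total)
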