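"""Reading and cleaning of narrative language-sample transcripts.

Transcripts arrive either in SALT convention (speaker-coded lines, parenthesized
mazes, bound-morpheme slashes, square-bracket codes) or as plain text with one
utterance per line. Cleaning strips everything that is transcription apparatus
rather than the child's language: mazes (repetitions, false starts, revisions)
are dropped wholesale, annotation characters are removed, bound-morpheme markers
are collapsed to the surface form the child actually produced, and tokens are
lowercased. Grammatical errors are deliberately left uncorrected: "go/ed"
becomes "goed", never "went".

The utterance is taken as given: one transcript line is one communication unit
(an independent clause plus its dependents); no re-segmentation is attempted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "Dialect",
    "RawTranscript",
    "Utterance",
    "CleanTranscript",
    "read_transcript",
    "remove_mazes",
    "clean_utterance",
    "clean_transcript",
]

#: Supported transcript dialects.
SALT = "salt"
PLAIN = "plain"
Dialect = str

#: Default speaker code for child lines in SALT transcripts.
CHILD_SPEAKER = "C"

#: SALT header lines begin with this marker.
HEADER_MARKER = "$"

# Characters that belong to the annotation alphabet and must never survive
# cleaning: parentheses (mazes), brackets (codes), slash (bound morphemes),
# plus assorted SALT sigils.
_ANNOTATION_CHARS = set("()[]/:;*{}<>")

# Anything that is not a lowercase letter, digit, apostrophe or hyphen is
# treated as separator after annotation removal.
_NONWORD_RE = re.compile(r"[^a-z0-9'\-]+")
_BRACKET_CODE_RE = re.compile(r"\[[^\]]*\]|\[[^\]]*$")
_X_TOKEN_RE = re.compile(r"^x+$")


@dataclass(frozen=True)
class Utterance:
    """One communication unit after cleaning: an indexed list of word tokens."""

    index: int
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("utterance index must be nonnegative")


@dataclass(frozen=True)
class RawTranscript:
    """A transcript as read from disk, before any cleaning.

    ``lines`` preserves source order as ``(speaker_code, text)`` pairs. For the
    plain dialect every line carries the child speaker code; for SALT, header
    lines carry the header marker as their speaker code.
    """

    transcript_id: str
    lines: tuple[tuple[str, str], ...]
    dialect: Dialect = PLAIN

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be nonempty")

    def scorable_lines(self, child_speaker: str = CHILD_SPEAKER) -> list[str]:
        """Texts of the lines attributable to the child, in source order."""
        if self.dialect == PLAIN:
            return [text for _, text in self.lines]
        return [text for code, text in self.lines if code == child_speaker]


@dataclass(frozen=True)
class CleanTranscript:
    """Cleaned, tokenized transcript; the unit every scorer consumes.

    May legitimately be empty — a transcript with zero scorable utterances
    scores 0 on every element.
    """

    transcript_id: str
    utterances: tuple[Utterance, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.utterances)

    def iter_tokens(self) -> Iterable[tuple[int, int, str]]:
        """Yield ``(utterance_index, position, token)`` over the transcript."""
        for utt in self.utterances:
            for pos, tok in enumerate(utt.tokens):
                yield utt.index, pos, tok


def read_transcript(
    path: str | Path,
    dialect: Dialect = PLAIN,
    transcript_id: str | None = None,
    child_speaker: str = CHILD_SPEAKER,
) -> RawTranscript:
    """Read a transcript file into a :class:`RawTranscript`.

    For ``dialect="plain"`` every nonblank line is one child utterance. For
    ``dialect="salt"``, lines beginning with ``$`` are headers, and the first
    whitespace-separated field of every other line is its speaker code; only
    lines whose code matches ``child_speaker`` are later scored.

    An empty file yields a valid transcript with zero lines.
    """
    path = Path(path)
    tid = transcript_id if transcript_id is not None else path.stem
    text = path.read_text(encoding="utf-8")
    lines: list[tuple[str, str]] = []
    for raw_line in text.splitlines():
        line = raw_line.strip()
        if not line:
            continue
        if dialect == PLAIN:
            lines.append((child_speaker, line))
            continue
        if line.startswith(HEADER_MARKER):
            lines.append((HEADER_MARKER, line))
            continue
        parts = line.split(None, 1)
        code = parts[0]
        body = parts[1] if len(parts) > 1 else ""
        lines.append((code, body))
    return RawTranscript(transcript_id=tid, lines=tuple(lines), dialect=dialect)


def remove_mazes(text: str) -> str:
    """Delete every parenthesized maze span, including nested spans.

    Mazes hold repetitions, false starts, and revisions, none of which count
    toward literate-language use. An unmatched ``(`` is recovered by treating
    it as extending to the end of the utterance (with a warning); a stray
    ``)`` is dropped.
    """
    out: list[str] = []
    depth = 0
    unbalanced = False
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            if depth == 0:
                unbalanced = True
            else:
                depth -= 1
        elif depth == 0:
            out.append(ch)
    if depth > 0:
        unbalanced = True
    if unbalanced:
        warnings.warn(
            f"unbalanced parentheses in utterance: {text!r}", stacklevel=2
        )
    return "".join(out)


def clean_utterance(text: str, dialect: Dialect = SALT) -> tuple[str, ...]:
    """Clean one utterance string to a tuple of lowercase word tokens.

    Applies, in order: maze removal, square-bracket code removal, collapse of
    bound-morpheme slashes (``dog/s`` -> ``dogs``), removal of annotation
    characters and punctuation, lowercasing, and removal of unintelligibility
    marks (``x``/``xx``/``xxx`` tokens). Errorful word forms are retained
    verbatim.
    """
    text = remove_mazes(text)
    text = _BRACKET_CODE_RE.sub(" ", text)
    # Bound-morpheme markers: concatenate root and suffix.
    text = text.replace("/", "")
    text = text.lower()
    text = _NONWORD_RE.sub(" ", text)
    tokens = []
    for tok in text.split():
        tok = tok.strip("'-")
        if not tok or not any(c.isalnum() for c in tok):
            continue
        if _X_TOKEN_RE.match(tok):
            continue
        tokens.append(tok)
    return tuple(tokens)


def clean_transcript(
    raw: RawTranscript, child_speaker: str = CHILD_SPEAKER
) -> CleanTranscript:
    """Clean every scorable line of ``raw`` into a :class:`CleanTranscript`.

    Utterances that come out empty (e.g., a line that was all maze) are
    dropped and the survivors re-indexed contiguously from 0.
    """
    utterances: list[Utterance] = []
    for text in raw.scorable_lines(child_speaker):
        tokens = clean_utterance(text, raw.dialect)
        if tokens:
            utterances.append(Utterance(index=len(utterances), tokens=tokens))
    return CleanTranscript(
        transcript_id=raw.transcript_id, utterances=tuple(utterances)
    )
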