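"""Transcript data model and I/O.

A language sample is stored as plain UTF-8 text, one utterance per line,
terminated by ``.``, ``?`` or ``!``.  Parenthesized spans follow the SALT
"maze" convention: material such as false starts, repeated words and fillers
that is excluded from the propositional content of the utterance, e.g.::

    (He) He is John.

Filled pauses (``um``, ``uh``, ...) are recognized against a configurable
lexicon at parse time.
"""

from __future__ import annotations

import csv
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "DEFAULT_FILLER_LEXICON",
    "TERMINATORS",
    "Token",
    "Utterance",
    "Transcript",
    "TranscriptParseError",
    "normalize_surface",
    "parse_transcript",
    "write_transcript",
    "read_transcript",
    "save_transcript",
    "read_manifest",
    "write_manifest",
]

TERMINATORS = (".", "?", "!")

#: Words or vocalizations that fill a pause.  The clinical literature names
#: "um, ah, oh" explicitly; the remaining entries follow common transcription
#: conventions.  Pass your own set to :func:`parse_transcript` to override.
DEFAULT_FILLER_LEXICON = frozenset({"um", "uh", "ah", "oh", "er", "hmm", "mm"})

_EDGE_PUNCT = "".join(c for c in string.punctuation if c not in "'")


def normalize_surface(surface: str) -> str:
    """Lower-case and strip edge punctuation (apostrophes inside words kept)."""
    s = surface.strip(_EDGE_PUNCT).strip()
    # strip stray edge apostrophes used as quotes, keep intra-word ones
    s = s.strip("'")
    return s.lower()


class TranscriptParseError(ValueError):
    """Raised for malformed transcript text; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class Token:
    """A single spoken token.

    ``normalized`` is the lower-cased, punctuation-stripped form used for all
    matching (filler lookup, repetition detection).  ``in_maze`` marks tokens
    inside a parenthesized maze annotation.
    """

    surface: str
    normalized: str
    is_filler: bool = False
    in_maze: bool = False


@dataclass(frozen=True)
class Utterance:
    """An independent clause with its dependent material, plus terminator."""

    tokens: tuple[Token, ...]
    terminator: str = "."

    def __post_init__(self) -> None:
        if self.terminator not in TERMINATORS:
            raise ValueError(f"invalid terminator {self.terminator!r}")

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Transcript:
    """An ordered sequence of utterances from one participant."""

    participant_id: str = ""
    utterances: tuple[Utterance, ...] = ()
    source_mode: Optional[str] = None  # phone | in_person | synthetic

    @property
    def n_utterances(self) -> int:
        return len(self.utterances)

    @property
    def n_tokens(self) -> int:
        return sum(u.n_tokens for u in self.utterances)


def _check_parentheses(line: str, line_number: int) -> None:
    depth = 0
    for ch in line:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TranscriptParseError("unbalanced ')'", line_number)
    if depth != 0:
        raise TranscriptParseError("unbalanced '('", line_number)


def _parse_line(
    line: str, line_number: int, lexicon: frozenset[str]
) -> Utterance:
    _check_parentheses(line, line_number)
    body = line.rstrip()
    terminator = "."
    if body and body[-1] in TERMINATORS:
        terminator = body[-1]
        body = body[:-1]

    tokens: list[Token] = []
    depth = 0
    current: list[str] = []
    current_in_maze = False

    def flush() -> None:
        nonlocal current
        if current:
            surface = "".join(current)
            norm = normalize_surface(surface)
            if norm:
                tokens.append(
                    Token(
                        surface=surface,
                        normalized=norm,
                        is_filler=norm in lexicon,
                        in_maze=current_in_maze,
                    )
                )
            current = []

    for ch in body:
        if ch == "(":
            flush()
            depth += 1
        elif ch == ")":
            flush()
            depth -= 1
        elif ch.isspace():
            flush()
        else:
            if not current:
                current_in_maze = depth > 0
            current.append(ch)
    flush()
    return Utterance(tokens=tuple(tokens), terminator=terminator)


def parse_transcript(
    text: str,
    filler_lexicon: Iterable[str] = DEFAULT_FILLER_LEXICON,
    participant_id: str = "",
    source_mode: Optional[str] = None,
) -> Transcript:
    """Parse raw transcript text into a :class:`Transcript`.

    One utterance per non-blank line.  Lines lacking a terminal ``.?!`` are
    treated as statements.  Unbalanced parentheses raise
    :class:`TranscriptParseError` with the offending line number.  An empty
    file yields a transcript with zero utterances.
    """
    lexicon = frozenset(normalize_surface(w) for w in filler_lexicon)
    utterances = []
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        utterances.append(_parse_line(line, i, lexicon))
    return Transcript(
        participant_id=participant_id,
        utterances=tuple(utterances),
        source_mode=source_mode,
    )


def write_transcript(t: Transcript) -> str:
    """Serialize a transcript back to text (one utterance per line).

    Round-trip property: ``parse_transcript(write_transcript(t))`` reproduces
    the utterance/token structure of ``t`` (consecutive maze tokens are merged
    into one parenthesized group).
    """
    lines = []
    for u in t.utterances:
        parts: list[str] = []
        maze_run: list[str] = []
        for tok in u.tokens:
            if tok.in_maze:
                maze_run.append(tok.surface)
            else:
                if maze_run:
                    parts.append("(" + " ".join(maze_run) + ")")
                    maze_run = []
                parts.append(tok.surface)
        if maze_run:
            parts.append("(" + " ".join(maze_run) + ")")
        lines.append(" ".join(parts) + u.terminator)
    return "".join(line + "\n" for line in lines)


def read_transcript(
    path: str | Path,
    filler_lexicon: Iterable[str] = DEFAULT_FILLER_LEXICON,
    participant_id: Optional[str] = None,
    source_mode: Optional[str] = None,
) -> Transcript:
    path = Path(path)
    pid = participant_id if participant_id is not None else path.stem
    return parse_transcript(
        path.read_text(encoding="utf-8"),
        filler_lexicon=filler_lexicon,
        participant_id=pid,
        source_mode=source_mode,
    )


def save_transcript(t: Transcript, path: str | Path) -> None:
    Path(path).write_text(write_transcript(t), encoding="utf-8")


MANIFEST_COLUMNS = ("participant_id", "transcript_path", "group_label", "source_mode")


def read_manifest(path: str | Path) -> list[dict[str, str]]:
    """Read a corpus manifest CSV (participant_id, transcript_path, group_label,
    source_mode).  Paths are interpreted relative to the manifest location."""
    path = Path(path)
    rows: list[dict[str, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "participant_id" not in reader.fieldnames:
            raise ValueError(f"{path}: not a corpus manifest (no participant_id column)")
        for row in reader:
            row = dict(row)
            row["transcript_path"] = str((path.parent / row["transcript_path"]).resolve())
            rows.append(row)
    ids = [r["participant_id"] for r in rows]
    if len(ids) != len(set(ids)):
        raise ValueError(f"{path}: duplicate participant_id in manifest")
    return rows


def write_manifest(rows: Sequence[dict[str, str]], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(MANIFEST_COLUMNS))
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in MANIFEST_COLUMNS})
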