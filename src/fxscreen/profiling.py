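"""Automatic extraction of the linguistic profile from a transcript.

The profile quantifies three things clinicians look at in a five-minute
monologue language sample:

* **dysfluency** — filled pauses (``um``, ``uh``) and exact repetitions of a
  linguistic unit of any length (word or phrase), where only fillers may
  intervene between the copies;
* **complexity / density** — utterance counts by terminator, words, morphemes,
  mean length of utterance (MLU, in morphemes), and the distribution of
  utterance lengths over short / medium / long bins;
* **temporal pattern** — the same measures recomputed on five contiguous
  equal-length segments of the token stream, capturing how dysfluency evolves
  over the course of the sample.

The default schema has 28 global features plus 5 x 12 per-segment features,
88 in total.  The schema is versioned so alternative feature sets can be
plugged in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import DEFAULT_FILLER_LEXICON, Token, Transcript, Utterance, normalize_surface

__all__ = [
    "MorphemeRules",
    "DEFAULT_MORPHEME_RULES",
    "RepetitionEvent",
    "FeatureSchema",
    "LinguisticProfile",
    "SegmentationError",
    "default_schema",
    "detect_filled_pauses",
    "detect_repetitions",
    "count_word_morphemes",
    "count_morphemes",
    "split_segments",
    "profile_transcript",
    "profiles_to_frame",
]


# ---------------------------------------------------------------------------
# Morpheme counting
# ---------------------------------------------------------------------------

#: Common words whose spelling mimics an inflection but which are monomorphemic.
_S_EXCEPTIONS = frozenset(
    "yes his hers its this thus us as was is gas bus plus news lens "
    "perhaps always campus focus virus basis crisis tennis".split()
)
_ED_EXCEPTIONS = frozenset(
    "need indeed feed seed deed speed shed sled bleed breed creed wicked "
    "hundred sacred naked hatred".split()
)
_ING_EXCEPTIONS = frozenset(
    "thing bring during nothing something anything everything morning "
    "evening spring string sibling ceiling darling".split()
)


@dataclass(frozen=True)
class MorphemeRules:
    """Configurable rule table for regular-inflection morpheme counting.

    Base word = 1 morpheme; each matched regular inflection (+s plural or
    third person, +ed, +ing) and each contraction / possessive part adds one.
    Fillers count zero.  The exception sets guard monomorphemic look-alikes
    (``yes``, ``thing``, ``need`` ...).
    """

    count_plural_s: bool = True
    count_past_ed: bool = True
    count_progressive_ing: bool = True
    count_contractions: bool = True
    s_exceptions: frozenset[str] = _S_EXCEPTIONS
    ed_exceptions: frozenset[str] = _ED_EXCEPTIONS
    ing_exceptions: frozenset[str] = _ING_EXCEPTIONS


DEFAULT_MORPHEME_RULES = MorphemeRules()


def count_word_morphemes(normalized: str, rules: MorphemeRules = DEFAULT_MORPHEME_RULES) -> int:
    """Morphemes in one normalized word form under the rule table."""
    if not normalized:
        return 0
    parts = [p for p in normalized.split("'") if p]
    if not parts:
        return 0
    count = 1
    if rules.count_contractions:
        count += len(parts) - 1  # n't, 's, 're, 'll ... each add one
    stem = parts[0]
    if (
        rules.count_progressive_ing
        and stem.endswith("ing")
        and len(stem) >= 5
        and stem not in rules.ing_exceptions
    ):
        count += 1
    elif (
        rules.count_past_ed
        and stem.endswith("ed")
        and len(stem) >= 4
        and stem not in rules.ed_exceptions
    ):
        count += 1
    elif (
        rules.count_plural_s
        and stem.endswith("s")
        and len(stem) >= 3
        and not stem.endswith("ss")
        and not stem.endswith("ous")
        and stem not in rules.s_exceptions
    ):
        count += 1
    return count


def count_morphemes(u: Utterance, rules: MorphemeRules = DEFAULT_MORPHEME_RULES) -> int:
    """Morphemes in an utterance: non-maze word tokens only, fillers count 0."""
    return sum(
        count_word_morphemes(tok.normalized, rules)
        for tok in u.tokens
        if not tok.in_maze and not tok.is_filler
    )


# ---------------------------------------------------------------------------
# Dysfluency detection
# ---------------------------------------------------------------------------


def detect_filled_pauses(
    u: Utterance, lexicon: Optional[Iterable[str]] = None
) -> tuple[int, tuple[int, ...]]:
    """Count filled pauses in an utterance and return their token positions.

    Maze tokens are included: a filler is a filler wherever it occurs.  When
    ``lexicon`` is None the filler flags assigned at parse time are used.
    """
    if lexicon is None:
        positions = tuple(i for i, tok in enumerate(u.tokens) if tok.is_filler)
    else:
        lex = frozenset(normalize_surface(w) for w in lexicon)
        positions = tuple(i for i, tok in enumerate(u.tokens) if tok.normalized in lex)
    return len(positions), positions


@dataclass(frozen=True)
class RepetitionEvent:
    """An exact duplication of a unit of ``unit_length`` tokens.

    ``n_copies`` >= 2 counts the whole run of copies; only filler tokens may
    appear between copies (``fillers_between`` counts them).  Unit length 1 is
    a word-level repetition, >= 2 phrase-level.
    """

    unit_length: int
    start_index: int
    n_copies: int
    fillers_between: int = 0

    @property
    def n_repetitions(self) -> int:
        """Number of repetitions the event contributes (copies beyond the first)."""
        return self.n_copies - 1

    @property
    def n_repeated_words(self) -> int:
        """Words occurring in the dysfluency: unit length per extra copy."""
        return self.unit_length * (self.n_copies - 1)


def detect_repetitions(u: Utterance, max_unit: int = 6) -> tuple[RepetitionEvent, ...]:
    """Find exact contiguous duplications of token units of length 1..max_unit.

    Matching is on normalized forms over all tokens (maze annotations
    included, so an annotated false start matches its resolution).  Only
    filler tokens may appear between copies; fillers themselves never form
    repetition units.  Longest unit wins: unit lengths are scanned from
    ``max_unit`` down to 1, left to right, and tokens consumed by an event
    cannot seed or join another event.
    """
    if max_unit < 1:
        raise ValueError("max_unit must be >= 1")
    toks = u.tokens
    n = len(toks)
    consumed = [False] * n
    events: list[RepetitionEvent] = []

    def usable_unit(start: int, length: int) -> bool:
        return all(
            not toks[j].is_filler and not consumed[j]
            for j in range(start, start + length)
        )

    for length in range(min(max_unit, n // 2), 0, -1):
        i = 0
        while i + 2 * length <= n:
            if not usable_unit(i, length):
                i += 1
                continue
            copies = [i]
            fillers_between = 0
            j = i + length
            while True:
                f = 0
                while j < n and toks[j].is_filler:
                    j += 1
                    f += 1
                if j + length <= n and usable_unit(j, length) and all(
                    toks[j + t].normalized == toks[i + t].normalized
                    for t in range(length)
                ):
                    copies.append(j)
                    fillers_between += f
                    j += length
                else:
                    break
            if len(copies) >= 2:
                events.append(
                    RepetitionEvent(
                        unit_length=length,
                        start_index=i,
                        n_copies=len(copies),
                        fillers_between=fillers_between,
                    )
                )
                for c in copies:
                    for t in range(c, c + length):
                        consumed[t] = True
                i = copies[-1] + length
            else:
                i += 1
    events.sort(key=lambda e: (e.start_index, -e.unit_length))
    return tuple(events)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


class SegmentationError(ValueError):
    pass


def _segment_sizes(n_tokens: int, k: int) -> list[int]:
    base, rem = divmod(n_tokens, k)
    return [base + 1 if i < rem else base for i in range(k)]


def split_segments(t: Transcript, k: int = 5, strict: bool = True) -> list[Transcript]:
    """Split the token stream into ``k`` contiguous near-equal spans.

    Span token counts differ by at most one (remainder-first allocation).
    Utterances crossing a boundary go to the segment holding their first
    token.  With ``strict`` (default), ``k`` greater than the total token
    count is an error; profiling relaxes this for degenerate inputs.
    """
    if k < 1:
        raise SegmentationError("k must be >= 1")
    total = t.n_tokens
    if strict and 0 < total < k:
        raise SegmentationError(f"cannot split {total} tokens into {k} segments")
    sizes = _segment_sizes(total, k)
    boundaries = np.cumsum([0] + sizes)  # token index ranges per segment
    segments: list[list[Utterance]] = [[] for _ in range(k)]
    pos = 0
    for u in t.utterances:
        seg = int(np.searchsorted(boundaries[1:], pos, side="right"))
        seg = min(seg, k - 1)
        segments[seg].append(u)
        pos += u.n_tokens
    return [
        Transcript(
            participant_id=t.participant_id,
            utterances=tuple(us),
            source_mode=t.source_mode,
        )
        for us in segments
    ]


# ---------------------------------------------------------------------------
# Feature schema and profile
# ---------------------------------------------------------------------------

GLOBAL_FEATURES = (
    "n_utterances",
    "n_statements",
    "n_questions",
    "n_exclamations",
    "n_words",
    "n_morphemes",
    "mlu",
    "n_one_word",
    "n_short",
    "pct_short",
    "n_medium",
    "pct_medium",
    "n_long",
    "pct_long",
    "n_filled_pauses",
    "filled_pauses_per_100_words",
    "n_repetitions",
    "n_word_repetitions",
    "n_phrase_repetitions",
    "n_repeated_words",
    "pct_repeated_words",
    "avg_repetitions_per_utterance",
    "n_utterances_with_repetition",
    "pct_utterances_with_repetition",
    "n_dysfluent_short",
    "n_dysfluent_medium",
    "n_dysfluent_long",
    "dysfluencies_per_100_words",
)

SEGMENT_FEATURES = (
    "n_utterances",
    "n_words",
    "mlu",
    "n_filled_pauses",
    "filled_pauses_per_100_words",
    "n_repetitions",
    "n_repeated_words",
    "pct_repeated_words",
    "n_short",
    "n_medium",
    "n_long",
    "avg_repetitions_per_utterance",
)


@dataclass(frozen=True)
class FeatureSchema:
    """Versioned ordered feature list with length-bin boundaries.

    Default: 28 global + 5 x 12 segment features = 88.  Length bins are in
    morphemes: short <= ``short_max``, medium ``short_max``+1..``medium_max``,
    long > ``medium_max``.
    """

    version: str = "fxscreen-88-v1"
    n_segments: int = 5
    short_max: int = 5
    medium_max: int = 10
    global_names: tuple[str, ...] = GLOBAL_FEATURES
    segment_names: tuple[str, ...] = SEGMENT_FEATURES

    @property
    def names(self) -> tuple[str, ...]:
        seg = tuple(
            f"seg{i}_{name}"
            for i in range(1, self.n_segments + 1)
            for name in self.segment_names
        )
        return self.global_names + seg

    def __post_init__(self) -> None:
        names = self.names
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def length_bin(self, morphemes: int) -> str:
        if morphemes <= self.short_max:
            return "short"
        if morphemes <= self.medium_max:
            return "medium"
        return "long"

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "n_segments": self.n_segments,
                "short_max": self.short_max,
                "medium_max": self.medium_max,
                "names": list(self.names),
            },
            indent=2,
        )


def default_schema() -> FeatureSchema:
    return FeatureSchema()


@dataclass(frozen=True)
class LinguisticProfile:
    """The extracted feature vector for one transcript, in schema order."""

    schema: FeatureSchema
    values: tuple[float, ...]
    participant_id: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.schema):
            raise ValueError(
                f"profile has {len(self.values)} values for a "
                f"{len(self.schema)}-feature schema"
            )

    def __getitem__(self, name: str) -> float:
        return self.values[self.schema.names.index(name)]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.schema.names), name=self.participant_id)


def _rate(numerator: float, denominator: float, scale: float = 100.0) -> float:
    """A percentage/rate with the zero-denominator convention: 0."""
    return scale * numerator / denominator if denominator > 0 else 0.0


def _block_stats(
    utterances: Sequence[Utterance],
    schema: FeatureSchema,
    rules: MorphemeRules,
    max_unit: int,
) -> dict[str, float]:
    n_utt = len(utterances)
    n_statements = sum(1 for u in utterances if u.terminator == ".")
    n_questions = sum(1 for u in utterances if u.terminator == "?")
    n_exclamations = sum(1 for u in utterances if u.terminator == "!")

    n_words = sum(1 for u in utterances for tok in u.tokens if not tok.in_maze)
    morphemes = [count_morphemes(u, rules) for u in utterances]
    n_morphemes = sum(morphemes)

    bins = {"short": 0, "medium": 0, "long": 0}
    for m in morphemes:
        bins[schema.length_bin(m)] += 1
    n_one_word = sum(1 for m in morphemes if m == 1)

    fp_counts = [detect_filled_pauses(u)[0] for u in utterances]
    n_filled = sum(fp_counts)

    events_per_utt = [detect_repetitions(u, max_unit=max_unit) for u in utterances]
    n_reps = sum(e.n_repetitions for evs in events_per_utt for e in evs)
    n_word_reps = sum(
        e.n_repetitions for evs in events_per_utt for e in evs if e.unit_length == 1
    )
    n_phrase_reps = sum(
        e.n_repetitions for evs in events_per_utt for e in evs if e.unit_length >= 2
    )
    n_repeated_words = sum(e.n_repeated_words for evs in events_per_utt for e in evs)
    n_utt_with_rep = sum(1 for evs in events_per_utt if evs)

    dysfluent = {"short": 0, "medium": 0, "long": 0}
    for m, fp, evs in zip(morphemes, fp_counts, events_per_utt):
        if fp > 0 or evs:
            dysfluent[schema.length_bin(m)] += 1

    return {
        "n_utterances": float(n_utt),
        "n_statements": float(n_statements),
        "n_questions": float(n_questions),
        "n_exclamations": float(n_exclamations),
        "n_words": float(n_words),
        "n_morphemes": float(n_morphemes),
        "mlu": _rate(n_morphemes, n_utt, scale=1.0),
        "n_one_word": float(n_one_word),
        "n_short": float(bins["short"]),
        "pct_short": _rate(bins["short"], n_utt),
        "n_medium": float(bins["medium"]),
        "pct_medium": _rate(bins["medium"], n_utt),
        "n_long": float(bins["long"]),
        "pct_long": _rate(bins["long"], n_utt),
        "n_filled_pauses": float(n_filled),
        "filled_pauses_per_100_words": _rate(n_filled, n_words),
        "n_repetitions": float(n_reps),
        "n_word_repetitions": float(n_word_reps),
        "n_phrase_repetitions": float(n_phrase_reps),
        "n_repeated_words": float(n_repeated_words),
        "pct_repeated_words": _rate(n_repeated_words, n_words),
        "avg_repetitions_per_utterance": _rate(n_reps, n_utt, scale=1.0),
        "n_utterances_with_repetition": float(n_utt_with_rep),
        "pct_utterances_with_repetition": _rate(n_utt_with_rep, n_utt),
        "n_dysfluent_short": float(dysfluent["short"]),
        "n_dysfluent_medium": float(dysfluent["medium"]),
        "n_dysfluent_long": float(dysfluent["long"]),
        "dysfluencies_per_100_words": _rate(n_filled + n_reps, n_words),
    }


def profile_transcript(
    t: Transcript,
    schema: Optional[FeatureSchema] = None,
    rules: MorphemeRules = DEFAULT_MORPHEME_RULES,
    max_unit: int = 6,
) -> LinguisticProfile:
    """Extract the full linguistic profile (default: 88 features).

    Rates with a zero denominator are emitted as 0; an empty transcript
    yields an all-zero profile.
    """
    schema = schema or default_schema()
    glob = _block_stats(t.utterances, schema, rules, max_unit)
    values = [glob[name] for name in schema.global_names]
    segments = split_segments(t, k=schema.n_segments, strict=False)
    for seg in segments:
        stats = _block_stats(seg.utterances, schema, rules, max_unit)
        values.extend(stats[name] for name in schema.segment_names)
    return LinguisticProfile(
        schema=schema, values=tuple(values), participant_id=t.participant_id
    )


def profiles_to_frame(profiles: Sequence[LinguisticProfile]) -> pd.DataFrame:
    """Stack profiles into a DataFrame indexed by participant_id."""
    if not profiles:
        return pd.DataFrame(columns=list(default_schema().names))
    schema = profiles[0].schema
    for p in profiles:
        if p.schema.version != schema.version:
            raise ValueError("mixed schema versions in profile set")
    frame = pd.DataFrame(
        [p.values for p in profiles],
        index=[p.participant_id for p in profiles],
        columns=list(schema.names),
    )
    frame.index.name = "participant_id"
    return frame
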