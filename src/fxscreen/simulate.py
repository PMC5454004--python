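"""Two-group synthetic cohort generator.

Emulates the study design the package targets: two groups of participants
(FX premutation ``carrier`` vs ``comparison``), each contributing a
five-minute-scale monologue transcript (~60 utterances / ~600 words by
default) and a BRIEF-A-style cognitive score row.  Group contrasts are
controlled by the per-group generative parameters:

* a **filled-pause hazard** per content token,
* a **repetition hazard** per utterance (with a word/phrase unit-length mix);
  injected repetitions are written as parenthesized maze annotations, the
  ground truth the profiler can be validated against,
* the **utterance length** distribution (negative-binomial over morphemes)
  and the utterance count distribution,
* **segment-position multipliers** scaling the dysfluency hazards across the
  five token-quintiles of the sample,
* per-scale **cognitive score** means/SDs (T-score metric).

The generated prose is not linguistically meaningful: words are drawn from a
fixed Zipf-weighted vocabulary.  That is irrelevant to every profile feature
except morpheme counts, which the vocabulary respects via the profiler's own
rule table.

Determinism: the same (spec, seed) yields byte-identical corpora; every
participant has an independent substream derived from the cohort seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cognitive import BRI_SCALES, MI_SCALES, SCALES, cognitive_frame, CognitiveProfile
from .corpus import (
    DEFAULT_FILLER_LEXICON,
    Token,
    Transcript,
    Utterance,
    save_transcript,
    write_manifest,
)
from .profiling import DEFAULT_MORPHEME_RULES, count_word_morphemes

__all__ = [
    "VOCABULARY",
    "GroupParams",
    "CohortSpec",
    "Cohort",
    "default_cohort_spec",
    "null_cohort_spec",
    "dysfluency_cognitive_spec",
    "generate_transcript",
    "generate_cohort",
    "write_cohort",
    "load_cohort_spec",
]

# Content vocabulary, roughly Zipf-ordered by everyday frequency.  Contains a
# mix of mono- and multi-morphemic forms; morpheme counts per word follow the
# profiler's rule table.
VOCABULARY: tuple[str, ...] = (
    "the", "and", "she", "he", "is", "was", "to", "a", "it", "that",
    "you", "of", "in", "my", "her", "his", "for", "on", "with", "but",
    "so", "we", "they", "do", "at", "this", "have", "be", "not", "son",
    "daughter", "school", "time", "work", "home", "like", "very", "good",
    "really", "now", "then", "when", "what", "who", "how", "about", "out",
    "up", "go", "going", "goes", "get", "gets", "got", "know", "knows",
    "think", "thinks", "want", "wants", "wanted", "help", "helps", "helped",
    "play", "plays", "played", "playing", "talk", "talks", "talked",
    "talking", "work", "works", "worked", "working", "love", "loves",
    "loved", "year", "years", "day", "days", "friend", "friends", "thing",
    "things", "kid", "kids", "happy", "hard", "big", "little", "nice",
    "proud", "always", "never", "sometimes", "well", "just", "still",
    "also", "much", "more", "other", "people", "family", "mother", "child",
    "children", "care", "cares", "cared", "caring", "need", "needs",
    "try", "tries", "tried", "trying", "enjoy", "enjoys", "enjoyed",
)

_FILLERS = ("um", "uh", "ah", "oh", "er")


def _zipf_weights(n: int, exponent: float = 1.0) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


_VOCAB_WEIGHTS = _zipf_weights(len(VOCABULARY))
_VOCAB_MORPHEMES = tuple(
    count_word_morphemes(w, DEFAULT_MORPHEME_RULES) for w in VOCABULARY
)


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one group.

    Counts are negative-binomial (mean / dispersion ``r``; variance
    mean + mean^2 / r), hazards are probabilities in [0, 1], cognitive scores
    are normal per scale on the T-score metric.
    """

    utterance_count_mean: float = 60.0
    utterance_count_dispersion: float = 25.0
    utterance_length_mean: float = 10.0  # morphemes
    utterance_length_dispersion: float = 6.0
    filled_pause_hazard: float = 0.030  # per content token
    repetition_hazard: float = 0.10  # per utterance
    repetition_unit_mix: tuple[float, ...] = (0.6, 0.3, 0.1)  # unit length 1,2,3
    segment_multipliers: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    question_prob: float = 0.05
    exclamation_prob: float = 0.03
    cognitive_means: dict[str, float] = field(
        default_factory=lambda: {s: 50.0 for s in SCALES}
    )
    cognitive_sds: dict[str, float] = field(
        default_factory=lambda: {s: 10.0 for s in SCALES}
    )
    validity_mean: float = 50.0
    validity_sd: float = 8.0
    age_mean: float = 48.0
    age_sd: float = 7.0
    education_probs: tuple[float, ...] = (0.05, 0.25, 0.45, 0.25)

    def __post_init__(self) -> None:
        for name in ("filled_pause_hazard", "repetition_hazard"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(m <= 0 for m in self.segment_multipliers):
            raise ValueError("segment multipliers must be positive")
        if len(self.segment_multipliers) != 5:
            raise ValueError("segment_multipliers must have length 5")


@dataclass(frozen=True)
class CohortSpec:
    """A full two-group cohort specification.

    ``informative_features`` records the ground-truth feature names whose
    generative parameters differ between groups (the recovery targets for
    feature-selection validation).
    """

    n_per_group: int = 100
    seed: int = 0
    carrier: GroupParams = field(default_factory=GroupParams)
    comparison: GroupParams = field(default_factory=GroupParams)
    informative_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for group in ("carrier", "comparison"):
            if group in d and isinstance(d[group], dict):
                g = dict(d[group])
                for key in ("repetition_unit_mix", "segment_multipliers", "education_probs"):
                    if key in g:
                        g[key] = tuple(g[key])
                d[group] = GroupParams(**g)
        if "informative_features" in d:
            d["informative_features"] = tuple(d["informative_features"])
        return cls(**d)


def default_cohort_spec(n_per_group: int = 100, seed: int = 0) -> CohortSpec:
    """The default study conditions: carriers show more filled pauses and
    repetitions, shorter utterances, stronger edge-of-sample dysfluency, and
    poorer Organization of Materials / Self-Monitor / Task Monitor scores."""
    carrier_means = {s: 50.0 for s in SCALES}
    for s in ("organization_of_materials", "self_monitor", "task_monitor"):
        carrier_means[s] = 55.0
    carrier = GroupParams(
        utterance_length_mean=9.0,
        filled_pause_hazard=0.045,
        repetition_hazard=0.15,
        segment_multipliers=(1.30, 1.05, 0.95, 1.00, 1.25),
        cognitive_means=carrier_means,
    )
    comparison = GroupParams(
        segment_multipliers=(1.15, 1.05, 1.00, 0.95, 0.85),
    )
    return CohortSpec(
        n_per_group=n_per_group,
        seed=seed,
        carrier=carrier,
        comparison=comparison,
        informative_features=(
            "n_filled_pauses",
            "n_repetitions",
            "mlu",
            "organization_of_materials",
            "self_monitor",
            "task_monitor",
        ),
    )


def null_cohort_spec(n_per_group: int = 50, seed: int = 0) -> CohortSpec:
    """Zero between-group differences: the label-permutation-symmetric null."""
    return CohortSpec(
        n_per_group=n_per_group,
        seed=seed,
        carrier=GroupParams(),
        comparison=GroupParams(),
        informative_features=(),
    )


def dysfluency_cognitive_spec(
    magnitude: float = 1.0, n_per_group: int = 50, seed: int = 0
) -> CohortSpec:
    """Effect-recovery conditions: only the filled-pause hazard and three
    cognitive scales differ between groups, scaled by ``magnitude``.

    Per unit of magnitude the carrier filled-pause hazard rises by 0.015
    over the 0.030 baseline and the three affected scales shift by +9
    T-points.  Other parameters are identical across groups, so the
    ground-truth informative features are exactly the four direct targets.
    """
    carrier_means = {s: 50.0 for s in SCALES}
    for s in ("organization_of_materials", "self_monitor", "task_monitor"):
        carrier_means[s] = 50.0 + 9.0 * magnitude
    carrier = GroupParams(
        filled_pause_hazard=min(1.0, 0.030 + 0.015 * magnitude),
        cognitive_means=carrier_means,
    )
    return CohortSpec(
        n_per_group=n_per_group,
        seed=seed,
        carrier=carrier,
        comparison=GroupParams(),
        informative_features=(
            "n_filled_pauses",
            "organization_of_materials",
            "self_monitor",
            "task_monitor",
        ),
    )


# ---------------------------------------------------------------------------
# Transcript generation
# ---------------------------------------------------------------------------


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Over-dispersed count draw: NB with mean ``mean`` and size ``dispersion``."""
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _draw_utterance_words(rng: np.random.Generator, target_morphemes: int) -> list[str]:
    """Draw content words until the morpheme target is met.

    Immediate duplicates are redrawn: fluent speech essentially never emits
    the same word twice in a row, so exact adjacent duplications are left to
    the explicit repetition-injection step.
    """
    words: list[str] = []
    morphemes = 0
    while morphemes < target_morphemes:
        idx = int(rng.choice(len(VOCABULARY), p=_VOCAB_WEIGHTS))
        for _ in range(8):
            if not words or VOCABULARY[idx] != words[-1]:
                break
            idx = int(rng.choice(len(VOCABULARY), p=_VOCAB_WEIGHTS))
        words.append(VOCABULARY[idx])
        morphemes += _VOCAB_MORPHEMES[idx]
    return words


def _word_token(surface: str, in_maze: bool = False) -> Token:
    return Token(surface=surface, normalized=surface, is_filler=False, in_maze=in_maze)


def _filler_token(surface: str) -> Token:
    return Token(surface=surface, normalized=surface, is_filler=True, in_maze=False)


def generate_transcript(
    params: GroupParams,
    seed: int | Sequence[int],
    participant_id: str = "",
) -> Transcript:
    """Generate one synthetic monologue transcript.

    Utterance count and per-utterance morpheme targets are drawn first; the
    resulting content-token stream fixes the five quintiles whose position
    multipliers scale the dysfluency hazards.  Fillers are then injected per
    content token, and finally repetition events: a contiguous non-filler
    unit is duplicated in front of itself as a parenthesized maze annotation,
    so injected events are detectable with or without the annotation.
    """
    rng = np.random.default_rng(seed)
    n_utt = max(1, _negbin(rng, params.utterance_count_mean, params.utterance_count_dispersion))
    targets = [
        1 + _negbin(rng, max(0.01, params.utterance_length_mean - 1.0),
                    params.utterance_length_dispersion)
        for _ in range(n_utt)
    ]
    contents = [_draw_utterance_words(rng, t) for t in targets]

    token_total = sum(len(c) for c in contents)
    starts = np.cumsum([0] + [len(c) for c in contents[:-1]])
    quintile = lambda pos: min(4, int(5 * pos / token_total)) if token_total else 0

    utterances = []
    for words, start in zip(contents, starts):
        mult = params.segment_multipliers[quintile(start)]
        tokens: list[Token] = []
        for offset, w in enumerate(words):
            tokens.append(_word_token(w))
            hazard = min(1.0, params.filled_pause_hazard * params.segment_multipliers[quintile(start + offset)])
            if hazard > 0 and rng.random() < hazard:
                tokens.append(_filler_token(_FILLERS[int(rng.integers(len(_FILLERS)))]))

        rep_hazard = min(1.0, params.repetition_hazard * mult)
        if rep_hazard > 0 and rng.random() < rep_hazard:
            runs = _nonfiller_runs(tokens)
            if runs:
                mix = np.asarray(params.repetition_unit_mix, dtype=float)
                mix = mix / mix.sum()
                unit_len = int(rng.choice(len(mix), p=mix)) + 1
                run_lo, run_hi = runs[int(rng.integers(len(runs)))]
                unit_len = min(unit_len, run_hi - run_lo)
                lo = run_lo + int(rng.integers(run_hi - run_lo - unit_len + 1))
                copy = [
                    dataclasses.replace(tokens[j], in_maze=True)
                    for j in range(lo, lo + unit_len)
                ]
                tokens[lo:lo] = copy

        r = rng.random()
        if r < params.question_prob:
            term = "?"
        elif r < params.question_prob + params.exclamation_prob:
            term = "!"
        else:
            term = "."
        utterances.append(Utterance(tokens=tuple(tokens), terminator=term))

    return Transcript(
        participant_id=participant_id,
        utterances=tuple(utterances),
        source_mode="synthetic",
    )


def _nonfiller_runs(tokens: Sequence[Token]) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, tok in enumerate(tokens):
        if tok.is_filler:
            if start is not None:
                runs.append((start, i))
                start = None
        elif start is None:
            start = i
    if start is not None:
        runs.append((start, len(tokens)))
    return runs


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """An in-memory synthetic cohort: transcripts, cognitive table, labels."""

    spec: CohortSpec
    transcripts: list[Transcript]
    cognitive: pd.DataFrame  # indexed by participant_id, 15 columns
    labels: pd.Series  # participant_id -> carrier | comparison

    @property
    def participant_ids(self) -> list[str]:
        return [t.participant_id for t in self.transcripts]


def _generate_cognitive_row(
    params: GroupParams, rng: np.random.Generator, participant_id: str
) -> CognitiveProfile:
    scales = {
        s: float(np.round(rng.normal(params.cognitive_means[s], params.cognitive_sds[s]), 1))
        for s in SCALES
    }
    edu_probs = np.asarray(params.education_probs, dtype=float)
    edu_probs = edu_probs / edu_probs.sum()
    return CognitiveProfile(
        participant_id=participant_id,
        scales=scales,
        validity=float(np.round(rng.normal(params.validity_mean, params.validity_sd), 1)),
        maternal_age=float(np.round(np.clip(rng.normal(params.age_mean, params.age_sd), 25, 80), 1)),
        maternal_education=int(rng.choice(4, p=edu_probs)) + 1,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full two-group cohort deterministically from the spec."""
    transcripts: list[Transcript] = []
    cognitive_profiles: list[CognitiveProfile] = []
    labels = {}
    for g_index, (label, params) in enumerate(
        (("carrier", spec.carrier), ("comparison", spec.comparison))
    ):
        for i in range(spec.n_per_group):
            pid = f"{'FX' if label == 'carrier' else 'CG'}{i + 1:03d}"
            transcripts.append(
                generate_transcript(params, seed=[spec.seed, g_index, i], participant_id=pid)
            )
            cog_rng = np.random.default_rng([spec.seed, g_index, i, 1])
            cognitive_profiles.append(_generate_cognitive_row(params, cog_rng, pid))
            labels[pid] = label
    cog = cognitive_frame(cognitive_profiles)
    lab = pd.Series(labels, name="label")
    lab.index.name = "participant_id"
    return Cohort(spec=spec, transcripts=transcripts, cognitive=cog, labels=lab)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort to disk: manifest.csv, transcripts/, cognitive.csv,
    ground_truth.json and the serialized spec."""
    out = Path(out_dir)
    (out / "transcripts").mkdir(parents=True, exist_ok=True)
    rows = []
    for t in cohort.transcripts:
        rel = f"transcripts/{t.participant_id}.txt"
        save_transcript(t, out / rel)
        rows.append(
            {
                "participant_id": t.participant_id,
                "transcript_path": rel,
                "group_label": cohort.labels[t.participant_id],
                "source_mode": t.source_mode or "synthetic",
            }
        )
    write_manifest(rows, out / "manifest.csv")
    cohort.cognitive.reset_index().to_csv(out / "cognitive.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(
            {"informative_features": list(cohort.spec.informative_features)},
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    (out / "cohort_spec.json").write_text(cohort.spec.to_json() + "\n", encoding="utf-8")
    return out


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Load a CohortSpec from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return CohortSpec.from_dict(data)
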