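"""Linguistic feature extraction: dysfluencies, morphemes, segments, profile."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fxscreen as fx
from fxscreen.profiling import (
    SegmentationError,
    _segment_sizes,
    count_morphemes,
    count_word_morphemes,
    default_schema,
)


def utt(text: str) -> fx.Utterance:
    return fx.parse_transcript(text).utterances[0]


class TestFilledPauses:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("She is uh a very uh lovely girl.", 2),
            ("He is John.", 0),
            ("Um uh um.", 3),
            ("(um) well um.", 2),  # maze fillers count
        ],
    )
    def test_counts(self, text, expected):
        count, positions = fx.detect_filled_pauses(utt(text))
        assert count == expected
        assert len(positions) == expected


class TestRepetitions:
    def test_word_level(self):
        events = fx.detect_repetitions(utt("(He) He is John."))
        assert len(events) == 1
        assert events[0].unit_length == 1
        assert events[0].n_copies == 2

    def test_phrase_level(self):
        events = fx.detect_repetitions(utt("(He is) He is John."))
        assert len(events) == 1
        assert events[0].unit_length == 2

    def test_fillers_allowed_between_copies(self):
        events = fx.detect_repetitions(utt("she is uh she is nice"))
        assert len(events) == 1
        assert events[0].unit_length == 2
        assert events[0].fillers_between == 1

    def test_no_events_in_fluent_utterance(self):
        assert fx.detect_repetitions(utt("He is John.")) == ()

    def test_fillers_never_form_units(self):
        assert fx.detect_repetitions(utt("um um um.")) == ()

    def test_triple_copy_counts_two_repetitions(self):
        (event,) = fx.detect_repetitions(utt("no no no."))
        assert event.n_copies == 3
        assert event.n_repetitions == 2

    def test_longest_unit_wins_no_double_count(self):
        # "(he is) he is" must be one phrase event, not phrase + two word events
        events = fx.detect_repetitions(utt("(he is) he is john john."))
        assert sorted(e.unit_length for e in events) == [1, 2]

    def test_interrupting_word_blocks_match(self):
        assert fx.detect_repetitions(utt("she is very she is nice")) == ()


class TestMorphemes:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Yes.", 1),
            ("He is John.", 3),
            ("dogs running", 4),
            ("don't", 2),  # contraction parts each add one
            ("the boy's dog", 4),  # possessive adds one
            ("he walked", 3),
            ("this thing is his.", 4),  # look-alike inflections ignored
            ("um uh.", 0),  # fillers count zero
            ("(he is) he is nice", 3),  # maze tokens excluded
        ],
    )
    def test_rule_table(self, text, expected):
        assert count_morphemes(utt(text)) == expected

    def test_rules_configurable(self):
        rules = fx.MorphemeRules(count_past_ed=False)
        assert count_word_morphemes("walked", rules) == 1


class TestSegments:
    def test_exact_division(self):
        t = fx.parse_transcript("\n".join("a b c d e." for _ in range(20)))
        segs = fx.split_segments(t, k=5)
        assert [s.n_tokens for s in segs] == [20, 20, 20, 20, 20]

    def test_remainder_first_allocation(self):
        assert _segment_sizes(103, 5) == [21, 21, 21, 20, 20]

    def test_k1_is_identity(self):
        t = fx.parse_transcript("a b.\nc d e.")
        (seg,) = fx.split_segments(t, k=1)
        assert seg.utterances == t.utterances

    def test_utterance_goes_to_segment_of_first_token(self):
        # 3 utterances x 4 tokens = 12 tokens, k=2 -> spans of 6;
        # the middle utterance starts at token 4 (first span)
        t = fx.parse_transcript("a b c d.\ne f g h.\ni j k l.")
        segs = fx.split_segments(t, k=2)
        assert [s.n_utterances for s in segs] == [2, 1]

    def test_too_many_segments_is_error(self):
        t = fx.parse_transcript("a b c.")
        with pytest.raises(SegmentationError):
            fx.split_segments(t, k=5)

    def test_order_and_partition_preserved(self):
        t = fx.parse_transcript("\n".join(f"w{i} x{i} y{i}." for i in range(11)))
        segs = fx.split_segments(t, k=5)
        recombined = [u for s in segs for u in s.utterances]
        assert recombined == list(t.utterances)


class TestProfile:
    def test_empty_transcript_is_all_zero(self):
        p = fx.profile_transcript(fx.parse_transcript(""))
        assert len(p.values) == 88
        assert all(v == 0.0 for v in p.values)

    def test_phrase_repetition_worked_example(self):
        p = fx.profile_transcript(fx.parse_transcript("(He is) He is John."))
        assert p["n_utterances"] == 1
        assert p["n_statements"] == 1
        assert p["n_repetitions"] == 1
        assert p["n_phrase_repetitions"] == 1
        assert p["n_word_repetitions"] == 0
        assert p["n_repeated_words"] == 2
        assert p["n_words"] == 3  # maze tokens excluded from word count

    def test_two_utterance_worked_example(self):
        text = "She is uh a very uh lovely girl.\nYes.\n"
        p = fx.profile_transcript(fx.parse_transcript(text))
        assert p["n_filled_pauses"] == 2
        assert p["n_one_word"] == 1
        # morphemes: 6 content words x 1 + yes -> MLU (6+1)/2
        assert p["mlu"] == pytest.approx(3.5)
        assert p["n_utterances"] == 2

    def test_length_bins_partition_utterances(self, small_cohort):
        for t in small_cohort.transcripts[:10]:
            p = fx.profile_transcript(t)
            assert p["n_short"] + p["n_medium"] + p["n_long"] == p["n_utterances"]
            assert (
                p["n_statements"] + p["n_questions"] + p["n_exclamations"]
                == p["n_utterances"]
            )

    def test_repeated_word_percentage_identity(self, small_cohort):
        for t in small_cohort.transcripts[:10]:
            p = fx.profile_transcript(t)
            if p["n_words"] > 0:
                assert p["pct_repeated_words"] == pytest.approx(
                    100.0 * p["n_repeated_words"] / p["n_words"]
                )

    def test_segment_blocks_consistent_with_global(self, small_cohort):
        for t in small_cohort.transcripts[:10]:
            p = fx.profile_transcript(t)
            for name, total in (
                ("n_words", p["n_words"]),
                ("n_filled_pauses", p["n_filled_pauses"]),
                ("n_utterances", p["n_utterances"]),
            ):
                seg_sum = sum(p[f"seg{i}_{name}"] for i in range(1, 6))
                assert seg_sum == total

    def test_profile_case_invariant(self):
        text = "She is uh a very uh lovely girl.\n(He is) He is John.\n"
        lower = fx.profile_transcript(fx.parse_transcript(text.lower()))
        upper = fx.profile_transcript(fx.parse_transcript(text.upper()))
        assert lower.values == upper.values

    def test_schema_has_88_unique_names(self):
        schema = default_schema()
        assert len(schema) == 88
        assert len(set(schema.names)) == 88

    def test_one_word_keys_on_morphemes(self):
        # a one-token inflected word has 2 morphemes: not a one-word utterance
        p = fx.profile_transcript(fx.parse_transcript("dogs."))
        assert p["n_one_word"] == 0

    def test_rates_bounded(self, small_cohort):
        for t in small_cohort.transcripts[:10]:
            p = fx.profile_transcript(t)
            for name in ("pct_short", "pct_medium", "pct_long",
                         "pct_repeated_words", "pct_utterances_with_repetition"):
                assert 0.0 <= p[name] <= 100.0
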