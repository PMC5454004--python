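"""Parse a short language sample and extract its linguistic profile.

The transcript dialect is one utterance per line; parenthesized spans are
SALT-style maze annotations (dysfluent material excluded from propositional
content).  The profiler counts filled pauses, exact repetitions, morphemes
and utterance-length structure.
"""

import fxscreen as fx

SAMPLE = """\
She is uh a very uh lovely girl.
(He is) He is John.
What is his name?
Yes.
"""

transcript = fx.parse_transcript(SAMPLE, participant_id="demo")
profile = fx.profile_transcript(transcript)

print(f"utterances: {int(profile['n_utterances'])} "
      f"(statements {int(profile['n_statements'])}, "
      f"questions {int(profile['n_questions'])})")
print(f"words (non-maze): {int(profile['n_words'])}, "
      f"MLU {profile['mlu']:.2f} morphemes/utterance")
print(f"filled pauses: {int(profile['n_filled_pauses'])}  "
      f"repetitions: {int(profile['n_repetitions'])} "
      f"(phrase-level {int(profile['n_phrase_repetitions'])})")
print(f"dysfluencies per 100 words: {profile['dysfluencies_per_100_words']:.1f}")
print(f"profile width: {len(profile.values)} features")

# The counts above follow the clinical feature definitions: 'uh' twice in the
# first utterance, one phrase repetition '(He is) He is', and 'Yes.' is the
# single one-word utterance.
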