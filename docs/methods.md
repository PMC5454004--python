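# Methods

## Transcript model and dialect

A language sample is plain UTF-8 text, one utterance per line, terminated by
`.`, `?` or `!` (a missing terminator is read as a statement, the dominant
type in monologue). Parenthesized spans follow the SALT maze convention:
dysfluent material (false starts, repeated words, fillers) excluded from
propositional content. Transcription conventions for this population are not
standardized in a machine-readable form, so this dialect is a deliberate
reconstruction: the simplest format that preserves utterance boundaries,
terminator identity and maze annotation. Tokenization is whitespace
splitting with edge punctuation stripped (intra-word apostrophes kept) and
lower-case normalization, making every downstream feature case-invariant.

Maze annotations are optional input. When present they serve as ground-truth
dysfluency marks; the profiler never requires them — repetition detection
works on the raw token stream.

## Linguistic features (88)

28 global features plus 12 features for each of five segments, under a
versioned schema (`fxscreen-88-v1`).

**Filled pauses** are tokens whose normalized form is in a configurable
lexicon (default `um, uh, ah, oh, er, hmm, mm`; the clinical literature
names *um, ah, oh* — the extras follow common transcription practice).
Fillers are counted wherever they occur, including inside mazes.

**Repetitions** are exact duplications of a token unit of any length
(default up to 6) where only fillers may appear between copies, matched on
normalized forms. Fillers never form part of a unit. Precedence: longest
unit wins globally, then left-to-right; tokens consumed by an event cannot
seed or join another. This prevents `(he is) he is` from being counted as
both a phrase event and two word events — word- and phrase-level counts are
disjoint. An event with *c* copies contributes *c − 1* repetitions and
*unit length × (c − 1)* repeated words. The detector is verified
exhaustively against an independently formulated brute-force oracle on all
short sequences over a content+filler alphabet, plus seeded random
sequences up to length 12 (exhaustive enumeration much past length 7 is
combinatorially explosive with no added coverage of the precedence logic).

**Morphemes** follow a configurable regular-inflection rule table in the
spirit of Brown/SALT counting: base word 1; plural/third-person `+s`, past
`+ed`, progressive `+ing`, possessives and contraction parts add 1 each;
exception lists guard monomorphemic look-alikes (*yes*, *thing*, *need*).
Fillers count 0 and maze tokens are excluded. MLU is morphemes per
utterance. The exact conventions behind clinical MLU vary between labs;
the rule table is therefore replaceable.

**Word counts** include every non-maze token (fillers included — they are
produced speech); maze material is excluded as non-propositional, but words
duplicated inside a maze still count toward repeated words, mirroring how
SALT-coded mazes are tallied for dysfluency.

**Length bins** partition utterances by morpheme count: short ≤ 5, medium
6–10, long ≥ 11. Descriptions that leave "exactly 5" unassigned are closed
here so the bins partition (required for the bin-sum invariant); a one-word
utterance is one with exactly 1 morpheme, so a single inflected token is not
"one word". A *dysfluent* utterance contains at least one filled pause or
repetition event; dysfluent counts are reported per length bin, and the
overall dysfluency rate is (filled pauses + repetitions) per 100 words.
All rates with zero denominators are emitted as 0, so an empty transcript
yields an all-zero profile.

**Segments.** The token stream is split into five contiguous spans whose
token counts differ by at most one (remainder allocated to the leading
spans); an utterance belongs to the segment holding its first token.
Segmenting is by text length, not time — transcripts carry no timestamps,
so "equal length" is interpreted as equal token count. `split_segments` is
strict (splitting fewer tokens than segments is an error); the profiler
relaxes this for degenerate inputs so tiny transcripts still profile.

## Cognitive features (15)

Nine BRIEF-A-style clinical scales on the T-score metric, the BRI (four
scales) and MI (five scales) composites and GEC (BRI + MI) recomputed by a
sum convention — norm-referenced T-score lookup tables are proprietary and
out of scope — plus a single validity composite, maternal age in years, and
maternal education on an ordinal 1–4 scale. Provided composite columns are
cross-checked against the recomputed values within a configurable tolerance.
The identity of the 15th feature is a documented reconstruction (a single
validity composite); the block is configurable.

## Information gain with MDL discretization

Ranking uses `IG(C, x) = H(C) − H(C | x)` in bits. Continuous features are
discretized by recursive binary splitting: each candidate cut (midpoint
between adjacent distinct sorted values) is scored by weighted class
entropy, and a split is accepted only if its gain exceeds the Fayyad–Irani
MDL threshold `(log₂(N−1) + log₂(3^k − 2) − [k·H(S) − k₁·H(S₁) − k₂·H(S₂)])/N`.
Features whose first cut is rejected receive gain 0, which matches the
observation that only a few cognitive scales carry non-zero gain against a
background of many uninformative features. Because cuts depend only on the
rank order of values, gain is invariant to strictly monotone transforms.
Ties in the ranking (ubiquitous at gain 0) are broken by schema order.
Constant labels are an error — ranking against zero class entropy is
meaningless.

## Cross-validation harness

Stratified k-fold (default k = 10), shuffled with the run seed. The design
is balanced two-group, which makes stratification the lower-variance
faithful choice over plain random splitting. Inside each training fold:
per-feature z-scoring (training-fold statistics; zero-SD features pass
through unscaled), then optional information-gain ranking with the
non-zero-gain subset used for that fold. If a fold selects nothing (typical
under the null), the full profile is used — the classifier then has to
find no structure, which is the behavior the null-calibration test checks.
Summary metrics come from the pooled out-of-fold confusion counts at a 0.5
score threshold, and a single ROC curve from the pooled out-of-fold scores
(the conventional single-curve presentation). Fold-level information gains
are retained so gains can be reported as mean ± SD across folds; gains may
also be computed once on a full dataset — both modes are exposed.

The five learners are scikit-learn estimators behind this module's surface:
logistic regression (max_iter 2000), Gaussian naive Bayes, AdaBoost with 50
depth-1 stumps, a Gini decision tree, and a 500-tree random forest with
√p features per split and vote fractions as scores. None of these defaults
is tuned; they are recorded in every output together with the seed.

## Evaluation metrics

Sensitivity, specificity, accuracy, MCC and F1 are computed natively from
the confusion matrix. Degenerate denominators: MCC with a zero denominator
is 0 (the continuous limit and the common convention for single-class
predictors); other zero-denominator metrics are 0; an all-zero matrix is an
error. The ROC curve enumerates all distinct score thresholds and AUC is
trapezoidal, which equals the pairwise rank statistic with ties counted ½ —
asserted against an independent pairwise oracle and scikit-learn.
The two-sample t test accepts printed summary statistics (mean/SD/n) or raw
vectors; the default is the pooled Student statistic (equal group sizes make
it identical to Welch), cross-checked against scipy.

Screening PPV is Bayes' rule at a supplied prevalence; the enrichment factor
PPV/prevalence expresses the fold-reduction in confirmatory genetic tests
per true carrier found. At sensitivity = specificity = 0.81 and prevalence
1/151 the PPV is ≈ 2.8% — about four-fold enrichment over the 0.662% base
rate. (Published estimates of this quantity depend on the exact operating
point used, which is why the package reports the operating point alongside
the PPV.)

## Synthetic cohorts

The generator emulates the study design: two groups (default 100 per group)
of five-minute-scale monologues (~60 utterances, ~600 words) plus cognitive
score tables. Utterance counts and morpheme-target lengths are negative
binomial (over-dispersed counts fit natural speech better than Poisson);
words are drawn from a fixed ~130-word Zipf-weighted vocabulary whose
morpheme counts follow the profiler's own rule table. Immediate duplicate
words are redrawn: fluent speech essentially never repeats a word verbatim
in adjacent positions, so exact adjacent duplication is reserved for the
explicit dysfluency injection (without this, high-frequency function words
produce accidental "repetitions" at rates that swamp the injected contrast).

Dysfluencies are injected by hazards — a filled-pause probability per
content token and a repetition probability per utterance (unit length mixed
60/30/10 over 1–3; the duplicated copy is written as a maze annotation, the
recoverable ground truth). Five segment-position multipliers scale both
hazards over the token-quintiles, emulating edge-of-sample dysfluency
elevation. Cognitive scales are normal draws per scale with configurable
group mean shifts.

Default study conditions (chosen once for clinical plausibility): carriers
have a 1.5× filled-pause hazard (0.045 vs 0.030 per token), 1.5× repetition
hazard (0.15 vs 0.10 per utterance), one morpheme shorter mean utterance
length (9 vs 10), stronger first/last-segment dysfluency multipliers, and
+0.5 SD shifts on Organization of Materials, Self-Monitor and Task Monitor.
Ground-truth informative features are recorded in a sidecar file.

What the generator does *not* emulate: syntax, semantics, discourse
structure, speaker-level trait heterogeneity beyond the distributions above,
transcription errors, or any correlation between CGG repeat length and
phenotype severity. Synthetic cohorts are therefore cleaner than real
speech; cross-validated scores on them (F1 ≈ 0.9 at the default conditions)
should be read as validating the machinery, not as performance claims about
real carriers, where published screening performance on comparable designs
is materially lower.

## Validation design

Beyond unit tests and worked examples, the suite checks: detector/oracle
equivalence for repetitions; AUC trapezoid = rank statistic on random score
sets; IG bounds and monotone invariance; fold-partition invariants and
byte-level reproducibility of seeded runs; profiler recovery of generator
hazards (mean filled-pause count vs hazard × token count over 200
replicates); null calibration (20 zero-effect cohorts of 50 per group give
mean pooled CV AUC within [0.4, 0.6]); and effect recovery on cohorts
injecting only the filled-pause hazard and the three cognitive-scale shifts
at magnitudes 1–3 (hazard +0.015 and +9 T-points per magnitude unit):
pooled CV F1 must be non-decreasing in magnitude, and at the largest
magnitude all four direct ground-truth features must rank in the top 10 by
mean information gain. The recovery cohorts deliberately perturb only two
effect axes: derived composite features (e.g. dysfluencies per 100 words)
pool signal across axes, so a recovery criterion phrased over direct
features is only well-posed when the injected axes are few. The largest
magnitude is a stress level (a 2.7 SD cognitive shift), not a clinical
claim. Problem sizes throughout (50–100 per group, 10–20 seeds) were chosen
to make sampling error small relative to the margins being asserted.
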