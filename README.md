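# fxscreen

Computational phenotyping for Fragile X (FX) premutation screening from
spoken-language samples and executive-function self-reports.

The FX premutation (55–200 CGG repeats in *FMR1*) affects roughly 1 in 151
females, most of whom are unaware of their status, and genetic testing is too
resource-intensive for population screening. Female carriers show subtle
linguistic and cognitive phenotypes — more dysfluent speech (filled pauses,
word/phrase repetitions), simpler and shorter utterances, and self-reported
executive-function difficulties. `fxscreen` implements an automated screening
pipeline over these phenotypes:

1. **Linguistic profiling** — parse five-minute monologue transcripts (one
   utterance per line, optional SALT-style parenthesized maze annotations)
   and extract an 88-feature profile: filled pauses, exact repetitions of
   units of any length (only fillers allowed between copies), morpheme-based
   mean length of utterance (MLU), utterance-length distributions, and the
   same measures over five equal-length segments of the sample.
2. **Cognitive profiling** — ingest BRIEF-A-style scale scores (nine clinical
   scales, BRI/MI/GEC composites recomputed by sum convention, a validity
   composite, maternal age and education) into a 15-feature block, giving a
   103-feature comprehensive profile per participant.
3. **Feature selection** — rank features by information gain
   `IG(C, x) = H(C) − H(C | x)` with entropy `H(X) = −Σ p(x) log₂ p(x)`,
   discretizing continuous features by supervised recursive binary splitting
   under the Fayyad–Irani MDL stopping criterion; the non-zero-gain subset is
   the *optimized profile*.
4. **Classification** — stratified 10-fold cross-validation of five standard
   learners (logistic regression, naive Bayes, AdaBoost, decision tree,
   random forest) with z-scoring and selection fitted inside training folds;
   pooled out-of-fold scores give a single ROC curve, pooled confusion counts
   give sensitivity, specificity, accuracy, `MCC` and
   `F1 = 2TP / (2TP + FN + FP)` — all implemented natively.
5. **Screening yield** — convert an operating point to the Bayesian positive
   predictive value `PPV = se·π / (se·π + (1−sp)(1−π))` at population
   prevalence π.

Because no participant data are public, the package includes a first-class
synthetic cohort generator with controllable group contrasts (dysfluency
hazards, utterance-length shifts, cognitive scale shifts, segment-position
multipliers) and ground-truth annotations, so every pipeline stage is
testable end to end.

## Worked example

```python
import fxscreen as fx

sample = """\
She is uh a very uh lovely girl.
(He is) He is John.
What is his name?
Yes.
"""
p = fx.profile_transcript(fx.parse_transcript(sample, participant_id="demo"))
print(int(p["n_filled_pauses"]), int(p["n_repetitions"]), p["mlu"])
```

prints `2 1 3.5`: two filled pauses (`uh`), one phrase-level repetition
(`(He is) He is`), and a mean length of utterance of 3.5 morphemes over the
four utterances. At cohort scale (see `examples/04_cross_validation.py`,
50 participants per group, seed 8):

```
algorithm                F1    AUC    MCC
logistic_regression   0.926  0.970  0.851
naive_bayes           0.860  0.929  0.724
adaboost              0.940  0.976  0.880
decision_tree         0.837  0.840  0.681
random_forest         0.949  0.981  0.900
```

Random forest leads, and `examples/05_screening_ppv.py` shows that a screen
with sensitivity = specificity = 0.81 applied at the 0.662% (1/151) female
carrier prevalence yields a PPV of 2.76% — a roughly four-fold reduction in
confirmatory genetic tests per carrier identified.

The `examples/` directory has one short script per capability: parsing and
profiling, cohort simulation, information-gain selection, cross-validation,
and screening PPV. A thin CLI (`fxscreen simulate|profile|select|run|screen`)
wraps the same functions for shell use.

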