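# Methods

This note documents the models and procedures implemented in `cqarank`,
the parameter defaults and why they were chosen, what the synthetic
benchmark does and does not exercise, and the numerical and design
decisions made where the design was genuinely open.

## Subquestion extraction and categorization

CQA posts bury one or more short questions in a verbose title and
description. Sentences are split deterministically on `. ? !`
terminators (no statistical tokenizer, so the split is identical across
environments); every sentence ending in `?` becomes a subquestion, and a
title with no `?` that opens with a question word is emitted as one
subquestion as well (titles frequently omit the mark).

Categories are assigned by ordered regular expressions over 13 classes.
The ordering resolves overlaps: `how often/frequently` and `how
much/many` are tested before bare `how`, `what amount/percentage/
quantity` before bare `what`, and `whose`/`whom` before `who`. The
`yes-no` class matches a leading auxiliary verb and only anchored at the
sentence start. Classification runs a start-anchored pass over all
classes first, then an any-position pass, and falls back to `others`.
Patterns are shipped as a YAML resource and can be overridden per
domain.

## Distance measures

**Word-sequence DTW.** A sentence is a sequence of words; the cost of
aligning two words is their unit-cost character-level Levenshtein
distance (delegated to the C implementation in `edlib`, with a pure
DP fallback for non-ASCII input). The cumulative recurrence

    f(i,j) = d(w_i, w_j) + min(f(i-1,j-1), f(i-1,j), f(i,j-1)),
    f(0,0) = 0,  f(i,0) = f(0,j) = ∞

is the standard one; `f(m,n)` is the distance. It is symmetric,
non-negative, zero exactly on identical sequences, and verified in the
test suite against exhaustive enumeration of all monotone warping paths
for short sequences.

*Known discrepancy.* The reference worked example this implementation
follows reports a DTW distance of 29 for the question pair quoted in the
README, alongside token counts (5, 12) and stop-word counts (1, 5) that
this implementation reproduces exactly. The stated recurrence yields 78
for that pair, confirmed independently by path enumeration. No
principled variant examined — open-begin/open-end alignment, constant
gap penalties, capped or length-normalized word costs, weighted
insert/delete costs, character-level DTW of the whole sentences, or the
hypothesis that the printed value already includes the ×0.5 concept
re-weighting — reproduces 29. The related reference value 14.5 for the
DTW cross-difference feature is fractional although the recurrence is
integer-valued on these inputs, which suggests the reference values were
produced by an undocumented preprocessing or cost variant. The package
implements the stated recurrence and reports its honest value; the
acceptance suite records the unmet reference value rather than papering
over it.

**Vector-space distance.** Euclidean distance between unigram tf-idf
vectors, with `idf = ln(N/df) + 1` (no smoothing), raw term counts, and
no vector normalization, fitted on the prospective question plus the
questions of its category. Euclidean rather than cosine distance is
deliberate. Out-of-vocabulary tokens are ignored at transform time.
scikit-learn's `TfidfVectorizer` with `norm=None, smooth_idf=False`
implements exactly this variant; the tests check it against
hand-computed vectors.

**Tokenizer.** Lowercase, whitespace split, per-token strip of leading
and trailing punctuation, internal punctuation kept (so `drug/alcohol`
is one token), empty tokens dropped. This convention reproduces the
reference token counts (5, 12) and is used consistently by every module.

**Concept re-weighting.** When the prospective and training question
each contain at least one word of a concept term of the configured
semantic types (default: "organic chemical", "pharmacologic substance"),
the distance is multiplied by a weight `w ∈ (0,1]`, applied exactly
once. The default `w = 0.5` is a configuration choice (no reference
value is published); it is recorded in every run manifest. The overlap
test is word-level, so the multi-word term "alcohol withdrawal" overlaps
the single word "alcohol".

## Concept recognition

A dictionary matcher stands in for a full UMLS/MetaMap pipeline behind a
pluggable interface: greedy longest-match over lowercased,
punctuation-stripped tokens against a TSV lexicon (term → semantic
types; multi-type terms merge), no stemming and no word-sense
disambiguation — determinism on noisy CQA text is worth more here than
recall. A ~50-term toy alcoholism lexicon is bundled for tests and
demos; precomputed annotations from a real concept mapper can be plugged
in via a JSON Lines file keyed by thread id. Because the matcher is not
MetaMap, the concept-overlap feature values of the reference worked
example (3, 3, 0, 4, 5) are not reproducible and are not asserted
anywhere; the concept features are instead validated by set-algebra
oracles.

## Retrieval structure

Per measure, the two smallest concept-weighted distances are retained
(ties broken by corpus order, for run-to-run determinism), and for each
retrieved question the best answer (best-answer flag) and second-best
answer (highest like count among the rest, ties in original order) are
taken. A fully populated category therefore yields 2 × 2 × 2 = 8
candidate triples. Duplicate (Q_t, A_t) pairs retrieved by both measures
are kept as distinct instances — the downstream training table counts
them twice, matching the retrieval contract — with an optional `dedupe`
switch. Buckets are scanned linearly; the intended corpora are
desk-scale (10³–10⁴ threads), so no approximate-nearest-neighbor index
is warranted.

## Features

The 13 features per triple are listed in the README. Decisions worth
recording:

- Stop-word counts use a bundled, versioned ~130-word English list
  (the feature values depend on its exact content, so it ships with the
  package rather than being imported from an external library).
- The concept set-difference features default to the symmetric
  difference `|S_P Δ S_T|`; a one-sided variant (`|S_P \ S_T|`) is
  switchable, since the reference example cannot disambiguate the two
  without the original concept-mapper output.
- Concept features count words of matched terms and use **all** lexicon
  semantic types; the drug-type restriction applies only to retrieval
  re-weighting.
- The cross-distance features use absolute differences; sign carries no
  meaning across measures.

## Re-ranking

Four classifier families are exposed behind one interface, all wrapped
in a standardization step: logistic regression; a linear-kernel SVM
whose decision values are mapped to probabilities by Platt scaling (a
maximum-likelihood 1-D logistic fit, cross-checked in the tests against
a two-parameter grid search); and a single-hidden-layer neural network
(10 units by default) in two variants — cross-entropy objective
(`nnet-entropy`, a classifier) and least-squares objective on 0/1
targets (`nnet-l2`, a regressor whose output is clipped to [0,1]).

The EM-style semi-supervised wrapper assigns **hard** labels to the
unlabeled pool in the E-step (matching a self-training reading of the
procedure), refits on labeled ∪ pseudo-labeled data in the M-step, and
stops when the pseudo-label assignment is unchanged or an iteration cap
is reached. Defaults: 1 iteration (empirically the fixed point is
reached almost immediately on well-separated data, and the paired-run
benchmark shows no gain from more), subsample fraction 1.0 (use the
whole pool; the subsample is seeded when < 1). An empty unlabeled pool
degenerates to supervised training with bitwise-identical predictions.

The decision cutoff is chosen on a 0.01 grid to maximize F1 of the
"valid" class on training data, smallest threshold on ties, with
prediction rule `p ≥ cutoff`. The cutoff — not resampling — is how the
~1:4 class imbalance of the validity labels is handled.

## Evaluation

- **Overall accuracy**: a test question is correct if at least one of
  its candidate triples is predicted valid and truly valid, or if it has
  no truly valid candidate and all candidates are predicted invalid.
- **MRR**: mean of 1/rank of the highest-ranked truly valid candidate;
  with several valid candidates the minimum rank is used. Questions with
  no valid candidate contribute 0 and stay in the denominator by default
  (the pessimistic choice, monotone in ranking quality); a flag excludes
  them.
- **Triple metrics**: precision/recall/F1 with "valid" positive;
  zero-division yields 0 with a warning. Accuracy and ROC are
  deliberately not reported (heavy class imbalance).
- **Cross-validation** groups folds by prospective question so a
  question's candidates never straddle train/test (the conservative
  reading; triple-level folding exists behind a flag but leaks question
  identity). Per fold, the cutoff is selected on the training folds
  only; the unlabeled pool is shared across folds for the
  semi-supervised variant. Accuracy and MRR are averaged over folds;
  precision/recall/F1 are computed from pooled confusion counts.
- **Information gain** uses base-2 entropy with continuous features cut
  into up to 10 equal-frequency bins (bin count configurable); it is
  checked against a longhand entropy computation.

## Synthetic benchmark

The generator emulates the data regime of a categorized health-CQA
archive at desk scale: questions are category templates over a
pseudo-word vocabulary with concept terms injected from the bundled
lexicon (rate 0.6 in questions, 0.3 in answers); each base question has
a planted paraphrase in the corpus with probability 0.7 (word
substitution at rate 0.1, deletion at 0.05), 2–4 answers per thread
with one best answer and uniform like counts; triple validity is
sampled from a logistic model over the z-scored 13 features with
Gaussian noise (σ = 0.5), with the intercept calibrated so the
triple-level valid rate is 0.2 (mirroring the ~19% valid rate typical of
manually annotated candidate triples). The strongest generating
coefficients are, in order of magnitude, the stop-word count of Q_p
(+2.6), the length of Q_p (−2.2), the DTW distance (−1.8), and the
question concept overlap (+1.4) — short, concept-rich questions close to
their retrieved question tend to have valid answers — mirroring the
empirically important features of this problem domain.

What passing the synthetic suites shows: the retrieval machinery ranks
planted paraphrases first under DTW (≥ 90% at noise 0.1), the feature
pipeline is numerically correct, the logistic family recovers the signs
of the three strongest generating coefficients (50/50 seeded runs at 50
base threads), and one EM iteration does not hurt — and on average
helps — test F1 when only ~15% of the non-test questions are labeled
(mirroring a ~1:6 labeled:unlabeled regime). What it does **not** show:
performance on real CQA text, where paraphrases are not word-level edits,
concept recognition is noisy, and validity is not a function of these 13
features alone. The headline metrics of the original alcoholism case
study require its 4,216-thread corpus and are out of scope here.

Problem sizes used by the test and acceptance suites (chosen for a
single-CPU desk run): 25–60 base threads per generated corpus, 50 runs
for sign recovery, 20 paired runs for the EM-vs-supervised comparison;
the full suite completes in a few minutes.

## Reproducibility

Every source of randomness flows from an explicit integer seed
(`numpy.random.default_rng`); generation, retrieval, training, fold
assignment, and the EM subsample are all deterministic given the seed.
Pipeline runs write a manifest (config hash, seed, package version);
rerunning with the same manifest reproduces the report exactly.

## Known limitations

- The worked-example DTW reference value is not reproduced (see the
  discrepancy note above); all other reference values of that example
  that are independent of the concept mapper are.
- The dictionary matcher has no disambiguation and no concept
  hierarchy; recall is bounded by the lexicon.
- The `nnet-l2` probability is a clipped regression output, not a
  calibrated probability; ranking quality, not calibration, is what the
  pipeline consumes.
- EM with discriminative base learners has no convergence guarantee;
  the iteration cap (default 1) is the practical stopping rule.
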