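# cqarank

Answer retrieval and semi-supervised re-ranking for consumer-health
community question answering (CQA).

On CQA sites such as health forums, many posted questions go unanswered
even though near-duplicate questions have already been resolved
elsewhere in the archive. `cqarank` implements a two-phase pipeline that
answers a new question from a corpus of previously resolved
question-answer threads, developed around an alcoholism case study but
applicable to any health-domain CQA archive:

1. **Candidate extraction (rule-based).** Verbose post titles and
   descriptions are reduced to short *subquestions*, each assigned by
   ordered question-word regexes to one of 13 categories (`yes-no`,
   `what-quantity`, `how-frequent`, `when`, `why`, `how`, `where`,
   `who`, `whose`, `whom`, `what`, `which`, `others`). Within its
   category, a prospective subquestion Q_p is compared to every resolved
   question Q_t under two distances:
   - **DTW**: dynamic time warping over word sequences,
     `f(i,j) = d(w_i, w_j) + min(f(i-1,j-1), f(i-1,j), f(i,j-1))` with
     `f(0,0)=0`, `f(i,0)=f(0,j)=∞`, where `d` is the character-level
     Levenshtein distance between words — word order matters, but
     insertions such as relative clauses are tolerated;
   - **VS**: Euclidean distance between unigram tf-idf vectors
     (`idf = ln(N/df) + 1`, raw counts, no normalization), fitted on the
     category's questions.

   When both questions mention a word from drug-related concept types
   ("organic chemical", "pharmacologic substance") recognized by a
   pluggable lexicon matcher (a stand-in for MetaMap/UMLS), the distance
   is multiplied by a weight `w = 0.5` — shared drug names are strong
   evidence of the same information need. The 2 closest questions per
   measure, with the best and second-best answer each (best-answer flag
   first, then like counts), yield **8 candidate triples (Q_p, Q_t,
   A_t)** per prospective question.

2. **Answer re-ranking (learned).** Each triple is described by 13
   features (text lengths, stop-word counts, VS and DTW distances and
   their cross-differences against the answer, and concept-overlap
   counts between the recognized concept sets S_P, S_T, S_A) and
   classified valid/invalid. Because labeled triples are expensive, an
   EM-style semi-supervised wrapper augments any of four classifier
   families (`nnet-entropy`, `nnet-l2`, `svm-linear` with Platt-scaled
   probabilities, `logistic`): fit on the labeled set, pseudo-label the
   unlabeled pool, refit, repeat until the pseudo-labels converge
   (default: one iteration). The decision cutoff on the predicted
   probability maximizes F1 on training data. Evaluation reports
   question-level overall accuracy and mean reciprocal rank (MRR),
   triple-level precision/recall/F1 under question-grouped 10-fold
   cross-validation, and information-gain feature rankings.

A seeded synthetic-corpus generator plants near-duplicate questions and
samples triple validity from a known logistic model over the same 13
features, so every stage is testable end to end with no external data.

## Worked example

```python
from cqarank import tokenize, dtw_distance, fit_tfidf, vs_distance, load_stoplist

q_p = "Anxiety medication for drug/alcohol addiction?"
q_t = ("Is chlordiazepoxide/librium a good medication for alcohol withdrawal "
       "and the associated anxiety?")

tp, tt = tokenize(q_p), tokenize(q_t)
print(len(tp), len(tt))                      # 5 12
stops = load_stoplist()
print(stops.count_in(tp), stops.count_in(tt))  # 1 5
print(dtw_distance(tp, tt))                  # 78.0
model = fit_tfidf([q_p, q_t])
print(round(vs_distance(model, q_p, q_t), 4))  # 5.6155
```

The token counts (5 and 12) are the lengths of Q_p and Q_t; the stop
counts (1 and 5) use the bundled stop list ("for"; "is a for and the");
78.0 is the cumulative DTW cost of the cheapest monotone alignment of
the two word sequences. Concept re-weighting in action:

```python
from cqarank.concept_recognition import bundled_lexicon, recognize, filter_types
from cqarank.similarity import DistanceValue, concept_weight, DTW

q1 = "Is chlordiazepoxide a good detox medication?"
q2 = "Does chlordiazepoxide help with alcohol detox?"
d = dtw_distance(tokenize(q1), tokenize(q2))
lex, types = bundled_lexicon(), ("organic chemical", "pharmacologic substance")
w = concept_weight(DistanceValue(d, DTW),
                   filter_types(recognize(q1, lex), types),
                   filter_types(recognize(q2, lex), types), 0.5)
print(d, "->", w.value)   # 23.0 -> 11.5  (shared drug term "chlordiazepoxide")
```

End to end on a synthetic corpus:

```bash
cqarank synth --seed 7 --n-threads 40 --out demo
# wrote 60 threads, 326 gold labels
cqarank evaluate --config demo_cfg.yaml   # corpus/gold paths, family: nnet-l2
```

prints (per-fold detail elided):

```json
{
  "overall_accuracy": 0.6833,
  "mrr": 0.3533,
  "precision": 0.6105,
  "recall": 0.6170,
  "f1": 0.6138,
  "confusion": {"tp": 58, "fp": 37, "tn": 349, "fn": 36}
}
```

`overall_accuracy` is the fraction of test questions for which the
re-ranker flags at least one truly valid answer (or correctly flags
nothing when no candidate is valid); `mrr` averages 1/rank of the first
truly valid answer in the model's ordering; the remaining values are
triple-level classification metrics with "valid" as the positive class.

Other subcommands: `extract` (categorized subquestions), `retrieve`
(candidate table for one question), `featurize` (13-column feature
matrix), `feature-rank` (information-gain table).

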