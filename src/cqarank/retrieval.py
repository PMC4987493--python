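"""Phase-I candidate-answer retrieval.

For a prospective subquestion, scan every training question in the same
question-word category under both distance measures (DTW and
vector-space), apply concept re-weighting, keep the two closest
questions per measure, and take each question's two best answers.  With
a full bucket this yields 2 measures x 2 questions x 2 answers = 8
candidate triples per prospective question.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

from .concept_recognition import ConceptLexicon, ConceptSet, filter_types, recognize
from .corpus_io import Answer, QAThread
from .question_extraction import QuestionClassifier, SubQuestion, extract_subquestions
from .similarity import (
    DTW,
    VECTOR_SPACE,
    DistanceValue,
    concept_weight,
    dtw_distance,
    fit_tfidf,
    tokenize,
    vs_distance,
)

logger = logging.getLogger(__name__)

MEASURES = (DTW, VECTOR_SPACE)

DEFAULT_SEMANTIC_TYPES = ("organic chemical", "pharmacologic substance")


@dataclass(frozen=True)
class RetrievalConfig:
    """Tunable parameters of candidate retrieval.

    ``concept_weight_value`` is the multiplier applied to a distance when
    the two questions share a word from the configured semantic types
    (1.0 disables re-weighting).
    """

    concept_weight_value: float = 0.5
    semantic_types: tuple[str, ...] = DEFAULT_SEMANTIC_TYPES
    questions_per_measure: int = 2
    answers_per_question: int = 2
    dedupe: bool = False


@dataclass(frozen=True)
class IndexedQuestion:
    """One training subquestion in a category bucket."""

    position: int  # order of appearance in the corpus (tie-break key)
    thread_id: str
    text: str
    thread: QAThread


@dataclass
class CategoryIndex:
    """Per-category buckets of training subquestions."""

    buckets: dict[str, list[IndexedQuestion]] = field(default_factory=dict)

    def bucket(self, category: str) -> list[IndexedQuestion]:
        return self.buckets.get(category, [])

    def __len__(self) -> int:
        return sum(len(b) for b in self.buckets.values())


@dataclass(frozen=True)
class Triple:
    """(Q_p, Q_t, A_t): the unit the re-ranker classifies valid/invalid."""

    prospective_id: str
    training_id: str
    answer_index: int
    q_p: str
    q_t: str
    a_t: str
    measure: str
    rank_of_question: int
    answer_rank: int
    distance: float
    concept_weighted: bool = False
    label: str | None = None

    def with_label(self, label: str | None) -> "Triple":
        return replace(self, label=label)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.prospective_id, self.training_id, self.answer_index)


def build_index(
    corpus: Sequence[QAThread], classifier: QuestionClassifier | None = None
) -> CategoryIndex:
    """Extract and categorize subquestions for every thread.

    Threads yielding no subquestion are skipped with a logged warning;
    a thread with several subquestions is indexed once per subquestion
    (the answers attach to the thread).
    """
    index = CategoryIndex()
    position = 0
    for thread in corpus:
        subquestions = extract_subquestions(thread, classifier)
        if not subquestions:
            logger.warning("thread %s has no detectable subquestion; skipped", thread.thread_id)
            continue
        for sq in subquestions:
            index.buckets.setdefault(sq.category, []).append(
                IndexedQuestion(position, thread.thread_id, sq.text, thread)
            )
            position += 1
    return index


def top_answers(thread: QAThread, k: int) -> list[Answer]:
    """The best answer first, then remaining answers by descending likes.

    Ties in likes keep original answer order (stable sort); at most k
    answers are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    best = [a for a in thread.answers if a.is_best]
    rest = [a for a in thread.answers if not a.is_best]
    rest.sort(key=lambda a: -a.likes)  # stable: ties keep original order
    return (best + rest)[:k]


def _concept_set(text: str, lexicon: ConceptLexicon, types: Sequence[str]) -> ConceptSet:
    return filter_types(recognize(text, lexicon), types)


def candidates(
    q_p: SubQuestion,
    index: CategoryIndex,
    lexicon: ConceptLexicon,
    config: RetrievalConfig = RetrievalConfig(),
) -> list[Triple]:
    """Candidate triples for one prospective subquestion.

    For each measure: concept-weighted distance to every same-category
    training question (the prospective question never retrieves itself),
    the ``questions_per_measure`` smallest kept (ties broken by corpus
    order), and ``answers_per_question`` answers per retrieved question.
    Duplicate (Q_t, A_t) pairs across measures are kept as distinct
    instances unless ``dedupe`` is set.
    """
    bucket = [iq for iq in index.bucket(q_p.category) if iq.thread_id != q_p.thread_id]
    if not bucket:
        logger.warning(
            "no training question in category %r for thread %s; unanswerable",
            q_p.category,
            q_p.thread_id,
        )
        return []

    cs_p = _concept_set(q_p.text, lexicon, config.semantic_types)
    cs_t = {iq.position: _concept_set(iq.text, lexicon, config.semantic_types) for iq in bucket}

    # tf-idf model over the prospective question plus its category's questions
    model = fit_tfidf([q_p.text] + [iq.text for iq in bucket])
    vectors = model.vectorizer.transform([q_p.text] + [iq.text for iq in bucket]).toarray()
    vs_values = ((vectors[1:] - vectors[0]) ** 2).sum(axis=1) ** 0.5
    tokens_p = tokenize(q_p.text)

    triples: list[Triple] = []
    for measure in MEASURES:
        scored: list[tuple[float, bool, IndexedQuestion]] = []
        for pos, iq in enumerate(bucket):
            if measure == DTW:
                tokens_t = tokenize(iq.text)
                if not tokens_p or not tokens_t:
                    continue
                raw = DistanceValue(dtw_distance(tokens_p, tokens_t), DTW)
            else:
                raw = DistanceValue(float(vs_values[pos]), VECTOR_SPACE)
            weighted = concept_weight(raw, cs_p, cs_t[iq.position], config.concept_weight_value)
            scored.append((weighted.value, weighted.concept_weighted, iq))
        scored.sort(key=lambda item: (item[0], item[2].position))  # stable tie-break
        for q_rank, (dist, weighted_flag, iq) in enumerate(
            scored[: config.questions_per_measure], start=1
        ):
            for a_rank, answer in enumerate(
                top_answers(iq.thread, config.answers_per_question), start=1
            ):
                triples.append(
                    Triple(
                        prospective_id=q_p.thread_id,
                        training_id=iq.thread_id,
                        answer_index=iq.thread.answers.index(answer),
                        q_p=q_p.text,
                        q_t=iq.text,
                        a_t=answer.text,
                        measure=measure,
                        rank_of_question=q_rank,
                        answer_rank=a_rank,
                        distance=dist,
                        concept_weighted=weighted_flag,
                    )
                )
    if config.dedupe:
        seen: set[tuple[str, str, int]] = set()
        unique = []
        for t in triples:
            if t.key not in seen:
                seen.add(t.key)
                unique.append(t)
        triples = unique
    return triples
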