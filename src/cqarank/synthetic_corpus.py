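"""Seeded generator of synthetic QA corpora with planted structure.

Every pipeline stage needs data with known ground truth: questions with
categories, planted near-duplicate questions (so retrieval has a right
answer), concept terms injected from the bundled lexicon (so the
concept features are non-trivial), and triple validity sampled from a
known logistic model over the same 13 features the pipeline computes —
which makes the re-ranker's learning target well-posed by construction
and the generating coefficients recoverable.

Templates over a synthetic pseudo-word vocabulary are used; realistic
English is not attempted, since the algorithms under test operate on
token sequences, not on meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .concept_recognition import ConceptLexicon, bundled_lexicon
from .corpus_io import Answer, QAThread, TripleAnnotation, INVALID, VALID
from .features import FEATURE_NAMES, extract_features, load_stoplist
from .question_extraction import extract_subquestions
from .retrieval import RetrievalConfig, Triple, build_index, candidates
from .similarity import fit_tfidf

# Default validity model on z-scored features.  The strongest signals are
# the stop-word count of Q_p (f3), its length (f1), the DTW distance (f7)
# and the concept overlap of the two questions (f9): short, concept-rich
# questions close to their retrieved question tend to have valid answers.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "f1": -2.2,
    "f2": -0.1,
    "f3": 2.6,
    "f4": 0.1,
    "f5": -0.3,
    "f6": -0.1,
    "f7": -1.8,
    "f8": -0.1,
    "f9": 1.4,
    "f10": 0.2,
    "f11": -0.1,
    "f12": 0.1,
    "f13": 0.1,
}

_OPENERS = {
    "yes-no": ("can", "is", "does", "should"),
    "what": ("what is", "what are"),
    "how": ("how do", "how can"),
    "why": ("why do", "why is"),
    "when": ("when should", "when do"),
}

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"


class GenerationError(Exception):
    """The generator configuration is infeasible."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions of the synthetic study regime.

    Defaults emulate a desk-scale version of a consumer-health CQA
    corpus: ~100 base threads across five question categories, most
    prospective questions having a planted in-corpus paraphrase, 2-4
    answers per thread, and a ~20% triple-level valid rate.
    """

    seed: int
    n_threads: int = 100
    categories: tuple[str, ...] = tuple(_OPENERS)
    vocab_size: int = 60
    near_duplicate_rate: float = 0.7
    paraphrase_noise: float = 0.1
    min_answers: int = 2
    max_answers: int = 4
    max_likes: int = 10
    concept_injection_rate: float = 0.6
    valid_rate: float = 0.2
    noise_scale: float = 0.5
    coefficients: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))

    def __post_init__(self) -> None:
        for name, p in (
            ("near_duplicate_rate", self.near_duplicate_rate),
            ("paraphrase_noise", self.paraphrase_noise),
            ("concept_injection_rate", self.concept_injection_rate),
            ("valid_rate", self.valid_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise GenerationError(f"{name} must be in [0, 1], got {p}")
        if self.vocab_size < 5:
            raise GenerationError("vocabulary must have at least 5 words")
        if self.n_threads < 2:
            raise GenerationError("need at least 2 threads")
        if not set(self.categories) <= set(_OPENERS):
            raise GenerationError(f"unknown categories {set(self.categories) - set(_OPENERS)}")


@dataclass
class SyntheticCorpus:
    """A generated corpus with its gold labels and true validity model."""

    threads: list[QAThread]
    annotations: list[TripleAnnotation]
    triples: list[Triple]
    X: np.ndarray  # 13-feature matrix aligned with triples
    y: np.ndarray  # 1 = valid, aligned with triples
    coefficients: dict[str, float]
    planted_paraphrase: dict[str, str]  # base thread id -> paraphrase thread id


def _make_vocabulary(rng: np.random.Generator, size: int) -> list[str]:
    words: list[str] = []
    seen = set()
    while len(words) < size:
        syllables = rng.integers(2, 4)
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(syllables)
        )
        if word not in seen:
            seen.add(word)
            words.append(word)
    return words


def _question_text(
    rng: np.random.Generator,
    category: str,
    vocabulary: Sequence[str],
    concept_terms: Sequence[str],
    injection_rate: float,
) -> str:
    opener = _OPENERS[category][rng.integers(len(_OPENERS[category]))]
    n_words = int(rng.integers(3, 8))
    words = [vocabulary[i] for i in rng.integers(0, len(vocabulary), n_words)]
    if rng.random() < injection_rate:
        position = int(rng.integers(0, len(words) + 1))
        words.insert(position, concept_terms[rng.integers(len(concept_terms))])
    return opener + " " + " ".join(words) + "?"


def _paraphrase(
    rng: np.random.Generator, text: str, vocabulary: Sequence[str], noise: float
) -> str:
    words = text.rstrip("?").split()
    kept: list[str] = list(words[:2])  # keep the opener so the category is stable
    for word in words[2:]:
        roll = rng.random()
        if roll < noise / 2:
            continue  # deletion
        if roll < noise:
            kept.append(vocabulary[rng.integers(len(vocabulary))])
        else:
            kept.append(word)
    if len(kept) < 3:
        kept = list(words)
    return " ".join(kept) + "?"


def _answer(
    rng: np.random.Generator,
    vocabulary: Sequence[str],
    concept_terms: Sequence[str],
    injection_rate: float,
) -> str:
    n_words = int(rng.integers(8, 20))
    words = [vocabulary[i] for i in rng.integers(0, len(vocabulary), n_words)]
    if rng.random() < injection_rate:
        position = int(rng.integers(0, len(words) + 1))
        words.insert(position, concept_terms[rng.integers(len(concept_terms))])
    return " ".join(words) + "."


def _make_thread(
    rng: np.random.Generator,
    thread_id: str,
    question: str,
    config: GeneratorConfig,
    vocabulary: Sequence[str],
    concept_terms: Sequence[str],
) -> QAThread:
    n_answers = int(rng.integers(config.min_answers, config.max_answers + 1))
    answers = [
        Answer(
            text=_answer(rng, vocabulary, concept_terms, config.concept_injection_rate / 2),
            likes=int(rng.integers(0, config.max_likes + 1)),
        )
        for _ in range(n_answers)
    ]
    best = int(rng.integers(n_answers))
    answers[best] = Answer(answers[best].text, is_best=True, likes=answers[best].likes)
    return QAThread(thread_id=thread_id, title=question, description="", answers=answers)


def generate(
    config: GeneratorConfig,
    lexicon: ConceptLexicon | None = None,
    retrieval_config: RetrievalConfig | None = None,
) -> SyntheticCorpus:
    """Generate a corpus, its candidate triples, and gold validity labels.

    Fully reproducible from ``config.seed``: the corpus bytes, the
    retrieval output, and the sampled labels are all deterministic.
    """
    rng = np.random.default_rng(config.seed)
    lexicon = lexicon or bundled_lexicon()
    retrieval_config = retrieval_config or RetrievalConfig()
    vocabulary = _make_vocabulary(rng, config.vocab_size)
    concept_terms = sorted(lexicon.entries)

    threads: list[QAThread] = []
    planted: dict[str, str] = {}
    for i in range(config.n_threads):
        category = config.categories[int(rng.integers(len(config.categories)))]
        question = _question_text(
            rng, category, vocabulary, concept_terms, config.concept_injection_rate
        )
        base_id = f"q{i:04d}"
        threads.append(_make_thread(rng, base_id, question, config, vocabulary, concept_terms))
        if rng.random() < config.near_duplicate_rate:
            partner_id = f"q{i:04d}p"
            paraphrase = _paraphrase(rng, question, vocabulary, config.paraphrase_noise)
            threads.append(
                _make_thread(rng, partner_id, paraphrase, config, vocabulary, concept_terms)
            )
            planted[base_id] = partner_id

    # phase-I retrieval over the generated corpus
    index = build_index(threads)
    stops = load_stoplist()
    tfidf_by_category = {
        category: fit_tfidf([iq.text for iq in bucket])
        for category, bucket in index.buckets.items()
    }
    triples: list[Triple] = []
    for thread in threads:
        for sq in extract_subquestions(thread):
            triples.extend(candidates(sq, index, lexicon, retrieval_config))

    if not triples:
        raise GenerationError("configuration produced no candidate triples")

    X = np.vstack(
        [
            extract_features(
                t, tfidf_by_category[_category_of(t, index)], lexicon, stops
            ).as_array()
            for t in triples
        ]
    )

    # gold validity from the configured logistic model over z-scored features
    beta = np.array([config.coefficients.get(name, 0.0) for name in FEATURE_NAMES])
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    z = (X - mean) / std

    # one label per unique triple key (the same candidate can be emitted
    # by both measures; its validity must not depend on the measure)
    keys = [t.key for t in triples]
    first_row: dict[tuple, int] = {}
    for row, key in enumerate(keys):
        first_row.setdefault(key, row)
    unique_keys = list(first_row)
    scores = z @ beta
    noise_of_key = dict(
        zip(unique_keys, rng.normal(0.0, config.noise_scale, size=len(unique_keys)))
    )
    # calibrate the intercept so the *triple-level* valid rate hits the
    # target (the same candidate emitted by both measures counts twice,
    # exactly as it does in the downstream training table)
    row_scores = np.array([scores[first_row[key]] + noise_of_key[key] for key in keys])

    def mean_rate(intercept: float) -> float:
        return float(expit(intercept + row_scores).mean()) - config.valid_rate

    intercept = brentq(mean_rate, -50.0, 50.0)
    draws = rng.random(len(unique_keys))
    label_of_key = {
        key: VALID
        if draw < expit(intercept + scores[first_row[key]] + noise_of_key[key])
        else INVALID
        for key, draw in zip(unique_keys, draws)
    }

    annotations = [
        TripleAnnotation(key[0], key[1], key[2], label_of_key[key]) for key in unique_keys
    ]
    triples = [t.with_label(label_of_key[t.key]) for t in triples]
    y = np.array([1 if t.label == VALID else 0 for t in triples])

    return SyntheticCorpus(
        threads=threads,
        annotations=annotations,
        triples=triples,
        X=X,
        y=y,
        coefficients=dict(config.coefficients),
        planted_paraphrase=planted,
    )


def _category_of(triple: Triple, index) -> str:
    for category, bucket in index.buckets.items():
        for iq in bucket:
            if iq.thread_id == triple.prospective_id and iq.text == triple.q_p:
                return category
    raise KeyError(f"prospective question of {triple.key} not in index")


@dataclass
class BenchmarkSplit:
    """Question-grouped labeled / unlabeled / test partition of the triples."""

    labeled_rows: np.ndarray
    unlabeled_rows: np.ndarray
    test_rows: np.ndarray


def benchmark_split(
    corpus: SyntheticCorpus,
    labeled_fraction: float,
    seed: int,
    test_fraction: float = 0.2,
) -> BenchmarkSplit:
    """Split triples by question into labeled, unlabeled pool, and test.

    ``test_fraction`` of the questions form the held-out test set; of
    the remainder, ``labeled_fraction`` keep their gold labels and the
    rest become the unlabeled pool (labels hidden).  The three row sets
    are disjoint and exhaustive.
    """
    if not 0.0 < labeled_fraction <= 1.0:
        raise ValueError("labeled_fraction must be in (0, 1]")
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    qids = [t.prospective_id for t in corpus.triples]
    unique = list(dict.fromkeys(qids))
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    n_test = int(round(test_fraction * len(order)))
    test_q = set(order[:n_test])
    remainder = order[n_test:]
    n_labeled = max(1, int(round(labeled_fraction * len(remainder))))
    labeled_q = set(remainder[:n_labeled])
    unlabeled_q = set(remainder[n_labeled:])
    rows = np.arange(len(corpus.triples))
    of = np.array(qids)
    return BenchmarkSplit(
        labeled_rows=rows[np.isin(of, list(labeled_q))],
        unlabeled_rows=rows[np.isin(of, list(unlabeled_q))],
        test_rows=rows[np.isin(of, list(test_q))],
    )
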