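"""Sentence distance measures for question retrieval.

Two measures are implemented:

* a dynamic-time-warping (DTW) distance over word sequences, where the
  cost of aligning two words is their character-level Levenshtein
  distance — this respects word order while tolerating insertions such
  as relative clauses; and
* a vector-space distance: Euclidean distance between unigram tf-idf
  vectors (idf = ln(N/df) + 1, raw term counts, no vector
  normalization), fitted on the question set of one category.

Either distance can be re-weighted when the two texts share a word
belonging to configured medical semantic types (e.g. "organic chemical",
"pharmacologic substance"): sharing a drug or chemical name is strong
evidence of the same information need, so the distance is multiplied by
a weight w in (0, 1].
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

try:  # fast C implementation for character-level edit distance
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

DTW = "dtw"
VECTOR_SPACE = "vector-space"

_STRIP = string.punctuation


def tokenize(text: str) -> list[str]:
    """Canonical tokenizer used by every module.

    Lowercase, split on whitespace, strip leading/trailing punctuation
    per token, keep internal punctuation ("drug/alcohol" is one token),
    drop empty tokens.
    """
    tokens = []
    for raw in text.lower().split():
        token = raw.strip(_STRIP)
        if token:
            tokens.append(token)
    return tokens


def _levenshtein_dp(a: str, b: str) -> int:
    # two-row DP fallback; also the reference for non-ASCII inputs
    if len(a) < len(b):
        a, b = b, a
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(
                min(previous[j] + 1, current[j - 1] + 1, previous[j - 1] + (ca != cb))
            )
        previous = current
    return previous[-1]


def levenshtein(a: str, b: str) -> int:
    """Unit-cost character-level edit distance (insert/delete/substitute)."""
    if not a or not b:
        return max(len(a), len(b))
    if a == b:
        return 0
    if _HAVE_EDLIB and a.isascii() and b.isascii():
        return edlib.align(a, b, task="distance")["editDistance"]
    return _levenshtein_dp(a, b)


def dtw_distance(s1: Sequence[str], s2: Sequence[str]) -> float:
    """Cumulative DTW distance between two word sequences.

    f(i,j) = d(w_i, w_j) + min(f(i-1,j-1), f(i-1,j), f(i,j-1)) with
    f(0,0) = 0 and f(i,0) = f(0,j) = infinity, where d is the
    character-level Levenshtein distance; returns f(m,n).
    """
    if not s1 or not s2:
        raise ValueError("dtw_distance requires two non-empty word sequences")
    m, n = len(s1), len(s2)
    cost_cache: dict[tuple[str, str], int] = {}

    def cost(a: str, b: str) -> int:
        key = (a, b)
        if key not in cost_cache:
            cost_cache[key] = levenshtein(a, b)
        return cost_cache[key]

    f = np.full((m + 1, n + 1), np.inf)
    f[0, 0] = 0.0
    for i in range(1, m + 1):
        wi = s1[i - 1]
        for j in range(1, n + 1):
            f[i, j] = cost(wi, s2[j - 1]) + min(f[i - 1, j - 1], f[i - 1, j], f[i, j - 1])
    return float(f[m, n])


@dataclass
class TfidfModel:
    """Unigram tf-idf model fitted on one category's question set.

    Wraps a scikit-learn vectorizer configured for the documented
    variant: raw term counts times idf = ln(N/df) + 1, no smoothing, no
    vector normalization.  Out-of-vocabulary tokens are ignored at
    transform time.
    """

    vectorizer: TfidfVectorizer
    n_documents: int

    @property
    def vocabulary(self) -> dict[str, int]:
        return dict(self.vectorizer.vocabulary_)

    @property
    def idf(self) -> dict[str, float]:
        idf = self.vectorizer.idf_
        return {term: float(idf[index]) for term, index in self.vectorizer.vocabulary_.items()}

    def vector(self, text: str) -> np.ndarray:
        return self.vectorizer.transform([text]).toarray()[0]


def fit_tfidf(questions: Sequence[str]) -> TfidfModel:
    """Fit the tf-idf model on a non-empty, ordered set of questions."""
    if not questions:
        raise ValueError("fit_tfidf requires at least one question")
    vectorizer = TfidfVectorizer(
        analyzer=tokenize,
        norm=None,
        smooth_idf=False,
        sublinear_tf=False,
    )
    vectorizer.fit(list(questions))
    return TfidfModel(vectorizer=vectorizer, n_documents=len(questions))


def vs_distance(model: TfidfModel, a: str, b: str) -> float:
    """Euclidean distance between the tf-idf vectors of two texts."""
    va, vb = model.vector(a), model.vector(b)
    return float(np.linalg.norm(va - vb))


@dataclass(frozen=True)
class DistanceValue:
    """A non-negative sentence distance and how it was obtained."""

    value: float
    measure: str
    concept_weighted: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("distance must be non-negative")
        if self.measure not in (DTW, VECTOR_SPACE):
            raise ValueError(f"unknown measure {self.measure!r}")


def concept_weight(dist: DistanceValue, cs1, cs2, w: float) -> DistanceValue:
    """Multiply a distance by w when the two concept sets share a word.

    ``cs1`` and ``cs2`` are :class:`~cqarank.concept_recognition.ConceptSet`
    objects already filtered to the configured semantic types; overlap is
    word-level (any single word of a concept term occurring in both).
    """
    if w <= 0:
        raise ValueError("concept weight must be positive")
    if cs1.words & cs2.words:
        return DistanceValue(dist.value * w, dist.measure, concept_weighted=True)
    return DistanceValue(dist.value, dist.measure, concept_weighted=False)
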