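"""The 13-dimensional feature vector of one candidate triple.

General features (1-8) describe the texts and their distances; concept
features (9-13) compare the medical-concept word sets S_P, S_T, S_A
recognized in the prospective question, the training question, and the
training answer.

========  =====================================================
feature   definition
========  =====================================================
f1        word count of Q_p
f2        word count of Q_t
f3        stop words in Q_p
f4        stop words in Q_t
f5        VS(Q_p, Q_t)
f6        |VS(Q_p, A_t) - VS(Q_t, A_t)|
f7        DTW(Q_p, Q_t)
f8        |DTW(Q_p, A_t) - DTW(Q_t, A_t)|
f9        |words(S_P) ∩ words(S_T)|
f10       |words(S_P) ∩ words(S_A)|
f11       1 if the overlap sets (S_P∩S_T) and (S_P∩S_A) differ
f12       |words(S_P) Δ words(S_T)|  (symmetric difference)
f13       |words(S_P) Δ words(S_A)|
========  =====================================================

Concept features count *words* of the matched concept terms, so a
multi-word term contributes each of its words.  The set differences
default to symmetric (one-sided available via ``symmetric_difference=False``,
which counts ``S_P \\ S_T`` only).  Concept sets use all lexicon semantic
types; the restriction to drug-related types applies only to retrieval
re-weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .concept_recognition import ConceptLexicon, recognize
from .retrieval import Triple
from .similarity import TfidfModel, dtw_distance, tokenize, vs_distance

FEATURE_NAMES = tuple(f"f{i}" for i in range(1, 14))


class FeatureError(Exception):
    """A triple's texts cannot be featurized."""


@dataclass(frozen=True)
class StopList:
    """A versioned set of lowercase stop words."""

    words: frozenset[str]

    def count_in(self, tokens: list[str]) -> int:
        return sum(token in self.words for token in tokens)

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)


def load_stoplist(path: str | Path | None = None) -> StopList:
    """The bundled ~130-word English stop list (or a user-supplied file)."""
    if path is None:
        text = resources.files("cqarank.data").joinpath("stopwords.txt").read_text("utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    words = frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )
    return StopList(words)


@dataclass(frozen=True)
class FeatureVector:
    """The 13 features of one triple, in fixed order f1..f13."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 13:
            raise ValueError("a feature vector has exactly 13 components")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def __getitem__(self, index: int) -> float:
        return self.values[index]


def extract_features(
    triple: Triple,
    tfidf: TfidfModel,
    lexicon: ConceptLexicon,
    stops: StopList,
    symmetric_difference: bool = True,
) -> FeatureVector:
    """Compute the 13 features of one triple; deterministic, all finite."""
    if not triple.q_p.strip() or not triple.q_t.strip() or not triple.a_t.strip():
        raise FeatureError(f"empty text in triple {triple.key}")

    tokens_p = tokenize(triple.q_p)
    tokens_t = tokenize(triple.q_t)
    tokens_a = tokenize(triple.a_t)
    if not tokens_p or not tokens_t or not tokens_a:
        raise FeatureError(f"no tokens in triple {triple.key}")

    f1 = float(len(tokens_p))
    f2 = float(len(tokens_t))
    f3 = float(stops.count_in(tokens_p))
    f4 = float(stops.count_in(tokens_t))
    f5 = vs_distance(tfidf, triple.q_p, triple.q_t)
    f6 = abs(vs_distance(tfidf, triple.q_p, triple.a_t) - vs_distance(tfidf, triple.q_t, triple.a_t))
    f7 = dtw_distance(tokens_p, tokens_t)
    f8 = abs(dtw_distance(tokens_p, tokens_a) - dtw_distance(tokens_t, tokens_a))

    s_p = recognize(triple.q_p, lexicon).words
    s_t = recognize(triple.q_t, lexicon).words
    s_a = recognize(triple.a_t, lexicon).words

    overlap_pt = s_p & s_t
    overlap_pa = s_p & s_a
    f9 = float(len(overlap_pt))
    f10 = float(len(overlap_pa))
    f11 = float(overlap_pt != overlap_pa)
    if symmetric_difference:
        f12 = float(len(s_p ^ s_t))
        f13 = float(len(s_p ^ s_a))
    else:
        f12 = float(len(s_p - s_t))
        f13 = float(len(s_p - s_a))

    return FeatureVector((f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13))
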