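"""Dictionary-based recognition of medical concept terms.

A full UMLS/MetaMap pipeline needs a licensed vocabulary and a running
service; at the scale of this package the same role — mapping surface
text to concept terms with semantic types — is played by a pluggable
recognizer whose default is a greedy longest-match dictionary matcher
over a TSV lexicon (term -> semantic type).  Output from a real concept
mapper can be plugged in via a precomputed-annotations JSON Lines file
keyed by thread id.

Matching is on lowercased, punctuation-stripped token sequences with no
stemming, which keeps recognition deterministic on noisy CQA text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .similarity import tokenize


class LexiconError(Exception):
    """The lexicon file is malformed."""


@dataclass
class ConceptLexicon:
    """Mapping from lowercase term (1-5 words) to its semantic types."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.max_words = max((len(t.split()) for t in self.entries), default=1)

    def __contains__(self, term: str) -> bool:
        return term.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def types(self, term: str) -> frozenset[str]:
        return self.entries.get(term.lower(), frozenset())


@dataclass(frozen=True)
class ConceptSet:
    """Concept terms recognized in one text, with their semantic types."""

    terms: frozenset[str]
    types_by_term: Mapping[str, frozenset[str]]

    @property
    def words(self) -> frozenset[str]:
        """Individual words of the matched terms (for word-level overlap)."""
        return frozenset(w for term in self.terms for w in term.split())

    def __len__(self) -> int:
        return len(self.terms)

    @staticmethod
    def empty() -> "ConceptSet":
        return ConceptSet(frozenset(), {})


def load_lexicon(path: str | Path) -> ConceptLexicon:
    """Load a TSV lexicon (term <TAB> semantic_type); multi-type terms merge."""
    entries: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise LexiconError(f"line {line_no}: expected 2 tab-separated columns")
            term, semtype = parts[0].strip().lower(), parts[1].strip().lower()
            if not term:
                raise LexiconError(f"line {line_no}: empty term")
            entries.setdefault(term, set()).add(semtype)
    return ConceptLexicon({t: frozenset(s) for t, s in entries.items()})


def bundled_lexicon() -> ConceptLexicon:
    """The packaged toy alcoholism lexicon (~50 terms)."""
    source = resources.files("cqarank.data").joinpath("alcoholism_lexicon.tsv")
    with resources.as_file(source) as path:
        return load_lexicon(path)


def recognize(text: str, lexicon: ConceptLexicon) -> ConceptSet:
    """Greedy longest-match concept recognition over the token stream.

    At each token position the longest lexicon term starting there wins
    and the scan resumes after it, so "alcohol withdrawal" beats its
    substring "alcohol".  Each matched term contributes once (set
    semantics).
    """
    tokens = tokenize(text)
    matched: set[str] = set()
    i = 0
    while i < len(tokens):
        advanced = False
        for span in range(min(lexicon.max_words, len(tokens) - i), 0, -1):
            term = " ".join(tokens[i : i + span])
            if term in lexicon:
                matched.add(term)
                i += span
                advanced = True
                break
        if not advanced:
            i += 1
    return ConceptSet(frozenset(matched), {t: lexicon.types(t) for t in matched})


def filter_types(cs: ConceptSet, types: Iterable[str]) -> ConceptSet:
    """Keep terms having at least one semantic type in ``types``."""
    wanted = {t.lower() for t in types}
    kept = frozenset(t for t in cs.terms if cs.types_by_term[t] & wanted)
    return ConceptSet(kept, {t: cs.types_by_term[t] for t in kept})


class PrecomputedRecognizer:
    """Concept sets read from a JSON Lines file of precomputed annotations.

    Each line: ``{"key": <id>, "terms": {"<term>": ["<semantic type>", ...]}}``.
    Lets users substitute real concept-mapper output for the dictionary
    matcher without touching the rest of the pipeline.
    """

    def __init__(self, path: str | Path):
        self._by_key: dict[str, ConceptSet] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                terms = {
                    term.lower(): frozenset(t.lower() for t in types)
                    for term, types in obj["terms"].items()
                }
                self._by_key[str(obj["key"])] = ConceptSet(frozenset(terms), terms)

    def lookup(self, key: str) -> ConceptSet:
        return self._by_key.get(key, ConceptSet.empty())
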