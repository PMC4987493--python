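"""Extraction of short subquestions from verbose CQA posts.

Posted questions bury one or more short question sentences in a long
title and description.  This module pulls those sentences out and
assigns each to one of thirteen question-word categories (yes-no,
what-quantity, how-frequent, when, why, how, where, who, whose, whom,
what, which, others) using ordered regular-expression rules.

The patterns live in a packaged YAML file (``data/question_patterns.yaml``)
so new domains can override them; the file order defines precedence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .corpus_io import QAThread

CATEGORIES = (
    "yes-no",
    "what-quantity",
    "how-frequent",
    "when",
    "why",
    "how",
    "where",
    "who",
    "whose",
    "whom",
    "what",
    "which",
    "others",
)

OTHERS = "others"


@dataclass(frozen=True)
class SubQuestion:
    """A short question sentence with its question-word category."""

    thread_id: str
    text: str
    category: str


@dataclass(frozen=True)
class _Rule:
    category: str
    start: tuple[re.Pattern, ...]
    anywhere: tuple[re.Pattern, ...]
    anchored_only: bool


class QuestionClassifier:
    """Ordered-regex classifier over the fixed category set.

    Two passes: first every category is tried anchored at the start of
    the sentence (in file order), then non-anchored categories are tried
    at any position.  No match yields ``others``.  Matching is
    case-insensitive on the raw sentence.
    """

    def __init__(self, rules_path: str | Path | None = None):
        if rules_path is None:
            source = resources.files("cqarank.data").joinpath("question_patterns.yaml")
            raw = yaml.safe_load(source.read_text(encoding="utf-8"))
        else:
            raw = yaml.safe_load(Path(rules_path).read_text(encoding="utf-8"))
        self._rules: list[_Rule] = []
        for entry in raw:
            category = entry["category"]
            if category not in CATEGORIES:
                raise ValueError(f"unknown category {category!r} in pattern file")
            patterns = entry["patterns"]
            self._rules.append(
                _Rule(
                    category=category,
                    start=tuple(re.compile(r"^\s*(?:" + p + ")", re.IGNORECASE) for p in patterns),
                    anywhere=tuple(re.compile(p, re.IGNORECASE) for p in patterns),
                    anchored_only=bool(entry.get("anchored_only", False)),
                )
            )

    def classify(self, text: str) -> str:
        """Category of one question sentence; total and deterministic."""
        if not text or not text.strip():
            raise ValueError("cannot classify empty text")
        for rule in self._rules:
            if any(p.search(text) for p in rule.start):
                return rule.category
        for rule in self._rules:
            if rule.anchored_only:
                continue
            if any(p.search(text) for p in rule.anywhere):
                return rule.category
        return OTHERS

    def starts_with_question_word(self, text: str) -> bool:
        return any(p.search(text) for rule in self._rules for p in rule.start)


_DEFAULT_CLASSIFIER: QuestionClassifier | None = None


def default_classifier() -> QuestionClassifier:
    global _DEFAULT_CLASSIFIER
    if _DEFAULT_CLASSIFIER is None:
        _DEFAULT_CLASSIFIER = QuestionClassifier()
    return _DEFAULT_CLASSIFIER


def classify_question(text: str) -> str:
    """Classify one question sentence with the packaged default rules."""
    return default_classifier().classify(text)


_SENTENCE_RE = re.compile(r"[^.?!]*[.?!]+|[^.?!]+")


def split_sentences(text: str) -> list[str]:
    """Deterministic sentence split on ``. ? !`` terminators.

    The terminator stays attached to its sentence; no statistical
    tokenizer is used, so the split is reproducible across environments.
    """
    return [s.strip() for s in _SENTENCE_RE.findall(text) if s.strip()]


def extract_subquestions(
    thread: QAThread, classifier: QuestionClassifier | None = None
) -> list[SubQuestion]:
    """All short question sentences of a thread, in document order.

    Every sentence in the title or description that ends with ``?``
    becomes one subquestion.  Titles often omit the question mark
    ("Can fully recovered alcoholics drink again"), so a title with no
    ``?`` that starts with a question word is also emitted.
    """
    clf = classifier or default_classifier()
    subquestions: list[SubQuestion] = []
    title_sentences = split_sentences(thread.title)
    found_in_title = False
    for sentence in title_sentences:
        if sentence.endswith("?"):
            found_in_title = True
            subquestions.append(
                SubQuestion(thread.thread_id, sentence, clf.classify(sentence))
            )
    if not found_in_title and thread.title.strip() and clf.starts_with_question_word(thread.title):
        sentence = thread.title.strip()
        subquestions.append(SubQuestion(thread.thread_id, sentence, clf.classify(sentence)))
    for sentence in split_sentences(thread.description):
        if sentence.endswith("?"):
            subquestions.append(
                SubQuestion(thread.thread_id, sentence, clf.classify(sentence))
            )
    return subquestions
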