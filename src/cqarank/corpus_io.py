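"""Reading and writing QA corpora, gold annotations, and concept lexicons.

A corpus is stored as JSON Lines: one thread per line, UTF-8, with the
canonical key order ``thread_id, title, description, answers`` (answers:
``text, is_best, likes``).  Gold triple annotations are a CSV table with
header ``prospective_id,training_id,answer_index,label``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

VALID = "valid"
INVALID = "invalid"
LABELS = (VALID, INVALID)


class CorpusError(Exception):
    """Base class for corpus-format problems."""


class SchemaError(CorpusError):
    """A record is missing a required key or has a malformed value."""


class IntegrityError(CorpusError):
    """A corpus-level invariant (e.g. unique thread ids) is violated."""


class AnnotationError(CorpusError):
    """A gold-annotation row cannot be parsed."""


@dataclass
class Answer:
    """One community answer: text, best-answer flag, like count."""

    text: str
    is_best: bool = False
    likes: int = 0

    def to_dict(self) -> dict:
        return {"text": self.text, "is_best": self.is_best, "likes": self.likes}


@dataclass
class QAThread:
    """One CQA post: a title, an optional description, and ordered answers."""

    thread_id: str
    title: str
    description: str = ""
    answers: list[Answer] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "thread_id": self.thread_id,
            "title": self.title,
            "description": self.description,
            "answers": [a.to_dict() for a in self.answers],
        }


@dataclass(frozen=True)
class TripleAnnotation:
    """Gold validity label for one (prospective, training, answer) triple."""

    prospective_id: str
    training_id: str
    answer_index: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise AnnotationError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.prospective_id == self.training_id:
            raise AnnotationError(
                f"prospective and training thread must differ ({self.prospective_id!r})"
            )


_THREAD_KEYS = ("thread_id", "title", "description", "answers")


def _parse_answer(obj: dict, line_no: int) -> Answer:
    if "text" not in obj:
        raise SchemaError(f"line {line_no}: answer missing required key 'text'")
    likes = int(obj.get("likes", 0))
    if likes < 0:
        raise SchemaError(f"line {line_no}: negative like count {likes}")
    return Answer(text=str(obj["text"]), is_best=bool(obj.get("is_best", False)), likes=likes)


def _parse_thread(obj: dict, line_no: int) -> QAThread:
    for key in ("thread_id", "title", "answers"):
        if key not in obj:
            raise SchemaError(f"line {line_no}: thread missing required key {key!r}")
    answers = [_parse_answer(a, line_no) for a in obj["answers"]]
    if sum(a.is_best for a in answers) > 1:
        raise IntegrityError(f"line {line_no}: more than one best answer")
    return QAThread(
        thread_id=str(obj["thread_id"]),
        title=str(obj["title"]),
        description=str(obj.get("description", "")),
        answers=answers,
    )


def load_corpus(path: str | Path) -> list[QAThread]:
    """Load a JSON Lines corpus, preserving thread and answer order.

    Raises :class:`SchemaError` (with the offending line number) for
    malformed records and :class:`IntegrityError` for duplicate ids.
    """
    threads: list[QAThread] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"line {line_no}: invalid JSON ({exc})") from exc
            thread = _parse_thread(obj, line_no)
            if thread.thread_id in seen:
                raise IntegrityError(f"line {line_no}: duplicate thread_id {thread.thread_id!r}")
            seen.add(thread.thread_id)
            threads.append(thread)
    return threads


def write_corpus(threads: Iterable[QAThread], path: str | Path) -> None:
    """Write threads as canonical JSON Lines (fixed key order, UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        for thread in threads:
            fh.write(json.dumps(thread.to_dict(), ensure_ascii=False) + "\n")


def load_annotations(path: str | Path) -> list[TripleAnnotation]:
    """Load gold triple annotations from CSV; labels parsed case-insensitively."""
    annotations: list[TripleAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"prospective_id", "training_id", "answer_index", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise AnnotationError(f"annotation CSV must have columns {sorted(required)}")
        for row_no, row in enumerate(reader, start=2):
            label = row["label"].strip().lower()
            if label not in LABELS:
                raise AnnotationError(f"row {row_no}: unknown label {row['label']!r}")
            annotations.append(
                TripleAnnotation(
                    prospective_id=row["prospective_id"],
                    training_id=row["training_id"],
                    answer_index=int(row["answer_index"]),
                    label=label,
                )
            )
    return annotations


def write_annotations(annotations: Sequence[TripleAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["prospective_id", "training_id", "answer_index", "label"])
        for ann in annotations:
            writer.writerow([ann.prospective_id, ann.training_id, ann.answer_index, ann.label])
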