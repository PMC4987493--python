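"""End-to-end pipeline: extract -> retrieve -> featurize -> train -> rank -> evaluate.

A run is driven by a :class:`PipelineConfig` (YAML-loadable), executes
each stage in order, caches stage outputs as CSV under the run
directory, and writes a manifest (config hash, seed, package version) so
a rerun with the same manifest reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concept_recognition import bundled_lexicon, load_lexicon
from .corpus_io import load_annotations, load_corpus, VALID
from .evaluation import EvaluationReport, cross_validate, information_gain_table
from .features import FEATURE_NAMES, extract_features, load_stoplist
from .question_extraction import extract_subquestions
from .retrieval import RetrievalConfig, build_index, candidates
from .similarity import fit_tfidf
from .ssl_em import ClassifierSpec

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run."""

    corpus_path: str
    annotations_path: str | None = None
    lexicon_path: str | None = None
    stoplist_path: str | None = None
    concept_weight: float = 0.5
    semantic_types: tuple[str, ...] = ("organic chemical", "pharmacologic substance")
    questions_per_measure: int = 2
    answers_per_question: int = 2
    dedupe: bool = False
    family: str = "nnet-l2"
    em_iterations: int = 1
    semi_supervised: bool = True
    k_folds: int = 10
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        try:
            config = PipelineConfig(**raw)
        except TypeError as exc:
            raise PipelineError(f"config: invalid key ({exc})") from exc
        if isinstance(config.semantic_types, list):
            config.semantic_types = tuple(config.semantic_types)
        return config

    def retrieval_config(self) -> RetrievalConfig:
        return RetrievalConfig(
            concept_weight_value=self.concept_weight,
            semantic_types=tuple(self.semantic_types),
            questions_per_measure=self.questions_per_measure,
            answers_per_question=self.answers_per_question,
            dedupe=self.dedupe,
        )

    def manifest(self) -> dict:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return {
            "config": asdict(self),
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "seed": self.seed,
            "version": __version__,
        }


def featurize_corpus(config: PipelineConfig) -> pd.DataFrame:
    """Stages extract/retrieve/featurize: one row per candidate triple."""
    corpus = load_corpus(config.corpus_path)
    lexicon = load_lexicon(config.lexicon_path) if config.lexicon_path else bundled_lexicon()
    stops = load_stoplist(config.stoplist_path)
    retrieval_config = config.retrieval_config()

    index = build_index(corpus)
    tfidf_by_category = {
        category: fit_tfidf([iq.text for iq in bucket])
        for category, bucket in index.buckets.items()
    }
    category_of = {
        (iq.thread_id, iq.text): category
        for category, bucket in index.buckets.items()
        for iq in bucket
    }

    rows = []
    for thread in corpus:
        for sq in extract_subquestions(thread):
            for t in candidates(sq, index, lexicon, retrieval_config):
                try:
                    fv = extract_features(
                        t, tfidf_by_category[category_of[(t.prospective_id, t.q_p)]],
                        lexicon, stops,
                    )
                except Exception as exc:
                    raise PipelineError(f"featurize: triple {t.key}: {exc}") from exc
                rows.append(
                    {
                        "prospective_id": t.prospective_id,
                        "training_id": t.training_id,
                        "answer_index": t.answer_index,
                        "measure": t.measure,
                        "rank_of_question": t.rank_of_question,
                        "answer_rank": t.answer_rank,
                        "distance": t.distance,
                        **dict(zip(FEATURE_NAMES, fv.values)),
                    }
                )
    return pd.DataFrame(rows)


def _attach_labels(table: pd.DataFrame, annotations) -> pd.DataFrame:
    label_of = {(a.prospective_id, a.training_id, a.answer_index): a.label for a in annotations}
    table = table.copy()
    table["label"] = [
        label_of.get((row.prospective_id, row.training_id, row.answer_index))
        for row in table.itertuples()
    ]
    return table


@dataclass
class PipelineResult:
    report: EvaluationReport
    feature_table: pd.DataFrame
    information_gain: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full pipeline and (optionally) write artifacts."""
    table = featurize_corpus(config)
    if table.empty:
        raise PipelineError("retrieve: no candidate triples produced from the corpus")
    if config.annotations_path is None:
        raise PipelineError("train: annotations_path is required to train and evaluate")
    annotations = load_annotations(config.annotations_path)
    table = _attach_labels(table, annotations)

    labeled = table[table["label"].notna()]
    unlabeled = table[table["label"].isna()]
    if labeled.empty:
        raise PipelineError("train: no triple matches the gold annotations")

    # the labeled/unlabeled split is by triple identity; the unlabeled pool
    # never exposes its (absent) labels to training
    feature_columns = list(FEATURE_NAMES)

    class _Row:
        __slots__ = ("prospective_id",)

        def __init__(self, qid):
            self.prospective_id = qid

    triples = [_Row(qid) for qid in labeled["prospective_id"]]
    spec = ClassifierSpec(family=config.family, seed=config.seed)
    report = cross_validate(
        triples,
        labeled[feature_columns].to_numpy(),
        (labeled["label"] == VALID).to_numpy(),
        spec,
        k=config.k_folds,
        unlabeled=unlabeled[feature_columns].to_numpy(),
        semi_supervised=config.semi_supervised,
        em_iterations=config.em_iterations,
        seed=config.seed,
    )
    gains = information_gain_table(
        labeled[feature_columns].to_numpy(),
        (labeled["label"] == VALID).to_numpy(),
        feature_columns,
    )
    result = PipelineResult(
        report=report, feature_table=table, information_gain=gains, manifest=config.manifest()
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "triples.csv", index=False)
        gains.to_csv(out / "information_gain.csv", index=False)
        (out / "report.json").write_text(report.to_json(indent=2))
        (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
    return result
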