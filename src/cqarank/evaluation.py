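"""Question-level and triple-level evaluation of the re-ranker.

Question-level metrics:

* *overall accuracy* — the fraction of test questions answered
  correctly, where a question counts correct if at least one of its
  candidate triples is predicted valid and is truly valid, or if it has
  no truly valid candidate and every candidate is predicted invalid;
* *mean reciprocal rank (MRR)* — the mean over questions of 1/rank of
  the highest-ranked truly valid candidate in the model's probability
  ordering (the minimum rank when several candidates are valid).
  Questions with no valid candidate contribute 0 by default and stay in
  the denominator (pessimistic, monotone in ranking quality); they can
  be excluded with a flag.

Triple-level metrics are standard precision/recall/F1 with "valid" as
the positive class (accuracy and ROC are avoided: the label distribution
is heavily imbalanced).

Cross-validation folds group triples by prospective question so that no
question's candidates straddle the train/test boundary (triple-level
folding is available behind a flag but leaks question identity).

Feature usefulness is measured by information gain
H(y) - sum_v p(v) H(y | f = v), with continuous features discretized
into equal-frequency bins.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import VALID
from .ssl_em import ClassifierSpec, RankModel, select_cutoff, train_em, train_supervised

logger = logging.getLogger(__name__)


@dataclass
class TripleMetrics:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


@dataclass
class EvaluationReport:
    """Aggregated metrics with per-fold detail."""

    overall_accuracy: float
    mrr: float
    precision: float
    recall: float
    f1: float
    confusion: dict = field(default_factory=dict)
    per_fold: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "mrr": self.mrr,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion,
            "per_fold": self.per_fold,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _is_valid(label) -> bool:
    if isinstance(label, str):
        return label == VALID
    return bool(label)


def overall_accuracy(questions: Sequence[tuple[Sequence, Sequence]]) -> float:
    """Fraction of questions with a correctly identified valid answer.

    ``questions`` holds, per question, aligned (predicted, gold) label
    sequences over its candidate triples.  A question with no truly
    valid candidate counts correct only when every candidate is
    predicted invalid.  Questions with no triples are excluded with a
    warning.
    """
    correct = 0
    total = 0
    for predicted, gold in questions:
        if len(predicted) != len(gold):
            raise ValueError("predicted and gold label sequences must align")
        if len(gold) == 0:
            logger.warning("question with no triples excluded from overall accuracy")
            continue
        total += 1
        pred_valid = [_is_valid(p) for p in predicted]
        gold_valid = [_is_valid(g) for g in gold]
        if any(gold_valid):
            if any(p and g for p, g in zip(pred_valid, gold_valid)):
                correct += 1
        else:
            if not any(pred_valid):
                correct += 1
    return correct / total if total else 0.0


def mean_reciprocal_rank(
    ranked_gold: Sequence[Sequence], exclude_no_valid: bool = False
) -> float:
    """MRR over questions; input is each question's gold validity flags
    in the model's descending-probability order."""
    reciprocal_ranks = []
    for flags in ranked_gold:
        ranks = [i for i, flag in enumerate(flags, start=1) if _is_valid(flag)]
        if ranks:
            reciprocal_ranks.append(1.0 / min(ranks))
        elif not exclude_no_valid:
            reciprocal_ranks.append(0.0)
    return float(np.mean(reciprocal_ranks)) if reciprocal_ranks else 0.0


def triple_metrics(predicted: Sequence, gold: Sequence) -> TripleMetrics:
    """Precision/recall/F1 with 'valid' as the positive class."""
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold label vectors must have equal length")
    tp = fp = tn = fn = 0
    for p, g in zip(predicted, gold):
        pv, gv = _is_valid(p), _is_valid(g)
        if pv and gv:
            tp += 1
        elif pv and not gv:
            fp += 1
        elif not pv and gv:
            fn += 1
        else:
            tn += 1
    if tp + fp == 0:
        logger.warning("no positive predictions; precision set to 0")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return TripleMetrics(precision, recall, f1, tp, fp, tn, fn)


def make_folds(question_ids: Sequence[str], k: int, seed: int) -> dict[str, int]:
    """Seeded partition of questions into k folds with sizes differing <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    unique = list(dict.fromkeys(question_ids))
    if len(unique) < k:
        raise ValueError(f"need at least {k} questions for {k} folds, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    assignment = {}
    for position, index in enumerate(order):
        assignment[unique[index]] = position % k + 1
    return assignment


def cross_validate(
    triples,
    X,
    y,
    spec: ClassifierSpec,
    k: int = 10,
    unlabeled: np.ndarray | None = None,
    semi_supervised: bool = False,
    em_iterations: int = 1,
    seed: int = 0,
    group_by_question: bool = True,
) -> EvaluationReport:
    """k-fold cross-validation of the re-ranker.

    Per fold: fit on the other folds (supervised, or EM with the full
    unlabeled pool), select the F1-maximizing cutoff on the training
    folds, then score the held-out fold.  Accuracy and MRR are averaged
    over folds; precision/recall/F1 come from the pooled confusion
    counts.  Fully reproducible from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    gold = np.asarray([1 if _is_valid(label) else 0 for label in y])
    qids = [t.prospective_id for t in triples]
    if group_by_question:
        fold_of_question = make_folds(qids, k, seed)
        fold_of_row = np.array([fold_of_question[q] for q in qids])
    else:
        per_row = make_folds([str(i) for i in range(len(qids))], k, seed)
        fold_of_row = np.array([per_row[str(i)] for i in range(len(qids))])

    pooled = Counter()
    fold_reports = []
    accuracies, mrrs = [], []
    for fold in range(1, k + 1):
        test_mask = fold_of_row == fold
        train_mask = ~test_mask
        spec_fold = ClassifierSpec(spec.family, dict(spec.hyperparameters), seed=spec.seed + fold)
        if semi_supervised and unlabeled is not None and len(unlabeled):
            model = train_em(
                (X[train_mask], gold[train_mask]), unlabeled, spec_fold, iterations=em_iterations
            )
        else:
            model = train_supervised(X[train_mask], gold[train_mask], spec_fold)
        train_probs = model.predict_proba(X[train_mask])
        model.cutoff = select_cutoff(train_probs, gold[train_mask])

        test_probs = model.predict_proba(X[test_mask])
        test_pred = test_probs >= model.cutoff
        test_gold = gold[test_mask]

        metrics = triple_metrics(test_pred, test_gold)
        for key in ("tp", "fp", "tn", "fn"):
            pooled[key] += getattr(metrics, key)

        per_question_pairs = []
        ranked_gold = []
        test_qids = np.asarray(qids)[test_mask]
        for qid in dict.fromkeys(test_qids):
            rows = np.flatnonzero(test_qids == qid)
            per_question_pairs.append((test_pred[rows].tolist(), test_gold[rows].tolist()))
            order = np.argsort(-test_probs[rows], kind="stable")
            ranked_gold.append(test_gold[rows][order].tolist())
        acc = overall_accuracy(per_question_pairs)
        mrr = mean_reciprocal_rank(ranked_gold)
        accuracies.append(acc)
        mrrs.append(mrr)
        fold_reports.append(
            {
                "fold": fold,
                "n_test_triples": int(test_mask.sum()),
                "n_test_questions": len(ranked_gold),
                "cutoff": model.cutoff,
                "overall_accuracy": acc,
                "mrr": mrr,
                **metrics.to_dict(),
            }
        )

    tp, fp, tn, fn = pooled["tp"], pooled["fp"], pooled["tn"], pooled["fn"]
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvaluationReport(
        overall_accuracy=float(np.mean(accuracies)),
        mrr=float(np.mean(mrrs)),
        precision=precision,
        recall=recall,
        f1=f1,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        per_fold=fold_reports,
    )


def _entropy(labels: np.ndarray) -> float:
    counts = np.bincount(labels.astype(int))
    p = counts[counts > 0] / labels.size
    return float(-(p * np.log2(p)).sum())


def information_gain(feature: Sequence[float], labels, bins: int = 10) -> float:
    """Entropy reduction of the labels given the (discretized) feature.

    Continuous features are cut into up to ``bins`` equal-frequency
    bins; features with few distinct values are used as-is.  Entropy is
    in bits.
    """
    x = np.asarray(feature, dtype=float)
    yb = np.asarray([1 if _is_valid(label) else 0 for label in labels])
    if x.size != yb.size:
        raise ValueError("feature and labels must align")
    if np.unique(x).size > bins:
        binned = pd.qcut(x, q=bins, labels=False, duplicates="drop")
        binned = np.asarray(binned)
    else:
        _, binned = np.unique(x, return_inverse=True)
    base = _entropy(yb)
    conditional = 0.0
    for value in np.unique(binned):
        mask = binned == value
        conditional += mask.mean() * _entropy(yb[mask])
    return max(0.0, base - conditional)


def information_gain_table(X, labels, feature_names: Sequence[str], bins: int = 10) -> pd.DataFrame:
    """Information gain of every feature, sorted descending."""
    X = np.asarray(X, dtype=float)
    gains = [information_gain(X[:, j], labels, bins=bins) for j in range(X.shape[1])]
    table = pd.DataFrame({"feature": list(feature_names), "information_gain": gains})
    return table.sort_values("information_gain", ascending=False).reset_index(drop=True)
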