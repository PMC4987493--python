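"""Phase-II answer re-ranking: supervised baselines and the EM wrapper.

Candidate triples from retrieval are classified valid/invalid by one of
four classifier families — a single-hidden-layer neural network with a
cross-entropy objective (``nnet-entropy``), the same network with a
least-squares objective (``nnet-l2``), a linear-kernel SVM with Platt
scaling (``svm-linear``), and logistic regression (``logistic``).

Labeled triples are scarce (annotation is expensive), so an
expectation-maximization-style semi-supervised wrapper is provided: fit
on the labeled set, predict hard labels for the unlabeled pool, refit on
labeled plus a seeded random subsample of the pseudo-labeled pool, and
repeat until the pseudo-labels stop changing or an iteration cap is hit.
One iteration is the default: in practice the parameters are already
near their fixed point after a single round.

Probabilities are turned into decisions by a cutoff selected to maximize
F1 on training data (the label distribution is heavily imbalanced, so
0.5 is a poor threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .corpus_io import INVALID, VALID

logger = logging.getLogger(__name__)

FAMILIES = ("nnet-entropy", "nnet-l2", "svm-linear", "logistic")


class TrainingError(Exception):
    """The training set violates a precondition (e.g. one class only)."""


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family with its hyperparameters and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")


def _as_binary(y: Sequence[str] | np.ndarray) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "bif":
        return arr.astype(int)
    return (arr == VALID).astype(int)


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    hidden = hp.pop("hidden_units", 10)
    if spec.family == "logistic":
        clf = LogisticRegression(max_iter=2000, random_state=spec.seed, **hp)
    elif spec.family == "svm-linear":
        clf = LinearSVC(random_state=spec.seed, max_iter=5000, dual=True, **hp)
    elif spec.family == "nnet-entropy":
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            max_iter=hp.pop("max_iter", 800),
            random_state=spec.seed,
            **hp,
        )
    else:  # nnet-l2: least-squares objective on 0/1 targets
        clf = MLPRegressor(
            hidden_layer_sizes=(hidden,),
            max_iter=hp.pop("max_iter", 800),
            random_state=spec.seed,
            **hp,
        )
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class PlattCalibration:
    """Sigmoid map from SVM decision values to probabilities.

    Maximum-likelihood logistic fit p(valid | s) = 1/(1 + exp(-(A s + B)))
    to the training decision values, the standard way of getting
    calibrated probabilities out of a margin classifier.
    """

    a: float
    b: float

    @staticmethod
    def fit(decision_values: np.ndarray, y: np.ndarray) -> "PlattCalibration":
        lr = LogisticRegression(C=1e6, max_iter=5000)  # effectively unpenalized
        lr.fit(decision_values.reshape(-1, 1), y)
        return PlattCalibration(a=float(lr.coef_[0, 0]), b=float(lr.intercept_[0]))

    def transform(self, decision_values: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(self.a * decision_values + self.b)))


@dataclass
class RankModel:
    """A fitted re-ranking model with calibration, cutoff, and manifest."""

    spec: ClassifierSpec
    pipeline: Pipeline
    calibration: PlattCalibration | None = None
    cutoff: float = 0.5
    manifest: dict = field(default_factory=dict)

    def predict_proba(self, X) -> np.ndarray:
        """Probability of 'valid' for each 13-feature row, in [0, 1]."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        family = self.spec.family
        if family == "svm-linear":
            scores = self.pipeline.decision_function(X)
            assert self.calibration is not None
            return self.calibration.transform(scores)
        if family == "nnet-l2":
            return np.clip(self.pipeline.predict(X), 0.0, 1.0)
        proba = self.pipeline.predict_proba(X)
        positive = list(self.pipeline.classes_).index(1)
        return proba[:, positive]

    def predict_labels(self, X) -> np.ndarray:
        """Hard valid/invalid labels at the model's cutoff (p >= cutoff)."""
        probs = self.predict_proba(X)
        return np.where(probs >= self.cutoff, VALID, INVALID)


def predict_proba(model: RankModel, X) -> np.ndarray:
    return model.predict_proba(X)


def train_supervised(X, y, spec: ClassifierSpec) -> RankModel:
    """Fit one classifier family on the labeled triples only."""
    X = np.asarray(X, dtype=float)
    yb = _as_binary(y)
    if len(np.unique(yb)) < 2:
        raise TrainingError("training labels must contain both classes")
    pipeline = _build_estimator(spec)
    target = yb.astype(float) if spec.family == "nnet-l2" else yb
    pipeline.fit(X, target)
    calibration = None
    if spec.family == "svm-linear":
        calibration = PlattCalibration.fit(pipeline.decision_function(X), yb)
    manifest = {
        "family": spec.family,
        "seed": spec.seed,
        "n_labeled": int(len(yb)),
        "n_unlabeled": 0,
        "em_iterations": 0,
    }
    return RankModel(spec=spec, pipeline=pipeline, calibration=calibration, manifest=manifest)


def train_em(
    labeled: tuple[np.ndarray, np.ndarray],
    unlabeled: np.ndarray,
    spec: ClassifierSpec,
    iterations: int = 1,
    subsample: float = 1.0,
) -> RankModel:
    """EM-style semi-supervised training.

    Per iteration: predict hard labels for the unlabeled pool with the
    current model, then refit on the labeled set plus a seeded random
    subsample of the pseudo-labeled pool.  Stops early when the
    pseudo-label assignment is unchanged between iterations.  An empty
    unlabeled pool degenerates to supervised training.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not 0.0 < subsample <= 1.0:
        raise ValueError("subsample must be in (0, 1]")
    X_l, y_l = np.asarray(labeled[0], dtype=float), _as_binary(labeled[1])
    X_u = np.asarray(unlabeled, dtype=float)

    model = train_supervised(X_l, y_l, spec)
    if X_u.size == 0:
        logger.info("empty unlabeled pool: EM degenerates to supervised training")
        return model

    rng = np.random.default_rng(spec.seed)
    previous: np.ndarray | None = None
    done = 0
    for iteration in range(iterations):
        pseudo = (model.predict_proba(X_u) >= 0.5).astype(int)
        if previous is not None and np.array_equal(pseudo, previous):
            break
        previous = pseudo
        n_sub = max(1, int(round(subsample * len(X_u))))
        chosen = rng.choice(len(X_u), size=n_sub, replace=False) if n_sub < len(X_u) else np.arange(len(X_u))
        X_fit = np.vstack([X_l, X_u[chosen]])
        y_fit = np.concatenate([y_l, pseudo[chosen]])
        if len(np.unique(y_fit)) < 2:  # degenerate pseudo-labels: keep labeled-only fit
            logger.warning("pseudo-labels collapsed to one class; stopping EM")
            break
        pipeline = _build_estimator(spec)
        target = y_fit.astype(float) if spec.family == "nnet-l2" else y_fit
        pipeline.fit(X_fit, target)
        calibration = None
        if spec.family == "svm-linear":
            calibration = PlattCalibration.fit(pipeline.decision_function(X_fit), y_fit)
        model = RankModel(spec=spec, pipeline=pipeline, calibration=calibration)
        done = iteration + 1
    model.manifest = {
        "family": spec.family,
        "seed": spec.seed,
        "n_labeled": int(len(y_l)),
        "n_unlabeled": int(len(X_u)),
        "em_iterations": done,
        "subsample": subsample,
    }
    return model


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def select_cutoff(probs: Sequence[float], labels) -> float:
    """Smallest threshold on a 0.01 grid maximizing F1 of 'valid'.

    A row is predicted valid when its probability is >= the threshold.
    """
    probs = np.asarray(probs, dtype=float)
    yb = _as_binary(labels)
    if yb.sum() == 0:
        raise TrainingError("cutoff selection needs at least one positive label")
    best_t, best_f1 = 0.0, -1.0
    for t in np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2):
        pred = probs >= t
        tp = int(np.sum(pred & (yb == 1)))
        fp = int(np.sum(pred & (yb == 0)))
        fn = int(np.sum(~pred & (yb == 1)))
        f1 = _f1(tp, fp, fn)
        if f1 > best_f1 + 1e-12:  # ties keep the smallest threshold
            best_t, best_f1 = float(t), f1
    return best_t


@dataclass(frozen=True)
class RankedAnswer:
    """One candidate answer with its model probability and validity flag."""

    triple_key: tuple[str, str, int]
    answer_text: str
    probability: float
    predicted_valid: bool


@dataclass(frozen=True)
class QuestionRanking:
    """Ranked answers for one prospective question."""

    prospective_id: str
    answers: tuple[RankedAnswer, ...]

    @property
    def best_answer(self) -> RankedAnswer | None:
        """Top-ranked answer flagged valid, or None if unanswerable."""
        for answer in self.answers:
            if answer.predicted_valid:
                return answer
        return None

    @property
    def unanswerable(self) -> bool:
        return self.best_answer is None


def rank_candidates(model: RankModel, triples, X) -> list[QuestionRanking]:
    """Rank each question's candidate answers by descending probability.

    ``triples`` and ``X`` are aligned (one feature row per triple).
    Candidates at or above the model cutoff are flagged valid; a question
    with no flagged candidate is unanswerable from the corpus.
    """
    probs = model.predict_proba(X)
    by_question: dict[str, list[tuple[int, float]]] = {}
    order: list[str] = []
    for i, triple in enumerate(triples):
        if triple.prospective_id not in by_question:
            order.append(triple.prospective_id)
        by_question.setdefault(triple.prospective_id, []).append((i, float(probs[i])))
    rankings = []
    for qid in order:
        entries = by_question[qid]
        entries.sort(key=lambda item: -item[1])  # stable: ties keep input order
        ranked = tuple(
            RankedAnswer(
                triple_key=triples[i].key,
                answer_text=triples[i].a_t,
                probability=p,
                predicted_valid=p >= model.cutoff,
            )
            for i, p in entries
        )
        rankings.append(QuestionRanking(prospective_id=qid, answers=ranked))
    return rankings
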