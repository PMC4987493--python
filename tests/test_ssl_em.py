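import numpy as np
import pytest

from cqarank.retrieval import Triple
from cqarank.ssl_em import (
    ClassifierSpec,
    FAMILIES,
    PlattCalibration,
    TrainingError,
    rank_candidates,
    select_cutoff,
    train_em,
    train_supervised,
)
from _oracles import best_cutoff_exhaustive, f1_score_by_counting


def separable_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal(-2.0, 0.4, size=(n // 2, 2)),
            rng.normal(+2.0, 0.4, size=(n // 2, 2)),
        ]
    )
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestTrainSupervised:
    def test_separable_logistic_reaches_training_accuracy_one(self):
        X, y = separable_data()
        model = train_supervised(X, y, ClassifierSpec("logistic", seed=0))
        model.cutoff = 0.5
        predicted = model.predict_proba(X) >= 0.5
        assert (predicted == y.astype(bool)).all()

    def test_single_class_labels_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(TrainingError):
            train_supervised(X, np.ones(5), ClassifierSpec("logistic"))

    def test_refit_with_same_seed_reproduces_predictions(self):
        X, y = separable_data()
        spec = ClassifierSpec("nnet-entropy", seed=3)
        p1 = train_supervised(X, y, spec).predict_proba(X)
        p2 = train_supervised(X, y, spec).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_row_permutation_with_fixed_seed_keeps_predictions(self):
        X, y = separable_data()
        order = np.random.default_rng(1).permutation(len(y))
        spec = ClassifierSpec("logistic", seed=0)
        p1 = train_supervised(X, y, spec).predict_proba(X)
        p2 = train_supervised(X[order], y[order], spec).predict_proba(X)
        assert np.allclose(p1, p2, atol=1e-6)

    def test_logistic_matches_likelihood_grid_oracle(self):
        # 1-D four-point toy set; effectively unpenalized fit
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = train_supervised(X, y, ClassifierSpec("logistic", hyperparameters={"C": 1e6}))
        probs = model.predict_proba(X)

        # brute-force likelihood over a (slope, intercept) grid on the
        # standardized feature (the model pipeline standardizes too)
        z = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std()
        best, best_ll = None, -np.inf
        for w in np.linspace(-20, 20, 161):
            for b in np.linspace(-5, 5, 41):
                p = 1 / (1 + np.exp(-(w * z + b)))
                ll = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
                if ll > best_ll:
                    best, best_ll = (w, b), ll
        w, b = best
        oracle_probs = 1 / (1 + np.exp(-(w * z + b)))
        # separable data: both fits drive the probabilities to the labels
        assert np.allclose(probs, oracle_probs, atol=0.05)


class TestPredictProba:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_outputs_within_unit_interval(self, family):
        X, y = separable_data()
        model = train_supervised(X, y, ClassifierSpec(family, seed=1))
        probs = model.predict_proba(X)
        assert probs.shape == (len(X),)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_dimension_mismatch_raises(self):
        X, y = separable_data()
        model = train_supervised(X, y, ClassifierSpec("logistic"))
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros(4))


class TestPlatt:
    def test_mapping_is_monotone_in_decision_value(self):
        scores = np.array([-3.0, -1.0, -0.5, 0.5, 1.0, 3.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        cal = PlattCalibration.fit(scores, y)
        probs = cal.transform(np.linspace(-5, 5, 50))
        assert (np.diff(probs) >= 0).all() or (np.diff(probs) <= 0).all()
        assert probs[-1] > probs[0]  # valid gets likelier with the margin

    def test_parameters_match_grid_search_oracle(self):
        scores = np.array([-2.0, -1.5, -0.2, 0.3, 1.1, 2.4])
        y = np.array([0, 0, 1, 0, 1, 1])
        cal = PlattCalibration.fit(scores, y)
        best_ll = -np.inf
        best = None
        for a in np.linspace(0.0, 10.0, 201):
            for b in np.linspace(-5.0, 5.0, 101):
                p = np.clip(1 / (1 + np.exp(-(a * scores + b))), 1e-12, 1 - 1e-12)
                ll = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
                if ll > best_ll:
                    best, best_ll = (a, b), ll
        fitted = np.clip(cal.transform(scores), 1e-12, 1 - 1e-12)
        fitted_ll = np.sum(y * np.log(fitted) + (1 - y) * np.log(1 - fitted))
        # the ML fit must be at least as likely as the best grid point
        assert fitted_ll >= best_ll - 0.05
        assert np.allclose(cal.transform(scores), 1 / (1 + np.exp(-(best[0] * scores + best[1]))), atol=0.15)


class TestTrainEm:
    def test_empty_unlabeled_pool_reproduces_supervised_bitwise(self):
        X, y = separable_data()
        spec = ClassifierSpec("logistic", seed=4)
        supervised = train_supervised(X, y, spec)
        em = train_em((X, y), np.empty((0, 2)), spec, iterations=3)
        assert np.array_equal(supervised.predict_proba(X), em.predict_proba(X))

    def test_fixed_point_on_separable_data(self):
        X, y = separable_data(seed=2)
        rng = np.random.default_rng(9)
        X_u = np.vstack(
            [rng.normal(-2.0, 0.4, size=(30, 2)), rng.normal(2.0, 0.4, size=(30, 2))]
        )
        spec = ClassifierSpec("logistic", seed=5)
        m1 = train_em((X, y), X_u, spec, iterations=1)
        m10 = train_em((X, y), X_u, spec, iterations=10)
        l1 = m1.predict_proba(X_u) >= 0.5
        l10 = m10.predict_proba(X_u) >= 0.5
        assert np.array_equal(l1, l10)
        assert m10.manifest["em_iterations"] <= 2  # converged, not capped

    def test_invalid_parameters_rejected(self):
        X, y = separable_data()
        with pytest.raises(ValueError):
            train_em((X, y), np.empty((0, 2)), ClassifierSpec("logistic"), iterations=0)
        with pytest.raises(ValueError):
            train_em((X, y), np.empty((0, 2)), ClassifierSpec("logistic"), subsample=0.0)


class TestSelectCutoff:
    def test_separable_probabilities_give_smallest_grid_threshold(self):
        probs = [0.9, 0.9, 0.1, 0.1]
        labels = [1, 1, 0, 0]
        assert select_cutoff(probs, labels) == pytest.approx(0.11)

    def test_all_equal_probabilities_give_zero_threshold(self):
        assert select_cutoff([0.4, 0.4, 0.4], [1, 0, 1]) == 0.0

    def test_no_positive_labels_is_error(self):
        with pytest.raises(TrainingError):
            select_cutoff([0.5, 0.5], [0, 0])

    def test_matches_exhaustive_threshold_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 40))
            probs = rng.random(n)
            labels = rng.random(n) < 0.3
            if not labels.any():
                labels[0] = True
            t = select_cutoff(probs, labels)
            achieved = f1_score_by_counting(probs >= t, labels)
            assert achieved == pytest.approx(best_cutoff_exhaustive(probs, labels))


class TestRankCandidates:
    def _triples(self, qid, n):
        return [
            Triple(qid, f"t{i}", 0, "q?", "tq?", f"answer {i}", "dtw", 1, 1, 1.0)
            for i in range(n)
        ]

    def _model_with_probs(self, probs, cutoff):
        class Stub:
            def __init__(self, probs, cutoff):
                self._probs = np.asarray(probs, dtype=float)
                self.cutoff = cutoff

            def predict_proba(self, X):
                return self._probs

        return Stub(probs, cutoff)

    def test_single_candidate_above_cutoff_is_best_answer(self):
        triples = self._triples("q1", 3)
        model = self._model_with_probs([0.2, 0.8, 0.1], cutoff=0.5)
        (ranking,) = rank_candidates(model, triples, np.zeros((3, 13)))
        assert ranking.best_answer.answer_text == "answer 1"
        assert not ranking.unanswerable

    def test_all_below_cutoff_marks_unanswerable(self):
        triples = self._triples("q1", 3)
        model = self._model_with_probs([0.2, 0.3, 0.1], cutoff=0.5)
        (ranking,) = rank_candidates(model, triples, np.zeros((3, 13)))
        assert ranking.unanswerable

    def test_ordering_matches_stable_sort_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 10))
            probs = np.round(rng.random(n), 1)  # coarse values force ties
            triples = self._triples("q1", n)
            model = self._model_with_probs(probs, cutoff=0.5)
            (ranking,) = rank_candidates(model, triples, np.zeros((n, 13)))
            got = [a.probability for a in ranking.answers]
            expected = sorted(probs.tolist(), reverse=True)
            assert got == expected
            # stability: equal probabilities keep the input order
            order = [a.triple_key[1] for a in ranking.answers]
            expected_order = [
                f"t{i}" for i, _ in sorted(enumerate(probs), key=lambda item: -item[1])
            ]
            assert order == expected_order
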