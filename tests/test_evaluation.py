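import math

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from cqarank.evaluation import (
    cross_validate,
    information_gain,
    make_folds,
    mean_reciprocal_rank,
    overall_accuracy,
    triple_metrics,
)
from cqarank.ssl_em import ClassifierSpec
from cqarank.synthetic_corpus import GeneratorConfig, generate
from _oracles import entropy_bits, information_gain_longhand


class TestOverallAccuracy:
    def test_all_questions_with_correct_valid_triple(self):
        questions = [([1, 0], [1, 0]), ([0, 1], [0, 1])]
        assert overall_accuracy(questions) == 1.0

    def test_all_invalid_question_counts_correct_when_all_predicted_invalid(self):
        questions = [([0, 0, 0], [0, 0, 0])]
        assert overall_accuracy(questions) == 1.0

    def test_all_invalid_question_fails_on_false_positive(self):
        questions = [([1, 0], [0, 0])]
        assert overall_accuracy(questions) == 0.0

    def test_valid_question_needs_true_positive_not_just_any_positive(self):
        # prediction flags the wrong triple: not correct
        questions = [([1, 0], [0, 1])]
        assert overall_accuracy(questions) == 0.0

    def test_matches_literal_definition_on_random_sets(self, rng):
        for _ in range(50):
            questions = []
            for _ in range(rng.integers(1, 10)):
                n = int(rng.integers(1, 8))
                questions.append(
                    ((rng.random(n) < 0.4).tolist(), (rng.random(n) < 0.3).tolist())
                )
            # independent literal re-implementation of the definition
            correct = 0
            for predicted, gold in questions:
                if any(gold):
                    correct += any(p and g for p, g in zip(predicted, gold))
                else:
                    correct += not any(predicted)
            assert overall_accuracy(questions) == pytest.approx(correct / len(questions))


class TestMeanReciprocalRank:
    def test_valid_at_rank_one(self):
        assert mean_reciprocal_rank([[1, 0, 0]]) == 1.0

    def test_two_questions_ranks_one_and_four(self):
        assert mean_reciprocal_rank([[1, 0, 0, 0], [0, 0, 0, 1]]) == pytest.approx(0.625)

    def test_multiple_valid_instances_use_minimum_rank(self):
        assert mean_reciprocal_rank([[0, 1, 1, 0]]) == pytest.approx(0.5)

    def test_question_with_no_valid_triple_contributes_zero(self):
        assert mean_reciprocal_rank([[1], [0, 0]]) == pytest.approx(0.5)

    def test_exclusion_flag_drops_no_valid_questions(self):
        assert mean_reciprocal_rank([[1], [0, 0]], exclude_no_valid=True) == 1.0

    def test_bounded_by_unit_interval(self, rng):
        for _ in range(30):
            ranked = [(rng.random(int(rng.integers(1, 6))) < 0.4).tolist() for _ in range(5)]
            assert 0.0 <= mean_reciprocal_rank(ranked) <= 1.0


class TestTripleMetrics:
    def test_perfect_predictions(self):
        m = triple_metrics([1, 0, 1], [1, 0, 1])
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_all_predicted_invalid_gives_zero_recall_and_f1(self):
        m = triple_metrics([0, 0, 0], [1, 0, 1])
        assert m.recall == 0.0 and m.f1 == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            triple_metrics([1], [1, 0])

    def test_confusion_counts_sum_to_total(self, rng):
        predicted = (rng.random(40) < 0.5).tolist()
        gold = (rng.random(40) < 0.3).tolist()
        m = triple_metrics(predicted, gold)
        assert m.tp + m.fp + m.tn + m.fn == 40

    def test_matches_sklearn_counting_oracle(self, rng):
        for _ in range(20):
            predicted = rng.random(30) < 0.5
            gold = rng.random(30) < 0.3
            m = triple_metrics(predicted.tolist(), gold.tolist())
            p, r, f, _ = precision_recall_fscore_support(
                gold, predicted, average="binary", zero_division=0.0
            )
            assert (m.precision, m.recall, m.f1) == pytest.approx((p, r, f))


class TestFolds:
    def test_sizes_differ_by_at_most_one(self, rng):
        for n in range(11, 41):
            ids = [f"q{i}" for i in range(n)]
            assignment = make_folds(ids, k=10, seed=int(rng.integers(1000)))
            sizes = np.bincount(list(assignment.values()))[1:]
            assert sizes.max() - sizes.min() <= 1
            assert sizes.sum() == n

    def test_leave_one_out_when_k_equals_question_count(self):
        ids = [f"q{i}" for i in range(7)]
        assignment = make_folds(ids, k=7, seed=0)
        assert sorted(assignment.values()) == list(range(1, 8))

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], k=1, seed=0)


@pytest.fixture(scope="module")
def small_benchmark():
    return generate(GeneratorConfig(seed=11, n_threads=30))


class TestCrossValidate:
    def test_same_seed_gives_identical_report(self, small_benchmark):
        c = small_benchmark
        spec = ClassifierSpec("logistic", seed=0)
        r1 = cross_validate(c.triples, c.X, c.y, spec, k=5, seed=3)
        r2 = cross_validate(c.triples, c.X, c.y, spec, k=5, seed=3)
        assert r1.to_dict() == r2.to_dict()

    def test_metrics_within_unit_interval(self, small_benchmark):
        c = small_benchmark
        report = cross_validate(c.triples, c.X, c.y, ClassifierSpec("logistic"), k=5, seed=1)
        for value in (report.overall_accuracy, report.mrr, report.precision, report.recall, report.f1):
            assert 0.0 <= value <= 1.0

    def test_confusion_counts_cover_every_triple(self, small_benchmark):
        c = small_benchmark
        report = cross_validate(c.triples, c.X, c.y, ClassifierSpec("logistic"), k=5, seed=1)
        assert sum(report.confusion.values()) == len(c.triples)

    def test_question_triples_never_straddle_folds(self, small_benchmark):
        c = small_benchmark
        qids = [t.prospective_id for t in c.triples]
        assignment = make_folds(qids, k=5, seed=3)
        seen = {}
        for qid in qids:
            fold = assignment[qid]
            assert seen.setdefault(qid, fold) == fold


class TestInformationGain:
    def test_feature_independent_of_label_is_near_zero(self, rng):
        y = rng.integers(0, 2, size=2000)
        x = rng.integers(0, 2, size=2000)  # independent coin
        assert information_gain(x, y) < 0.01

    def test_feature_identical_to_label_gives_label_entropy(self):
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        assert information_gain(y.astype(float), y) == pytest.approx(entropy_bits(y.tolist()))

    def test_constant_labels_give_zero(self):
        assert information_gain([1.0, 2.0, 3.0], [1, 1, 1]) == 0.0

    def test_twelve_row_table_matches_longhand_entropy(self):
        x = [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]
        y = [1, 1, 1, 0, 1, 0, 0, 0, 1, 0, 1, 0]
        expected = information_gain_longhand(x, y)
        # longhand: H(y)=1; v=0 and v=1 each H=0.811278, v=2 H=1
        assert expected == pytest.approx(
            1.0 - (4 / 12) * (-(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))) * 2 - (4 / 12) * 1.0
        )
        assert information_gain([float(v) for v in x], y) == pytest.approx(expected)

    def test_gain_never_exceeds_label_entropy(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, size=100)
            x = rng.normal(size=100)
            assert information_gain(x, y) <= entropy_bits(y.tolist()) + 1e-9
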