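"""Threshold optimisation, confusion matrices and the two null models."""

import itertools

import numpy as np
import pytest

from earkit import evaluate
from earkit.datatypes import ParameterError


def brute_force_best_accuracy(values, predicted):
    """Oracle: try every triple of cut positions with naive counting."""
    v = np.asarray(values, float)
    p = np.asarray(predicted, int)
    distinct = np.unique(v)
    cuts = [distinct[0] - 1.0]
    cuts += [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
    cuts += [distinct[-1] + 1.0]
    best = -1
    for c1, c2, c3 in itertools.combinations_with_replacement(cuts, 3):
        correct = 0
        for val, pred in zip(v, p):
            if val < c1:
                k = 1
            elif val < c2:
                k = 2
            elif val < c3:
                k = 3
            else:
                k = 4
            correct += (k == pred)
        best = max(best, correct)
    return best / v.size


class TestBinObserved:
    def test_basic_binning(self):
        out = evaluate.bin_observed([0.1, 0.3, 0.6, 0.9], (0.25, 0.5, 0.75))
        assert out.tolist() == [1, 2, 3, 4]

    def test_boundary_left_closed(self):
        assert evaluate.bin_observed([0.5], (0.25, 0.5, 0.75)).tolist() == [3]

    def test_all_below_first_threshold(self):
        out = evaluate.bin_observed([0.0, 0.1, 0.2], (0.25, 0.5, 0.75))
        assert out.tolist() == [1, 1, 1]

    def test_nonincreasing_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            evaluate.bin_observed([0.1], (0.5, 0.5, 0.75))


class TestOptimizeThresholds:
    def test_separable_case_perfect(self):
        t = evaluate.optimize_thresholds([0.1, 0.2, 0.8, 0.9], [1, 1, 4, 4])
        classes = evaluate.bin_observed([0.1, 0.2, 0.8, 0.9], t)
        assert classes.tolist() == [1, 1, 4, 4]

    def test_constant_prediction_degenerate_thresholds(self):
        values = [0.1, 0.2, 0.3, 0.4]
        t = evaluate.optimize_thresholds(values, [1, 1, 1, 1])
        assert evaluate.bin_observed(values, t).tolist() == [1, 1, 1, 1]

    def test_matches_bruteforce_random_instances(self):
        rng = np.random.default_rng(99)
        for trial in range(30):
            n = int(rng.integers(4, 13))
            values = np.round(rng.uniform(0, 1, size=n), 3)
            while np.unique(values).size < 4:
                values = np.round(rng.uniform(0, 1, size=n), 3)
            predicted = rng.integers(1, 5, size=n)
            t = evaluate.optimize_thresholds(values, predicted)
            acc = np.mean(evaluate.bin_observed(values, t) == predicted)
            assert acc == pytest.approx(
                brute_force_best_accuracy(values, predicted))

    def test_rank_only_dependence(self):
        """Accuracy is invariant under strictly monotone value transforms."""
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 1, size=12)
        predicted = rng.integers(1, 5, size=12)
        t1 = evaluate.optimize_thresholds(values, predicted)
        t2 = evaluate.optimize_thresholds(np.exp(3 * values), predicted)
        a1 = np.mean(evaluate.bin_observed(values, t1) == predicted)
        a2 = np.mean(evaluate.bin_observed(np.exp(3 * values), t2) == predicted)
        assert a1 == pytest.approx(a2)

    def test_too_few_distinct_values(self):
        with pytest.raises(ParameterError):
            evaluate.optimize_thresholds([1, 1, 2, 2], [1, 2, 3, 4])


class TestConfusion:
    def test_perfect_classifier_diagonal(self):
        pred = [1, 2, 3, 4, 1, 2]
        conf, acc = evaluate.confusion_and_accuracy(pred, pred)
        assert acc == 1.0
        assert np.trace(conf) == 6
        assert conf.sum() == 6

    def test_reversed_classes_zero_diagonal(self):
        pred = [1, 2, 3, 4]
        obs = [4, 3, 2, 1]
        conf, acc = evaluate.confusion_and_accuracy(pred, obs)
        assert acc == 0.0 and np.trace(conf) == 0

    def test_manual_tally(self):
        pred = [1, 1, 2, 3, 3, 4, 4, 4]
        obs = [1, 2, 2, 3, 4, 4, 4, 1]
        conf, acc = evaluate.confusion_and_accuracy(pred, obs)
        assert conf[0, 0] == 1 and conf[0, 1] == 1
        assert conf[1, 1] == 1
        assert conf[2, 2] == 1 and conf[2, 3] == 1
        assert conf[3, 3] == 2 and conf[3, 0] == 1
        assert acc == pytest.approx(5 / 8)

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            evaluate.confusion_and_accuracy([1, 2], [1])


class TestPermutationNull:
    def test_exchangeable_case(self):
        pred = [1] * 20
        obs = [1, 2, 3, 4] * 5
        res = evaluate.permutation_null(pred, obs, n_perm=500, seed=1)
        assert res.null_mean == pytest.approx(0.25, abs=1e-9)
        assert res.real_accuracy == pytest.approx(0.25)
        assert 30 < res.percentile_outperformed < 70 or res.null_sd == 0

    def test_null_mean_matches_closed_form(self):
        rng = np.random.default_rng(3)
        pred = rng.integers(1, 5, size=60)
        obs = rng.integers(1, 5, size=60)
        res = evaluate.permutation_null(pred, obs, n_perm=1000, seed=2)
        expect = evaluate.expected_permutation_accuracy(pred, obs)
        se = res.null_sd / np.sqrt(res.n_iterations)
        assert abs(res.null_mean - expect) < 3 * se

    def test_seeded_determinism(self):
        pred = [1, 2, 3, 4, 1, 2, 3, 4]
        obs = [1, 1, 3, 4, 2, 2, 3, 4]
        a = evaluate.permutation_null(pred, obs, n_perm=200, seed=11)
        b = evaluate.permutation_null(pred, obs, n_perm=200, seed=11)
        assert np.array_equal(a.accuracies, b.accuracies)


class TestBootstrapNull:
    def test_mean_quarter(self):
        obs = [1, 2, 3, 4] * 20
        res = evaluate.bootstrap_random_null(obs, real_accuracy=0.3,
                                             n_runs=1000, seed=4)
        se = np.sqrt(0.25 * 0.75 / 80) / np.sqrt(1000)
        assert abs(res.null_mean - 0.25) < 3 * se

    def test_single_item_bernoulli(self):
        res = evaluate.bootstrap_random_null([2], real_accuracy=1.0,
                                             n_runs=2000, seed=5)
        assert set(np.unique(res.accuracies)) <= {0.0, 1.0}
        assert abs(res.null_mean - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 2000)

    def test_sd_matches_binomial(self):
        obs = [1, 2, 3, 4] * 20
        res = evaluate.bootstrap_random_null(obs, real_accuracy=0.3,
                                             n_runs=1000, seed=6)
        expected_sd = np.sqrt(0.25 * 0.75 / 80)
        se_sd = expected_sd / np.sqrt(2 * (1000 - 1))
        assert abs(res.null_sd - expected_sd) < 3 * se_sd


class TestEndToEnd:
    def test_evaluate_predictions_consistency(self):
        rng = np.random.default_rng(8)
        pred = rng.integers(1, 5, size=40)
        values = rng.uniform(0, 1, size=40)
        res = evaluate.evaluate_predictions(pred, values, n_perm=200,
                                            n_boot=200, seed=3)
        assert res.confusion.sum() == 40
        assert res.accuracy == pytest.approx(np.trace(res.confusion) / 40)
        assert res.thresholds[0] < res.thresholds[1] < res.thresholds[2]

    def test_class_names_accepted(self):
        res = evaluate.evaluate_predictions(
            ["weak", "moderate", "strong", "strongest"] * 3,
            list(np.linspace(0, 1, 12)), n_perm=50, n_boot=50, seed=0)
        assert res.n == 12
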