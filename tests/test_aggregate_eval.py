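"""Patch-vote aggregation, metrics, ROC/AUC, bootstrap CIs and McNemar."""

import itertools

import numpy as np
import pytest

from steatolens.aggregate_eval import (
    NON_VALID,
    VALID,
    AggregationConfig,
    EvaluationError,
    aggregate,
    bootstrap_ci,
    importance_report,
    mcnemar,
    metrics,
    require_impurity,
    roc_auc,
)


def brute_force_auc(scores, truths):
    """Pairwise probability P(s_pos > s_neg) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, truths) if t == NON_VALID]
    neg = [s for s, t in zip(scores, truths) if t == VALID]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAggregate:
    def test_twenty_percent_boundary_is_non_valid(self):
        pred = aggregate([NON_VALID] * 5 + [VALID] * 20)
        assert pred.fraction == pytest.approx(0.20)
        assert pred.decision == NON_VALID

    def test_all_valid(self):
        assert aggregate([VALID] * 20).decision == VALID

    def test_just_below_threshold_is_valid(self):
        pred = aggregate([NON_VALID] * 4 + [VALID] * 21)
        assert pred.fraction == pytest.approx(0.16)
        assert pred.decision == VALID

    def test_zero_patches_errors(self):
        with pytest.raises(EvaluationError):
            aggregate([])

    def test_monotone_in_non_valid_votes(self, rng):
        cfg = AggregationConfig(0.2)
        for _ in range(50):
            votes = list(rng.integers(0, 2, size=rng.integers(1, 30)))
            before = aggregate(votes, cfg).decision
            after = aggregate(votes + [NON_VALID], cfg).decision
            assert not (before == NON_VALID and after == VALID)


class TestMetrics:
    def test_confusion_arithmetic(self):
        d = [NON_VALID] * 10 + [VALID] * 10
        t = [NON_VALID] * 9 + [VALID] + [NON_VALID] * 2 + [VALID] * 8
        m = metrics(d, t)
        assert (m.tp, m.fp, m.fn, m.tn) == (9, 1, 2, 8)
        assert m.accuracy == pytest.approx(0.85)
        assert m.precision == pytest.approx(0.90)
        assert m.recall == pytest.approx(9 / 11, abs=1e-4)

    def test_all_correct(self):
        m = metrics([0, 1, 1], [0, 1, 1])
        assert (m.accuracy, m.precision, m.recall) == (1.0, 1.0, 1.0)

    def test_no_positive_predictions(self):
        m = metrics([VALID] * 4, [VALID, VALID, NON_VALID, NON_VALID])
        assert m.precision is None and m.recall == 0.0


class TestRocAuc:
    def test_pairwise_example_with_tie(self):
        scores = [0.8, 0.6, 0.3, 0.6]
        truths = [NON_VALID, NON_VALID, VALID, VALID]
        _, auc = roc_auc(scores, truths)
        assert auc == pytest.approx(0.875)

    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == pytest.approx(0.5)

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 50))
            truths = rng.integers(0, 2, n)
            if len(np.unique(truths)) < 2:
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            _, auc = roc_auc(scores, truths)
            assert auc == pytest.approx(brute_force_auc(scores, truths), abs=1e-9)

    def test_single_class_errors(self):
        with pytest.raises(EvaluationError):
            roc_auc([0.1, 0.2], [1, 1])


def _accuracy(d, t):
    return float((np.asarray(d) == np.asarray(t)).mean())


class TestBootstrapCi:
    def test_degenerate_all_correct(self):
        lo, hi = bootstrap_ci(_accuracy, [1, 1, 0], [1, 1, 0], B=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_matches_exhaustive_enumeration(self):
        # n=3 with one error: enumerate all 27 equally likely resamples
        d, t = [1, 1, 0], [1, 1, 1]
        outcomes = [
            _accuracy([d[i] for i in idx], [t[i] for i in idx])
            for idx in itertools.product(range(3), repeat=3)
        ]
        exact = np.quantile(outcomes, [0.025, 0.975], method="inverted_cdf")
        lo, hi = bootstrap_ci(_accuracy, d, t, B=20000, seed=1)
        assert (lo, hi) == pytest.approx(tuple(exact), abs=1e-9)

    def test_deterministic_given_seed(self):
        d = [1, 0, 1, 1, 0, 1]
        t = [1, 1, 1, 0, 0, 1]
        assert bootstrap_ci(_accuracy, d, t, B=500, seed=3) == bootstrap_ci(
            _accuracy, d, t, B=500, seed=3
        )

    def test_mostly_undefined_metric_errors(self):
        def undefined(d, t):
            return None

        with pytest.raises(EvaluationError):
            bootstrap_ci(undefined, [1, 0], [1, 0], B=100, seed=0)


class TestMcnemar:
    def test_binomial_tail_example(self):
        # b=10, c=2 discordant pairs: p = 2 * P(X <= 2 | 12, 1/2) = 158/4096
        model = [True] * 10 + [False] * 2 + [True] * 5
        surgeon = [False] * 10 + [True] * 2 + [True] * 5
        assert mcnemar(model, surgeon) == pytest.approx(158 / 4096)

    def test_symmetric_discordance_is_one(self):
        model = [True, False, True, False]
        surgeon = [False, True, False, True]
        assert mcnemar(model, surgeon) == 1.0

    def test_no_discordance_is_one(self):
        assert mcnemar([True, False], [True, False]) == 1.0


class TestImportance:
    def test_planted_feature_ranks_first(self, rng):
        from sklearn.ensemble import RandomForestClassifier

        n = 300
        y = rng.integers(0, 2, n)
        X = rng.normal(0, 1, (n, 6))
        X[:, 2] = y + rng.normal(0, 0.05, n)  # feature 2 mirrors the label
        model = RandomForestClassifier(n_estimators=100, random_state=0).fit(X, y)
        names = [f"f{i}" for i in range(6)]
        rep = importance_report(model, X, y, names, seed=0)
        assert rep["impurity"][0][0] == "f2"
        assert rep["permutation"][0][0] == "f2"

    def test_noise_feature_near_zero_permutation(self, rng):
        from sklearn.ensemble import RandomForestClassifier

        n = 300
        y = rng.integers(0, 2, n)
        X = rng.normal(0, 1, (n, 4))
        X[:, 0] = y + rng.normal(0, 0.05, n)
        model = RandomForestClassifier(n_estimators=100, random_state=0).fit(X, y)
        rep = importance_report(model, X, y, ["f0", "f1", "f2", "f3"], seed=0)
        perm = dict(rep["permutation"])
        assert abs(perm["f3"]) < 0.05

    def test_rankings_are_permutations(self, rng):
        from sklearn.ensemble import RandomForestClassifier

        y = rng.integers(0, 2, 100)
        X = rng.normal(0, 1, (100, 5))
        X[:, 0] += y
        model = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        rep = importance_report(model, X, y, list("abcde"), seed=0)
        for ranking in rep.values():
            assert sorted(n for n, _ in ranking) == sorted("abcde")

    def test_non_forest_impurity_errors(self):
        from sklearn.svm import SVC

        with pytest.raises(EvaluationError):
            require_impurity(SVC())
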