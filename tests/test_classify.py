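import math

import numpy as np
import pytest

from mammosub.classify import (
    CLASSIFIER_NAMES,
    CVPlan,
    EvalReport,
    auc,
    build_cv,
    fisher_compare,
    make_classifier,
    optimal_cutoff,
    train_eval,
)
from mammosub.phantom import make_feature_cohort


class TestBuildCV:
    def test_lopo_one_singleton_fold_per_patient(self):
        plan = build_cv(["A", "B", "C"], scheme="LOPO")
        assert len(plan.folds) == 3
        assert all(len(test) == 1 for _, test in plan.folds)
        assert sorted(t for _, test in plan.folds for t in test) == ["A", "B", "C"]

    def test_grouped_kfold_partitions_evenly(self):
        ids = [f"P{i}" for i in range(10)]
        plan = build_cv(ids, scheme="grouped_kfold", k=5, seed=0)
        assert len(plan.folds) == 5
        assert all(len(test) == 2 for _, test in plan.folds)

    def test_no_train_test_overlap_in_any_plan(self):
        for scheme, k in (("LOPO", 0), ("grouped_kfold", 3)):
            plan = build_cv([f"P{i}" for i in range(7)], scheme=scheme, k=k or 3, seed=1)
            for train, test in plan.folds:
                assert not set(train) & set(test)

    def test_overlapping_plan_rejected_by_invariant(self):
        with pytest.raises(ValueError):
            CVPlan(scheme="LOPO", folds=[(["A", "B"], ["B"])])

    def test_k_larger_than_patients_rejected(self):
        with pytest.raises(ValueError):
            build_cv(["A", "B"], scheme="grouped_kfold", k=3)


class TestOptimalCutoff:
    def test_separable_scores_give_zero_errors(self):
        t = optimal_cutoff(np.ones(5), np.zeros(5))
        assert 0.0 < t <= 1.0
        assert (np.zeros(5) >= t).sum() == 0 and (np.ones(5) < t).sum() == 0

    def test_identical_sets_balance_fp_fn(self, rng):
        s = rng.random(20)
        t = optimal_cutoff(s, s)
        fp, fn = int((s >= t).sum()), int((s < t).sum())
        assert fp == fn

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            pos = rng.random(rng.integers(2, 15))
            neg = rng.random(rng.integers(2, 15))
            t = optimal_cutoff(pos, neg)
            cands = np.concatenate([pos, neg, [max(pos.max(), neg.max()) + 1]])

            def key(th):
                fp = int((neg >= th).sum())
                fn = int((pos < th).sum())
                return (abs(fp - fn), fp + fn)

            assert key(t) == min(key(th) for th in cands)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutoff(np.array([]), np.array([0.5]))


class TestAUC:
    def test_perfect_separation_is_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auc(scores, labels) == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.random(1000)
        labels = rng.integers(0, 2, 1000)
        assert abs(auc(scores, labels) - 0.5) < 0.05

    def test_matches_pairwise_count_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 50))
            scores = rng.choice(np.linspace(0, 1, 11), n)  # force ties
            labels = np.concatenate([[0, 1], rng.integers(0, 2, n - 2)])
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum(
                1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
            )
            assert auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestFisher:
    def test_diagonal_table_closed_form(self):
        # full hypergeometric enumeration: only the two diagonal tables are
        # as extreme, each with probability 1/C(20,10)
        p = fisher_compare([10, 0], [0, 10])
        assert p == pytest.approx(2.0 / math.comb(20, 10), rel=1e-9)

    def test_identical_rows_give_p_one(self):
        assert fisher_compare([5, 5], [5, 5]) == 1.0

    def test_row_swap_symmetry(self, rng):
        for _ in range(5):
            a = list(rng.integers(0, 20, 2))
            b = list(rng.integers(0, 20, 2))
            assert fisher_compare(a, b) == pytest.approx(fisher_compare(b, a))

    def test_matches_enumeration_oracle(self):
        """Exhaustive conditional enumeration of all tables with the same
        margins, summing probabilities <= the observed table's."""
        a, b = [7, 3], [2, 8]
        n1, n2 = sum(a), sum(b)
        m1 = a[0] + b[0]

        def prob(x):
            return (
                math.comb(n1, x) * math.comb(n2, m1 - x) / math.comb(n1 + n2, m1)
            )

        p_obs = prob(a[0])
        p_exact = sum(
            prob(x)
            for x in range(max(0, m1 - n2), min(n1, m1) + 1)
            if prob(x) <= p_obs * (1 + 1e-9)
        )
        assert fisher_compare(a, b) == pytest.approx(p_exact, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_compare([-1, 2], [3, 4])


class TestEvalReport:
    def test_published_sensitivity_arithmetic(self):
        """93 of 114 positives found -> 81.6% sensitivity (a published
        ensemble-voting row)."""
        rep = EvalReport(tp=93, fn=21, tn=475, fp=40, auc=0.87, cutoff=0.5)
        assert rep.sensitivity == pytest.approx(81.6, abs=0.05)
        assert rep.specificity == pytest.approx(100 * 475 / 515, abs=0.05)
        assert rep.accuracy == pytest.approx(100 * 568 / 629, abs=0.05)


class TestTrainEval:
    def test_deterministic_given_seed(self):
        X, y, g = make_feature_cohort(8, 3.0, seed=5)
        cv = build_cv(g, "LOPO")
        r1 = train_eval(X, y, g, cv, classifiers=["decision_tree", "knn9"], seed=3)
        r2 = train_eval(X, y, g, cv, classifiers=["decision_tree", "knn9"], seed=3)
        for name in r1:
            assert r1[name].to_dict() == r2[name].to_dict()

    def test_separable_cohort_classified_well(self):
        X, y, g = make_feature_cohort(16, 6.0, seed=2)
        cv = build_cv(g, "LOPO")
        rep = train_eval(X, y, g, cv, classifiers=["random_forest"], seed=2)
        assert rep["random_forest"].accuracy > 80.0
        assert rep["random_forest"].auc > 0.9

    def test_all_folds_skipped_raises(self):
        X = np.random.default_rng(0).standard_normal((6, 4))
        y = np.array([0, 0, 0, 1, 1, 1])
        g = np.array(["A", "A", "A", "B", "B", "B"])  # each train fold single-class
        cv = build_cv(g, "LOPO")
        with pytest.raises(RuntimeError):
            train_eval(X, y, g, cv, classifiers=["knn9"], seed=0)

    def test_all_classifier_names_constructible(self):
        for name in CLASSIFIER_NAMES:
            assert make_classifier(name, seed=0) is not None
        with pytest.raises(ValueError):
            make_classifier("svm")
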