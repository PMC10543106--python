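"""Labeling, metrics, repeated CV, permutation machinery and consensus
extraction."""

from __future__ import annotations

import numpy as np
import pytest

from oracles import auc_bruteforce, r2_mse_bruteforce

from acupredict import cv_engine as cv
from acupredict.cv_engine import CVReport, ConsensusSet
from acupredict.selection_model import ThresholdGrid, make_grid


class TestLabels:
    @pytest.mark.parametrize("base,post,label", [
        (5.0, 2.0, 1),    # improvement 3
        (4.0, 2.0, 1),    # boundary: "at least two points"
        (3.0, 2.0, -1),   # improvement 1
    ])
    def test_responder_rule(self, base, post, label):
        ls = cv.assign_labels([base], [post])
        assert ls.responder[0] == label
        assert ls.improvement[0] == base - post

    def test_missing_post_score_rejected(self):
        with pytest.raises(ValueError, match="post"):
            cv.assign_labels([3.0, 4.0], [1.0, np.nan])

    def test_inconsistent_labelset_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            cv.LabelSet(np.array([1, 1]), np.array([3.0, 1.0]))


class TestClassificationMetrics:
    def test_perfect_ranking(self):
        m = cv.compute_classification_metrics([1, 1, -1, -1], [2, 1, -1, -2])
        assert m == {"accuracy": 1.0, "sensitivity": 1.0,
                     "specificity": 1.0, "auc": 1.0}

    def test_all_tied_decisions_give_auc_half(self):
        m = cv.compute_classification_metrics([1, -1, 1, -1], [0.5] * 4)
        assert m["auc"] == 0.5

    def test_auc_matches_pairwise_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(6, 20))
            y = np.where(rng.random(n) < 0.5, 1, -1)
            y[:2] = [1, -1]
            d = np.round(rng.normal(size=n), 1)  # ties likely
            m = cv.compute_classification_metrics(y, d)
            assert m["auc"] == pytest.approx(auc_bruteforce(y, d), abs=1e-12)

    def test_single_class_flagged_undefined(self):
        m = cv.compute_classification_metrics([1, 1, 1], [1.0, -0.5, 2.0])
        assert np.isnan(m["specificity"]) and np.isnan(m["auc"])
        assert m["accuracy"] == pytest.approx(2 / 3)

    def test_confusion_identity(self):
        rng = np.random.default_rng(1)
        y = np.where(rng.random(40) < 0.5, 1, -1)
        d = rng.normal(size=40)
        m = cv.compute_classification_metrics(y, d)
        pred = np.where(d >= 0, 1, -1)
        tp = np.sum((pred == 1) & (y == 1))
        tn = np.sum((pred == -1) & (y == -1))
        assert m["accuracy"] == pytest.approx((tp + tn) / 40, abs=1e-12)


class TestRegressionMetrics:
    def test_exact_predictions(self):
        m = cv.compute_regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m == {"r2": 1.0, "mse": 0.0}

    def test_mean_predictor_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        m = cv.compute_regression_metrics(y, np.full(4, y.mean()))
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_example_matches_formula(self):
        y = np.array([2.0, 4.0, 1.0, 3.0, 5.0])
        p = np.array([2.5, 3.5, 1.5, 2.0, 6.0])
        m = cv.compute_regression_metrics(y, p)
        r2, mse = r2_mse_bruteforce(y, p)
        assert m["r2"] == pytest.approx(r2, abs=1e-12)
        assert m["mse"] == pytest.approx(mse, abs=1e-12)

    def test_constant_truth_flagged(self):
        m = cv.compute_regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(m["r2"]) and m["mse"] > 0


def _signal_data(n=100, seed=0):
    """One feature fully determines the label; the rest are noise."""
    rng = np.random.default_rng(seed)
    driver = rng.normal(size=n)
    X = np.column_stack([driver, rng.normal(size=(n, 9))])
    y = np.where(driver >= np.median(driver), 1.0, -1.0)
    return X, y


class TestRepeatedCV:
    def test_realizable_signal_recovered(self):
        X, y = _signal_data()
        rep = cv.run_repeated_cv(X, y, ThresholdGrid((0.1, 0.5)),
                                 n_iterations=5, master_seed=3)
        assert rep.mean_metric("accuracy", 0) >= 0.95
        assert rep.mean_metric("accuracy", 1) >= 0.95  # driver has |rho| ~ 0.87

    def test_deterministic_under_master_seed(self):
        X, y = _signal_data(60, seed=1)
        r1 = cv.run_repeated_cv(X, y, ThresholdGrid((0.2,)), n_iterations=4,
                                master_seed=7, store_selection=True)
        r2 = cv.run_repeated_cv(X, y, ThresholdGrid((0.2,)), n_iterations=4,
                                master_seed=7, store_selection=True)
        for m in r1.metrics:
            assert np.array_equal(r1.metrics[m], r2.metrics[m], equal_nan=True)
        for a, b in zip(r1.selections, r2.selections):
            for fa, fb in zip(a, b):
                assert all(np.array_equal(x, y_) for x, y_ in zip(fa, fb))

    def test_iteration_mean_equals_fold_mean(self):
        """Recompute one iteration by hand with the same fold plan and
        check the aggregated accuracy is the mean of fold accuracies."""
        X, y = _signal_data(80, seed=2)
        thr = np.array([0.2])
        rep = cv.run_repeated_cv(X, y, ThresholdGrid((0.2,)), n_folds=10,
                                 n_iterations=1, master_seed=9)
        it_seed = cv._subseed(9, 0)
        folds = list(cv._fold_iterator(y, 10, "svc", True, it_seed))
        accs = []
        for train_idx, test_idx in folds:
            fit = cv.fit_fold(X, y, train_idx, thr)
            dec = fit.decide(X[test_idx], 0)
            accs.append(cv.compute_classification_metrics(y[test_idx], dec)["accuracy"])
        assert rep.metrics["accuracy"][0, 0] == pytest.approx(np.mean(accs), abs=1e-12)

    def test_leakage_ban_heldout_mutation_changes_nothing(self):
        X, y = _signal_data(50, seed=4)
        train_idx = np.arange(40)
        thr = np.array([0.1, 0.3])
        fit = cv.fit_fold(X, y, train_idx, thr)
        X_mut = X.copy()
        X_mut[40:] = 1e6  # arbitrary garbage in the held-out rows
        fit_mut = cv.fit_fold(X_mut, y, train_idx, thr)
        for s1, s2 in zip(fit.selections, fit_mut.selections):
            assert np.array_equal(s1, s2)
        for m1, m2 in zip(fit.models, fit_mut.models):
            assert np.array_equal(m1.weights, m2.weights)
            assert m1.bias == m2.bias
        assert np.array_equal(fit.center, fit_mut.center)
        assert np.array_equal(fit.scale, fit_mut.scale)

    def test_empty_selection_falls_back_to_majority(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        y = np.where(rng.random(40) < 0.7, 1.0, -1.0)
        fit = cv.fit_fold(X, y, np.arange(30), np.array([0.999]))
        assert fit.selections[0].size == 0
        dec = fit.decide(X[30:], 0)
        assert np.all(np.sign(dec) == np.sign(dec[0]))

    def test_svr_task_reports_pooled_r2(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 5))
        y = 2.0 * X[:, 0] + 0.1 * rng.normal(size=60)
        rep = cv.run_repeated_cv(X, y, ThresholdGrid((0.2,)), task="svr",
                                 n_iterations=3, master_seed=2)
        assert rep.mean_metric("r2") > 0.9
        assert rep.mean_metric("mse") < 0.5


class TestPermutation:
    def test_strong_signal_beats_all_nulls(self):
        X, y = _signal_data(60, seed=7)
        res = cv.permutation_test(X, y, threshold=0.1, B=20, n_folds=5,
                                  master_seed=1)
        assert res.p_value == pytest.approx(1 / 21)
        assert res.significant

    def test_pvalue_counting_formula(self):
        X, y = _signal_data(60, seed=8)
        res = cv.permutation_test(X, y, threshold=0.1, B=19, n_folds=5,
                                  master_seed=2)
        as_good = int(np.sum(res.null_stats >= res.observed))
        assert res.p_value == (1 + as_good) / 20
        assert 0 < res.p_value <= 1

    def test_lower_is_better_statistic(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 4))
        y = 3.0 * X[:, 1] + 0.2 * rng.normal(size=50)
        res = cv.permutation_test(X, y, threshold=0.1, statistic="mse",
                                  task="svr", B=20, n_folds=5, master_seed=3)
        assert res.better == "lower"
        assert res.observed < np.min(res.null_stats)
        assert res.significant and res.p_value == pytest.approx(1 / 21)


class TestOperatingThreshold:
    def _report(self, means):
        arr = np.asarray(means, dtype=float)[None, :]
        return CVReport("svc", np.linspace(0.05, 0.05 * len(means), len(means)),
                        {"accuracy": arr, "sensitivity": arr,
                         "specificity": arr, "auc": arr}, 10, 0)

    def test_max_rule_ties_to_larger_threshold(self):
        rep = self._report([0.6, 0.9, 0.9, 0.7])
        assert cv.select_operating_threshold(rep, "max_mean_accuracy") == \
            pytest.approx(0.15)

    def test_monotone_curve_picks_last(self):
        rep = self._report([0.5, 0.6, 0.7, 0.8])
        assert cv.select_operating_threshold(rep, "max_mean_accuracy") == \
            pytest.approx(0.20)

    def test_plateau_on_flat_curve_picks_first(self):
        rep = self._report([0.7, 0.7, 0.7, 0.7])
        assert cv.select_operating_threshold(rep, "plateau", window=3) == \
            pytest.approx(0.05)

    def test_fixed_rule(self):
        rep = self._report([0.5, 0.6])
        assert cv.select_operating_threshold(rep, "fixed", value=0.15) == 0.15

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            cv.select_operating_threshold(self._report([0.5]), "best_ever")


def _toy_report(selections, weights, thresholds=(0.15,), ids=None):
    n_it = len(selections)
    metrics = {m: np.zeros((n_it, len(thresholds)))
               for m in ("accuracy", "sensitivity", "specificity", "auc")}
    return CVReport("svc", np.asarray(thresholds), metrics, len(selections[0]),
                    0, feature_ids=ids, selections=selections, weights=weights)


class TestConsensus:
    def test_feature_missing_in_one_fold_excluded(self):
        # 2 iterations x 2 folds; feature 1 drops from one fold once
        sel = [
            [[np.array([0, 1])], [np.array([0, 1])]],
            [[np.array([0, 1])], [np.array([0])]],
        ]
        wts = [
            [[np.array([0.5, 0.2])], [np.array([0.3, 0.4])]],
            [[np.array([0.1, 0.6])], [np.array([0.7])]],
        ]
        cons = cv.extract_consensus(_toy_report(sel, wts), 0.15)
        assert list(cons.feature_indices) == [0]
        # fold-mean weights per iteration for feature 0
        assert cons.weight_trace[:, 0] == pytest.approx([0.4, 0.4])

    def test_always_retained_feature_survives(self):
        sel = [[[np.array([2])], [np.array([2])]] for _ in range(3)]
        wts = [[[np.array([0.3])], [np.array([-0.1])]] for _ in range(3)]
        cons = cv.extract_consensus(_toy_report(sel, wts), 0.15)
        assert list(cons.feature_indices) == [2]
        assert cons.weight_trace[:, 0] == pytest.approx([0.1, 0.1, 0.1])

    def test_empty_consensus_warns_but_returns(self):
        sel = [[[np.array([0])], [np.array([1])]]]
        wts = [[[np.array([0.5])], [np.array([0.5])]]]
        with pytest.warns(UserWarning, match="empty"):
            cons = cv.extract_consensus(_toy_report(sel, wts), 0.15)
        assert cons.size == 0

    def test_consensus_shrinks_with_more_iterations(self, signal_features,
                                                    signal_labels):
        common = dict(grid=ThresholdGrid((0.15,)), n_folds=10, master_seed=5,
                      store_selection=True, store_weights=True)
        rep5 = cv.run_repeated_cv(signal_features, signal_labels,
                                  n_iterations=5, **common)
        rep10 = cv.run_repeated_cv(signal_features, signal_labels,
                                   n_iterations=10, **common)
        c5 = set(cv.extract_consensus(rep5, 0.15).feature_indices.tolist())
        c10 = set(cv.extract_consensus(rep10, 0.15).feature_indices.tolist())
        assert c10 <= c5

    def test_consensus_requires_stored_selection(self, signal_features,
                                                 signal_labels):
        rep = cv.run_repeated_cv(signal_features, signal_labels,
                                 ThresholdGrid((0.15,)), n_iterations=1,
                                 master_seed=5)
        with pytest.raises(ValueError, match="store"):
            cv.extract_consensus(rep, 0.15)


class TestExternalValidation:
    def test_empty_predictive_set_rejected(self):
        cons = ConsensusSet(np.array([], dtype=int), [], [], np.zeros((1, 0)))
        with pytest.raises(ValueError, match="empty"):
            cv.validate_external(cons, np.zeros((10, 5)), np.ones(10))

    def test_missing_columns_rejected(self, signal_features, signal_labels):
        cons = ConsensusSet(np.array([0, 1]), ["gender", "not_a_feature"],
                            [], np.zeros((1, 2)))
        with pytest.raises(KeyError, match="not_a_feature"):
            cv.validate_external(cons, signal_features, signal_labels, B=1,
                                 n_iterations=1)
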