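"""Task construction, blocked CV structure, learners and the R^2 rules."""

import numpy as np
import pandas as pd
import pytest

from physioappraisal import CVScheme, LearnerSettings
from physioappraisal.benchmark import (
    blocked_cv_assign,
    build_task,
    fit_learner,
    out_of_sample_r2,
    ridge_preprocess,
    robustness,
    run_benchmark,
)
from physioappraisal.config import MISSING_CODE
from physioappraisal.errors import ConfigError, EmptyTaskError

from conftest import make_block_task, table_from_task


def _small_table_and_ratings():
    task = make_block_task(0, n_subjects=5, rows_per_subject=2)
    table = table_from_task(task)
    idx = table.data.index
    ratings = pd.DataFrame(
        {
            "subject": idx.get_level_values("subject"),
            "video": idx.get_level_values("video"),
            "item": [2, 3, MISSING_CODE, 4, 5, MISSING_CODE, 1, 2, MISSING_CODE, 3],
        }
    )
    return table, ratings


class TestBuildTask:
    def test_missing_exclusion_count(self):
        table, ratings = _small_table_and_ratings()
        task = build_task(table, ratings, "item")
        assert task.n == 7
        assert not np.any(task.y == MISSING_CODE)

    def test_reversal_maps_r_to_six_minus_r(self):
        table, ratings = _small_table_and_ratings()
        plain = build_task(table, ratings, "item")
        reversed_ = build_task(table, ratings, "item", reversal_flags={"item": True})
        np.testing.assert_allclose(reversed_.y, 6.0 - plain.y)

    def test_identity_without_missing_or_reversal(self):
        table, ratings = _small_table_and_ratings()
        ratings = ratings.copy()
        ratings.loc[ratings.item == MISSING_CODE, "item"] = 3
        task = build_task(table, ratings, "item")
        assert task.n == 10
        np.testing.assert_allclose(np.sort(task.y), np.sort(ratings.item.to_numpy(float)))

    def test_all_missing_is_an_error(self):
        table, ratings = _small_table_and_ratings()
        ratings["item"] = MISSING_CODE
        with pytest.raises(EmptyTaskError):
            build_task(table, ratings, "item")


class TestBlockedCV:
    def test_100_test_sets_and_partition_property(self):
        task = make_block_task(1, n_subjects=12, rows_per_subject=4)
        scheme = CVScheme(repetitions=20, folds=5, seed=3)
        assignments = blocked_cv_assign(task.groups, scheme)
        assert len(assignments) == 20
        total_test_sets = 0
        for fold_ids in assignments:
            assert sorted(np.unique(fold_ids)) == [0, 1, 2, 3, 4]
            counts = np.bincount(fold_ids)
            assert counts.sum() == task.n  # every row in exactly one fold
            total_test_sets += 5
            # blocking: all rows of one subject share a fold
            for subj in np.unique(task.groups):
                folds = np.unique(fold_ids[task.groups == subj])
                assert folds.size == 1
        assert total_test_sets == 100

    def test_assignment_varies_across_repetitions(self):
        task = make_block_task(1, n_subjects=15, rows_per_subject=2)
        assignments = blocked_cv_assign(task.groups, CVScheme(repetitions=5, folds=5, seed=0))
        assert any(
            not np.array_equal(assignments[0], other) for other in assignments[1:]
        )

    def test_fewer_subjects_than_folds_rejected(self):
        task = make_block_task(1, n_subjects=3, rows_per_subject=2)
        with pytest.raises(ConfigError):
            blocked_cv_assign(task.groups, CVScheme(repetitions=1, folds=5))


class TestOutOfSampleR2:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert out_of_sample_r2(y, y) == pytest.approx(1.0)

    def test_test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert out_of_sample_r2(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_negative_score(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([4.0, 3.0, 2.0, 1.0])
        assert out_of_sample_r2(y, pred) == pytest.approx(-3.0)

    def test_zero_test_variance_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            out_of_sample_r2(np.array([2.0, 2.0]), np.array([1.0, 2.0]))


class TestLearners:
    def test_featureless_predicts_train_mean(self):
        X = np.zeros((5, 3))
        model = fit_learner("FL", X, np.array([1.0, 2, 3, 4, 6]), LearnerSettings())
        np.testing.assert_allclose(model.predict(np.zeros((7, 3))), 3.2)

    def test_ridge_shrinks_to_mean_at_huge_penalty(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 10))
        y = rng.standard_normal(50) + 3.0
        model = fit_learner("RIDGE", X, y, LearnerSettings(ridge_alpha=1e12))
        np.testing.assert_allclose(model.predict(X), y.mean(), atol=1e-6)

    def test_rf_fits_noisefree_single_feature_function(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-2, 2, size=(300, 1))
        y = np.sin(X[:, 0])
        settings = LearnerSettings(rf_n_estimators=100, rf_min_samples_leaf=1)
        model = fit_learner("RF", X, y, settings, seed=0)
        assert out_of_sample_r2(y, model.predict(X)) > 0.9

    def test_unknown_learner_rejected(self):
        with pytest.raises(ConfigError):
            fit_learner("SVM", np.zeros((2, 2)), np.zeros(2), LearnerSettings())


class TestRidgePreprocess:
    def test_hand_computed_outlier_is_imputed_from_retained_values(self):
        col = np.zeros(100)
        col[17] = 100.0  # mean 1, sample SD 10, z = 9.9
        train = col[:, None]
        out_train, out_apply = ridge_preprocess(train, train.copy(), seed=0)
        assert out_train[17, 0] == 0.0  # draws come from the all-zero retained pool
        assert out_apply[17, 0] == 0.0

    def test_inliers_unchanged(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, size=(40, 5))
        out, _ = ridge_preprocess(X, X.copy(), seed=1)
        np.testing.assert_array_equal(out, X)

    def test_same_seed_same_imputations(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 4))
        X[0, 0] = 50.0
        a, _ = ridge_preprocess(X, X.copy(), seed=9)
        b, _ = ridge_preprocess(X, X.copy(), seed=9)
        np.testing.assert_array_equal(a, b)


class TestRobustness:
    @pytest.mark.parametrize(
        "positives,expected", [(86, True), (85, True), (84, False), (100, True)]
    )
    def test_85_percent_rule(self, positives, expected):
        values = np.concatenate([np.ones(positives), -np.ones(100 - positives)])
        assert robustness(values) is expected

    def test_zeros_count_as_non_positive(self):
        values = np.concatenate([np.ones(84), np.zeros(16)])
        assert robustness(values) is False


class TestRunBenchmark:
    def test_fl_fold_scores_never_positive(self):
        task = make_block_task(5, n_subjects=12, rows_per_subject=4)
        scheme = CVScheme(repetitions=4, folds=4, seed=1)
        (res,) = run_benchmark(task, scheme, learners=("FL",))
        assert res.fold_scores.size == 16
        assert np.all(res.fold_scores <= 1e-12)

    def test_all_noise_target_is_not_robust(self):
        task = make_block_task(6, n_subjects=15, rows_per_subject=4, signal_block=None)
        scheme = CVScheme(repetitions=4, folds=5, seed=2)
        settings = LearnerSettings(rf_n_estimators=50)
        results = run_benchmark(task, scheme, settings=settings)
        for res in results:
            assert res.aggregate < 0.05
            assert not res.robust

    def test_signal_task_recovered_by_rf(self):
        task = make_block_task(7, n_subjects=15, rows_per_subject=4, noise_sd=0.2)
        scheme = CVScheme(repetitions=4, folds=5, seed=3)
        settings = LearnerSettings(rf_n_estimators=50)
        (res,) = run_benchmark(task, scheme, learners=("RF",), settings=settings)
        assert res.aggregate > 0.3
        assert res.robust
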