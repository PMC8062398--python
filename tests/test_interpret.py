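"""Interpretable-set rule, single-feature models, ALE correctness."""

import numpy as np
import pandas as pd
import pytest

from physioappraisal import LearnerSettings
from physioappraisal.errors import ConfigError
from physioappraisal.features import feature_blocks
from physioappraisal.interpret import (
    ale_profile,
    fit_single_feature_model,
    interpretable_features,
    select_best_feature,
    single_feature_importance,
)

from conftest import make_block_task

FAST = LearnerSettings(rf_n_estimators=40)


def test_interpretable_set_membership_rule():
    all_cols = [c for cols in feature_blocks().values() for c in cols]
    selected = set(interpretable_features(all_cols))
    assert "zyg.mav" in selected
    assert "eda.rms" in selected
    assert "front.log_detector" in selected
    assert "zyg.abs_moment4" in selected
    assert "hrv.sdnn" in selected and "hrv.pnn50" in selected
    assert "hrv.lf_hf" not in selected  # band ratio excluded
    assert "hrv.sd2_sd1" not in selected  # Poincare measure excluded
    assert "zyg.ar1" not in selected  # not an amplitude feature
    assert "eda.peak_freq" not in selected
    # EMG amplitude family: 9 features x 4 sampled channels + 6 HRV
    assert len(selected) == 9 * 4 + 6


def test_single_feature_importance_matches_block_machinery_and_depth():
    task = make_block_task(0, n_subjects=12, rows_per_subject=4, noise_sd=0.2)
    feat = task.blocks["zyg"][0]
    res = single_feature_importance(task, feat, settings=FAST, n_iter=10, seed=2)
    from physioappraisal.importance import r2_block

    same = r2_block(task, [feat], settings=FAST, n_iter=10, seed=2, max_depth=3)
    np.testing.assert_array_equal(res.iteration_values, same.iteration_values)

    model = fit_single_feature_model(task, feat, settings=FAST, seed=0, tree_depth=3)
    assert all(est.tree_.max_depth <= 3 for est in model.estimators_)
    with pytest.raises(ConfigError):
        single_feature_importance(task, "missing.f9", n_iter=2)


def test_select_best_feature_prefers_signal_then_lexicographic_ties():
    task = make_block_task(1, n_subjects=14, rows_per_subject=4, noise_sd=0.2)
    driver = task.blocks["zyg"][0]
    best, results = select_best_feature(
        task, [driver, task.blocks["hrv"][0]], settings=FAST, n_iter=20, seed=3
    )
    assert best == driver
    assert results[driver].robust

    # duplicate columns give identical importance: the tie breaks to the
    # lexicographically smaller id
    task.X["aaa.dup"] = task.X[driver]
    task.X["zzz.dup"] = task.X[driver]
    best_tie, _ = select_best_feature(
        task, ["zzz.dup", "aaa.dup"], settings=FAST, n_iter=20, seed=3
    )
    assert best_tie == "aaa.dup"


def test_select_best_feature_returns_none_without_robust_candidate():
    task = make_block_task(2, n_subjects=12, rows_per_subject=4, signal_block=None)
    best, results = select_best_feature(
        task, [task.blocks["eda"][0], task.blocks["hrv"][0]], settings=FAST, n_iter=20, seed=1
    )
    assert best is None
    assert not any(r.robust for r in results.values())


class _Constant:
    def predict(self, X):
        return np.full(np.asarray(X).shape[0], 1.7)


class _Identity:
    def __init__(self, col):
        self.col = col

    def predict(self, X):
        return np.asarray(X)[:, self.col]


class _Linear2:
    def predict(self, X):
        X = np.asarray(X)
        return 2.0 * X[:, 0] - 1.5 * X[:, 1]


def _frame(n=400, rho=0.6, seed=0):
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rho * x1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return pd.DataFrame({"a": x1, "b": x2})


def test_ale_of_ignored_feature_is_zero():
    X = _frame()
    profile = ale_profile(_Constant(), X, "a", n_intervals=10)
    np.testing.assert_allclose(profile.effects, 0.0, atol=1e-12)


def test_ale_of_identity_model_is_centered_feature():
    X = _frame(seed=1)
    profile = ale_profile(_Identity(0), X, "a", n_intervals=20)
    x = X["a"].to_numpy()
    in_range = (x >= profile.grid[0]) & (x <= profile.grid[-1])
    wmean = np.average(
        np.repeat(profile.grid[1:], profile.n_per_interval.astype(int))
    )
    expected = profile.grid - wmean
    spacing = np.max(np.diff(profile.grid))
    assert np.max(np.abs(profile.effects - expected)) < spacing
    assert in_range.sum() == profile.n_per_interval.sum()


def test_ale_centering_identity():
    X = _frame(seed=2)
    profile = ale_profile(_Identity(0), X, "a", n_intervals=15)
    weighted = np.sum(profile.n_per_interval * profile.effects[1:])
    assert abs(weighted / profile.n_per_interval.sum()) < 1e-10


def test_ale_quantile_restriction():
    X = _frame(seed=3)
    profile = ale_profile(_Identity(0), X, "a", n_intervals=12, quantile_range=(0.05, 0.95))
    q05, q95 = np.quantile(X["a"], [0.05, 0.95])
    assert profile.grid[0] >= q05 - 1e-12
    assert profile.grid[-1] <= q95 + 1e-12
    assert np.all(np.diff(profile.grid) > 0)


def test_ale_additive_model_decomposes_per_feature():
    """For an additive linear model on correlated inputs, each feature's ALE
    matches its own component's slope."""
    X = _frame(n=800, rho=0.7, seed=4)
    model = _Linear2()
    pa = ale_profile(model, X, "a", n_intervals=20)
    pb = ale_profile(model, X, "b", n_intervals=20)
    for profile, slope, col in ((pa, 2.0, "a"), (pb, -1.5, "b")):
        grid_dev = profile.grid - np.average(
            np.repeat(profile.grid[1:], profile.n_per_interval.astype(int))
        )
        spacing = np.max(np.abs(np.diff(profile.grid)))
        assert np.max(np.abs(profile.effects - slope * grid_dev)) < abs(slope) * spacing, col


def test_ale_rejects_degenerate_feature():
    X = pd.DataFrame({"a": np.ones(50)})
    with pytest.raises(ValueError):
        ale_profile(_Identity(0), X, "a", n_intervals=5)
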