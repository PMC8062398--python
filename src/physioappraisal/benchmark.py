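"""Subject-blocked cross-validated prediction benchmark.

One regression task per appraisal item (134 features -> 1-5 rating, missing
"does not apply" answers excluded, negative-poled items reversed), evaluated
with a 20 x 5 cross-validation in which all observations of one subject
share a fold.  Three learners are compared: a featureless mean predictor
(FL), ridge regression on standardized features with a 3-SD outlier
elimination + empirical-imputation step (RIDGE), and a random forest (RF).
Performance is the out-of-sample R^2 per test fold, aggregated by unweighted
mean over the 100 folds; an appraisal counts as robustly predictable when at
least 85% of the fold scores are strictly positive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.preprocessing import StandardScaler

from .config import MISSING_CODE, CVScheme, LearnerSettings
from .datatypes import CVResult, FeatureTable, RegressionTask
from .errors import ConfigError, EmptyTaskError

LEARNERS = ("FL", "RIDGE", "RF")


# ---------------------------------------------------------------------------
# task construction

def build_task(
    features: FeatureTable,
    appraisals: pd.DataFrame,
    appraisal_id: str,
    reversal_flags: dict[str, bool] | None = None,
) -> RegressionTask:
    """Align feature rows with one item's ratings; drop missing, reverse polarity."""
    if appraisal_id not in appraisals.columns:
        raise ConfigError(f"build_task: unknown appraisal {appraisal_id!r}")
    ratings = appraisals.set_index(["subject", "video"])[appraisal_id]
    ratings = ratings.reindex(features.data.index)
    keep = ratings.notna() & (ratings != MISSING_CODE)
    if not keep.any():
        raise EmptyTaskError(f"build_task: no observations left for {appraisal_id!r}")
    y = ratings[keep].to_numpy(dtype=float)
    if reversal_flags and reversal_flags.get(appraisal_id, False):
        y = 6.0 - y
    X = features.data.loc[keep.to_numpy()]
    groups = X.index.get_level_values("subject").to_numpy()
    return RegressionTask(
        appraisal_id=appraisal_id,
        X=X,
        y=y,
        groups=groups,
        blocks=dict(features.blocks),
    )


# ---------------------------------------------------------------------------
# blocked resampling

def blocked_cv_assign(groups: np.ndarray, scheme: CVScheme) -> list[np.ndarray]:
    """Fold id per row, one array per repetition.

    Within each repetition subjects are shuffled by a seeded permutation and
    dealt round-robin into near-equal folds, so all rows of a subject share
    a fold and the partitions differ across repetitions.
    """
    scheme.validate()
    groups = np.asarray(groups)
    subjects = np.unique(groups)
    if subjects.size < scheme.folds:
        raise ConfigError(
            f"blocked_cv_assign: {subjects.size} subjects < {scheme.folds} folds"
        )
    assignments = []
    for rep in range(scheme.repetitions):
        rng = np.random.default_rng([scheme.seed & 0x7FFFFFFF, 101, rep])
        order = rng.permutation(subjects)
        fold_of = {subj: i % scheme.folds for i, subj in enumerate(order)}
        assignments.append(np.array([fold_of[g] for g in groups]))
    return assignments


def blocked_split(groups: np.ndarray, train_fraction: float, rng: np.random.Generator):
    """One subject-blocked train/test split (train_fraction of *subjects*)."""
    subjects = np.unique(groups)
    order = rng.permutation(subjects)
    n_train = max(1, min(subjects.size - 1, int(round(train_fraction * subjects.size))))
    train_subjects = set(order[:n_train])
    train_mask = np.array([g in train_subjects for g in groups])
    return np.nonzero(train_mask)[0], np.nonzero(~train_mask)[0]


# ---------------------------------------------------------------------------
# scoring and learners

def out_of_sample_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """1 - SS_res / SS_tot against the *test-fold* mean; may be negative."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("out_of_sample_r2: need equal, nonzero-length arrays")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot <= 0:
        raise ZeroDivisionError("out_of_sample_r2: zero variance in the test fold")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


class MeanPredictor:
    """Featureless learner: predicts the training mean everywhere."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


def ridge_preprocess(
    train_X: np.ndarray, apply_X: np.ndarray, seed: int, outlier_z: float = 3.0
):
    """3-SD outlier elimination with empirical imputation, learned on train.

    Per feature column: values with |z| > ``outlier_z`` (mean/SD from the
    training fold) are eliminated and replaced by seeded draws (with
    replacement) from the column's retained training values; the training
    thresholds are applied to both sets.  Columns whose training values are
    all eliminated are dropped (with a warning).
    """
    train_X = np.asarray(train_X, dtype=float).copy()
    apply_X = np.asarray(apply_X, dtype=float).copy()
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    keep_cols = []
    for j in range(train_X.shape[1]):
        col = train_X[:, j]
        mu, sd = col.mean(), col.std(ddof=1) if col.size > 1 else 0.0
        if sd == 0:
            keep_cols.append(j)
            continue
        bad_train = np.abs(col - mu) > outlier_z * sd
        retained = col[~bad_train]
        if retained.size == 0:
            warnings.warn(f"ridge_preprocess: column {j} fully eliminated; dropped")
            continue
        keep_cols.append(j)
        if bad_train.any():
            train_X[bad_train, j] = rng.choice(retained, size=int(bad_train.sum()))
        bad_apply = np.abs(apply_X[:, j] - mu) > outlier_z * sd
        if bad_apply.any():
            apply_X[bad_apply, j] = rng.choice(retained, size=int(bad_apply.sum()))
    return train_X[:, keep_cols], apply_X[:, keep_cols]


def make_rf(settings: LearnerSettings, n_features: int, seed: int, max_depth=None):
    return RandomForestRegressor(
        n_estimators=settings.rf_n_estimators,
        max_features=settings.rf_max_features(n_features),
        min_samples_leaf=settings.rf_min_samples_leaf,
        max_depth=max_depth if max_depth is not None else settings.rf_max_depth,
        random_state=seed & 0x7FFFFFFF,
        n_jobs=1,
    )


def fit_learner(
    kind: str,
    train_X: np.ndarray,
    train_y: np.ndarray,
    settings: LearnerSettings,
    seed: int = 0,
):
    """Fit one of FL / RIDGE / RF; returns a ``predict(X)``-capable model.

    RIDGE standardizes features and expects :func:`ridge_preprocess` to have
    been applied already (it is fold-local by construction).
    """
    if kind == "FL":
        return MeanPredictor().fit(train_X, train_y)
    if kind == "RIDGE":
        scaler = StandardScaler().fit(train_X)
        model = Ridge(alpha=settings.ridge_alpha).fit(scaler.transform(train_X), train_y)

        class _Pipe:
            def predict(self, X):
                return model.predict(scaler.transform(X))

        return _Pipe()
    if kind == "RF":
        return make_rf(settings, train_X.shape[1], seed).fit(train_X, train_y)
    raise ConfigError(f"fit_learner: unknown learner {kind!r}")


# ---------------------------------------------------------------------------
# benchmark driver

def robustness(values: np.ndarray, min_positive_fraction: float = 0.85) -> bool:
    """True iff at least 85% of the values are strictly positive."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("robustness: empty values")
    return bool(np.count_nonzero(values > 0) / values.size >= min_positive_fraction)


def run_benchmark(
    task: RegressionTask,
    scheme: CVScheme,
    learners=LEARNERS,
    settings: LearnerSettings = LearnerSettings(),
) -> list[CVResult]:
    """Run the blocked 20 x 5 benchmark for each requested learner."""
    assignments = blocked_cv_assign(task.groups, scheme)
    X_all = task.X.to_numpy(dtype=float)
    results = []
    for kind in learners:
        scores = []
        skipped = 0
        for rep, fold_ids in enumerate(assignments):
            for fold in range(scheme.folds):
                test = fold_ids == fold
                train = ~test
                assert not set(task.groups[train]) & set(task.groups[test]), "subject leakage"
                fold_seed = ((scheme.seed & 0xFFFF) << 14) | (rep << 4) | fold
                Xtr, Xte = X_all[train], X_all[test]
                if kind == "RIDGE":
                    Xtr, Xte = ridge_preprocess(Xtr, Xte, fold_seed, settings.outlier_z)
                model = fit_learner(kind, Xtr, task.y[train], settings, seed=fold_seed)
                try:
                    scores.append(out_of_sample_r2(task.y[test], model.predict(Xte)))
                except ZeroDivisionError:
                    warnings.warn(
                        f"{task.appraisal_id}/{kind}: zero-variance test fold "
                        f"(rep {rep}, fold {fold}) skipped"
                    )
                    skipped += 1
        scores = np.asarray(scores)
        results.append(
            CVResult(
                appraisal_id=task.appraisal_id,
                learner=kind,
                fold_scores=scores,
                aggregate=float(scores.mean()),
                q15=float(np.quantile(scores, 0.15)),
                robust=robustness(scores),
                n=task.n,
                n_skipped_folds=skipped,
            )
        )
    return results


def benchmark_report(results: list[CVResult]) -> pd.DataFrame:
    rows = [
        {
            "appraisal": r.appraisal_id,
            "learner": r.learner,
            "aggregate_r2": r.aggregate,
            "q15": r.q15,
            "robust": r.robust,
            "n": r.n,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
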