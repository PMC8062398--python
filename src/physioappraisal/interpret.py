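"""Single-feature importance and accumulated-local-effects interpretation.

For each predictable appraisal the interpretable candidate set (amplitude
features of the EMG/EDA channels plus the time-domain HRV features) is
screened with a single-feature random forest of maximum depth 3 using the
same blocked resampling as the channel importance; the candidate with the
most robust importance is selected and its first-order ALE profile is
computed over 20 quantile intervals restricted to the feature's 5-95%
quantile range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ImportanceSettings, InterpretSettings, LearnerSettings
from .datatypes import ALEProfile, BlockImportanceResult, RegressionTask
from .errors import ConfigError
from .importance import r2_block

#: Amplitude-height feature family (clearly tied to muscle contraction for
#: EMG and sympathetic arousal for EDA).
AMPLITUDE_FEATURES = (
    "mav",
    "mav_trim20",
    "tmav",
    "ssi",
    "rms",
    "abs_moment3",
    "abs_moment4",
    "abs_moment5",
    "log_detector",
)

#: HRV time-domain features (all describe beat-to-beat variability); the
#: frequency-band ratio and the Poincare shape measure are excluded.
HRV_TIME_DOMAIN = ("sdnn", "rmssd", "pnn50", "tinn", "tri_index", "rel_rr_tri_index")


def interpretable_features(columns) -> list[str]:
    """Membership derived by rule from the feature ids, never hand-listed."""
    out = []
    for col in columns:
        channel, name = col.split(".", 1)
        if channel in ("zyg", "corr", "front", "eda") and name in AMPLITUDE_FEATURES:
            out.append(col)
        elif channel == "hrv" and name in HRV_TIME_DOMAIN:
            out.append(col)
    return out


def single_feature_importance(
    task: RegressionTask,
    feature_id: str,
    settings: LearnerSettings = LearnerSettings(),
    n_iter: int = 100,
    seed: int = 0,
    tree_depth: int = 3,
    train_fraction: float = 0.6,
) -> BlockImportanceResult:
    """R2_B machinery with B = {feature} and tree depth capped at 3."""
    if feature_id not in task.X.columns:
        raise ConfigError(f"single_feature_importance: unknown feature {feature_id!r}")
    return r2_block(
        task,
        [feature_id],
        settings=settings,
        n_iter=n_iter,
        train_fraction=train_fraction,
        seed=seed,
        max_depth=tree_depth,
        measure_name="R2_feature",
    )


def select_best_feature(
    task: RegressionTask,
    candidate_set,
    settings: LearnerSettings = LearnerSettings(),
    n_iter: int = 100,
    seed: int = 0,
    tree_depth: int = 3,
):
    """Robustness gate first, then highest mean importance; ties broken
    lexicographically.  Returns (feature_id or None, per-candidate results)."""
    if not candidate_set:
        raise ConfigError("select_best_feature: empty candidate set")
    results = {
        feat: single_feature_importance(
            task, feat, settings=settings, n_iter=n_iter, seed=seed, tree_depth=tree_depth
        )
        for feat in candidate_set
    }
    robust = [(feat, r.mean) for feat, r in results.items() if r.robust]
    if not robust:
        return None, results
    best = min(robust, key=lambda fr: (-fr[1], fr[0]))
    return best[0], results


def ale_profile(
    model,
    X: pd.DataFrame,
    feature_id: str,
    n_intervals: int = 20,
    quantile_range: tuple[float, float] = (0.05, 0.95),
) -> ALEProfile:
    """First-order accumulated local effects of one feature.

    Interval boundaries are empirical quantiles of the feature restricted to
    ``quantile_range``; per interval the mean prediction difference between
    the upper and lower boundary (other features untouched) is accumulated
    and the profile is centered by the occupancy-weighted mean.
    """
    if feature_id not in X.columns:
        raise ConfigError(f"ale_profile: unknown feature {feature_id!r}")
    x = X[feature_id].to_numpy(dtype=float)
    q_lo, q_hi = quantile_range
    qs = np.quantile(x, np.linspace(q_lo, q_hi, n_intervals + 1))
    grid = np.unique(qs)
    if grid.size < 2:
        raise ValueError(f"ale_profile: feature {feature_id!r} has no spread in the quantile range")
    k = grid.size - 1

    in_range = (x >= grid[0]) & (x <= grid[-1])
    idx = np.clip(np.searchsorted(grid, x[in_range], side="left") - 1, 0, k - 1)
    X_in = X.loc[in_range].copy()

    local = np.zeros(k)
    n_per = np.zeros(k)
    for j in range(k):
        rows = idx == j
        n_j = int(rows.sum())
        n_per[j] = n_j
        if n_j == 0:
            continue
        X_hi = X_in.loc[rows].copy()
        X_lo = X_hi.copy()
        X_hi[feature_id] = grid[j + 1]
        X_lo[feature_id] = grid[j]
        local[j] = float(np.mean(model.predict(X_hi.to_numpy(float)) - model.predict(X_lo.to_numpy(float))))

    effects = np.concatenate([[0.0], np.cumsum(local)])
    total = n_per.sum()
    if total > 0:
        center = float(np.sum(n_per * effects[1:]) / total)
        effects = effects - center
    return ALEProfile(feature_id=feature_id, grid=grid, effects=effects, n_per_interval=n_per)


def fit_single_feature_model(
    task: RegressionTask,
    feature_id: str,
    settings: LearnerSettings = LearnerSettings(),
    seed: int = 0,
    tree_depth: int = 3,
):
    """Depth-3 random forest on the single feature (the model the ALE plots use)."""
    from .benchmark import make_rf

    X = task.X[[feature_id]].to_numpy(dtype=float)
    rf = make_rf(settings, 1, seed, max_depth=tree_depth)
    return rf.fit(X, task.y)


def ale_table(profile: ALEProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": profile.feature_id,
            "grid_value": profile.grid,
            "effect": profile.effects,
            "n_interval": np.concatenate([[0], profile.n_per_interval]).astype(int),
        }
    )


def plot_ale(profile: ALEProfile, path) -> None:
    """Minimal line-plot writer (PNG) for one ALE profile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile.grid, profile.effects, marker="o", ms=3)
    ax.axhline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel(profile.feature_id)
    ax.set_ylabel("accumulated local effect")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
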