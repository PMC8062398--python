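"""Blocked channel-importance measures R2_B and dR2_B.

R2_B: mean out-of-sample R^2 over 100 subject-blocked 60/40 splits of a
random forest trained on one channel block alone (the block's "main
effect", shared variance included).  dR2_B: mean difference, over the same
kind of splits, between the full-model R^2 and the R^2 of the model trained
without the block (the variance the block uniquely explains).  A measure is
robust when at least 85% of its 100 iteration values are strictly positive;
non-robust entries are masked in the report.

Iteration i of either measure derives its split from ``seed + i``, so R2_B
and dR2_B requested with the same seed share splits iteration by iteration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ImportanceSettings, LearnerSettings
from .datatypes import BlockImportanceResult, RegressionTask
from .errors import ConfigError
from .benchmark import blocked_split, make_rf, out_of_sample_r2, robustness


def _resolve_block(task: RegressionTask, block) -> list[str]:
    """A block name (channel) or an explicit column list -> column list."""
    if isinstance(block, str):
        if block not in task.blocks:
            raise ConfigError(f"unknown block {block!r}")
        cols = list(task.blocks[block])
    else:
        cols = list(block)
    unknown = [c for c in cols if c not in task.X.columns]
    if unknown:
        raise ConfigError(f"block columns not in task: {unknown}")
    if not cols:
        raise ConfigError("block is empty")
    return cols


def _iteration_seed(seed: int, i: int) -> int:
    return (seed + i) & 0x7FFFFFFF


def _split_for_iteration(task, train_fraction, seed, i):
    rng = np.random.default_rng([_iteration_seed(seed, i), 202])
    return blocked_split(task.groups, train_fraction, rng)


def r2_block(
    task: RegressionTask,
    block,
    settings: LearnerSettings = LearnerSettings(),
    n_iter: int = 100,
    train_fraction: float = 0.6,
    seed: int = 0,
    max_depth: int | None = None,
    measure_name: str = "R2_B",
) -> BlockImportanceResult:
    """Block-only performance over repeated subject-blocked 60/40 splits."""
    cols = _resolve_block(task, block)
    X = task.X[cols].to_numpy(dtype=float)
    values = np.empty(n_iter)
    for i in range(n_iter):
        train, test = _split_for_iteration(task, train_fraction, seed, i)
        assert not set(task.groups[train]) & set(task.groups[test]), "subject leakage"
        rf = make_rf(settings, X.shape[1], _iteration_seed(seed, i), max_depth=max_depth)
        rf.fit(X[train], task.y[train])
        values[i] = out_of_sample_r2(task.y[test], rf.predict(X[test]))
    return BlockImportanceResult(
        appraisal_id=task.appraisal_id,
        block=block if isinstance(block, str) else "custom",
        measure=measure_name,
        iteration_values=values,
        mean=float(values.mean()),
        robust=robustness(values),
    )


def delta_r2_block(
    task: RegressionTask,
    block,
    settings: LearnerSettings = LearnerSettings(),
    n_iter: int = 100,
    train_fraction: float = 0.6,
    seed: int = 0,
) -> BlockImportanceResult:
    """Incremental performance: full-model R^2 minus complement-model R^2.

    Both models of one iteration see identical train/test rows and identical
    forest seed (the shared-split contract).
    """
    cols = _resolve_block(task, block)
    all_cols = list(task.X.columns)
    comp_cols = [c for c in all_cols if c not in set(cols)]
    if not comp_cols:
        raise ConfigError("delta_r2_block: complement of the block is empty")
    X_full = task.X[all_cols].to_numpy(dtype=float)
    X_comp = task.X[comp_cols].to_numpy(dtype=float)
    values = np.empty(n_iter)
    for i in range(n_iter):
        train, test = _split_for_iteration(task, train_fraction, seed, i)
        assert not set(task.groups[train]) & set(task.groups[test]), "subject leakage"
        it_seed = _iteration_seed(seed, i)
        rf_full = make_rf(settings, X_full.shape[1], it_seed)
        rf_full.fit(X_full[train], task.y[train])
        r2_full = out_of_sample_r2(task.y[test], rf_full.predict(X_full[test]))
        rf_comp = make_rf(settings, X_comp.shape[1], it_seed)
        rf_comp.fit(X_comp[train], task.y[train])
        r2_comp = out_of_sample_r2(task.y[test], rf_comp.predict(X_comp[test]))
        values[i] = r2_full - r2_comp
    return BlockImportanceResult(
        appraisal_id=task.appraisal_id,
        block=block if isinstance(block, str) else "custom",
        measure="dR2_B",
        iteration_values=values,
        mean=float(values.mean()),
        robust=robustness(values),
    )


def importance_report(results: list[BlockImportanceResult]) -> pd.DataFrame:
    """Long-format table; non-robust entries keep their value but are
    flagged ``omitted`` (the display-masking rule: more than 15% non-positive
    iteration values)."""
    rows = [
        {
            "appraisal": r.appraisal_id,
            "channel": r.block,
            "measure": r.measure,
            "mean": r.mean,
            "robust": r.robust,
            "omitted": not r.robust,
            "n_iter": int(r.iteration_values.size),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def iteration_table(results: list[BlockImportanceResult]) -> pd.DataFrame:
    """Per-iteration long-format audit table."""
    rows = [
        {
            "appraisal": r.appraisal_id,
            "channel": r.block,
            "measure": r.measure,
            "iteration": i,
            "value": v,
        }
        for r in results
        for i, v in enumerate(r.iteration_values)
    ]
    return pd.DataFrame(rows)
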