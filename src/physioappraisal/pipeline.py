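"""End-to-end orchestration: simulate -> preprocess -> features ->
benchmark -> importance -> ALE, with a run manifest recording every seed and
assumed default."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import (
    ASSUMED_DEFAULTS,
    CVScheme,
    ImportanceSettings,
    InterpretSettings,
    LearnerSettings,
    StudyConfig,
    config_as_dict,
)
from .benchmark import benchmark_report, build_task, run_benchmark
from .datatypes import CHANNELS
from .errors import EmptyTaskError, PhysioAppraisalError
from .features import FeatureParams, build_feature_table
from .importance import delta_r2_block, importance_report, r2_block
from .interpret import (
    ale_profile,
    ale_table,
    fit_single_feature_model,
    interpretable_features,
    select_best_feature,
)
from .io import read_signals, write_dataset, write_feature_table
from .preprocess import preprocess_dataset, segment_recordings
from .synthetic import generate_study

log = logging.getLogger("physioappraisal")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "results"
    in_dir: str | None = None  # read raw signals from disk instead of simulating
    study: StudyConfig = field(default_factory=StudyConfig)
    scheme: CVScheme = field(default_factory=CVScheme)
    learners: LearnerSettings = field(default_factory=LearnerSettings)
    importance: ImportanceSettings = field(default_factory=ImportanceSettings)
    interpret: InterpretSettings = field(default_factory=InterpretSettings)
    feature_params: FeatureParams = field(default_factory=FeatureParams)
    items: tuple[str, ...] | None = None  # None: all items in the appraisal table
    reversal_flags: dict = field(default_factory=dict)
    seed: int = 0
    write_raw: bool = False
    write_plots: bool = False


def _manifest(config: RunConfig) -> dict:
    return {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "study": config_as_dict(config.study),
        "cv_scheme": config_as_dict(config.scheme),
        "learners": config_as_dict(config.learners),
        "importance": config_as_dict(config.importance),
        "interpret": config_as_dict(config.interpret),
        "feature_params": config_as_dict(config.feature_params),
        "assumed_defaults": ASSUMED_DEFAULTS,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the in-memory artifacts.

    Artifacts on disk: ``features.csv`` + ``feature_blocks.json``,
    ``benchmark.csv`` + ``benchmark_folds.csv``, ``importance.csv``,
    ``ale_profiles.csv`` and ``run_manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.study.seed = config.seed
    config.scheme.seed = config.seed

    stage = "simulate/read"
    try:
        if config.in_dir is not None:
            raw = read_signals(config.in_dir)
            recordings, baselines = segment_recordings(
                raw.streams, raw.segments, raw.baseline_window
            )
            appraisals = raw.appraisals
            if appraisals is None:
                raise PhysioAppraisalError("input directory has no appraisals.csv")
        else:
            dataset = generate_study(config.study, include_streams=config.write_raw)
            if config.write_raw:
                write_dataset(dataset, out / "raw")
            recordings, baselines = dataset.recordings, dataset.baselines
            appraisals = dataset.appraisals
        log.info("%s: %d recordings, %d baselines", stage, len(recordings), len(baselines))

        stage = "preprocess"
        clean = preprocess_dataset(recordings, baselines)

        stage = "features"
        table = build_feature_table(clean, params=config.feature_params)
        write_feature_table(table, out)
        log.info(
            "features: %d rows x %d columns; block sizes %s",
            *table.data.shape,
            {ch: len(cols) for ch, cols in table.blocks.items()},
        )

        stage = "benchmark"
        items = config.items or [
            c for c in appraisals.columns if c not in ("subject", "video")
        ]
        all_results = []
        tasks = {}
        for item in items:
            try:
                task = build_task(table, appraisals, item, config.reversal_flags)
            except EmptyTaskError:
                log.warning("benchmark: item %s empty after exclusion, skipped", item)
                continue
            tasks[item] = task
            all_results.extend(
                run_benchmark(task, config.scheme, settings=config.learners)
            )
        bench_df = benchmark_report(all_results)
        bench_df.to_csv(out / "benchmark.csv", index=False)
        folds = pd.DataFrame(
            [
                {"appraisal": r.appraisal_id, "learner": r.learner, "fold": i, "r2": v}
                for r in all_results
                for i, v in enumerate(r.fold_scores)
            ]
        )
        folds.to_csv(out / "benchmark_folds.csv", index=False)

        rf_rows = bench_df[bench_df.learner == "RF"]
        predictable = list(rf_rows[rf_rows.robust].appraisal)
        log.info("benchmark: %d/%d items robustly predictable", len(predictable), len(items))

        stage = "importance"
        imp_results = []
        for item in predictable:
            task = tasks[item]
            for ch in CHANNELS:
                imp_results.append(
                    r2_block(
                        task,
                        ch,
                        settings=config.learners,
                        n_iter=config.importance.n_iter,
                        train_fraction=config.importance.train_fraction,
                        seed=config.seed,
                    )
                )
                imp_results.append(
                    delta_r2_block(
                        task,
                        ch,
                        settings=config.learners,
                        n_iter=config.importance.n_iter,
                        train_fraction=config.importance.train_fraction,
                        seed=config.seed,
                    )
                )
        imp_df = importance_report(imp_results)
        imp_df.to_csv(out / "importance.csv", index=False)

        stage = "ale"
        ale_rows = []
        for item in predictable:
            task = tasks[item]
            candidates = interpretable_features(task.X.columns)
            best, _ = select_best_feature(
                task,
                candidates,
                settings=config.learners,
                n_iter=config.importance.n_iter,
                seed=config.seed,
                tree_depth=config.interpret.tree_depth,
            )
            if best is None:
                log.info("ale: no robust interpretable feature for %s", item)
                continue
            model = fit_single_feature_model(
                task, best, settings=config.learners, seed=config.seed,
                tree_depth=config.interpret.tree_depth,
            )
            profile = ale_profile(
                model,
                task.X[[best]],
                best,
                n_intervals=config.interpret.n_intervals,
                quantile_range=config.interpret.quantile_range,
            )
            tbl = ale_table(profile)
            tbl.insert(0, "appraisal", item)
            ale_rows.append(tbl)
            if config.write_plots:
                from .interpret import plot_ale

                (out / "ale_plots").mkdir(exist_ok=True)
                plot_ale(profile, out / "ale_plots" / f"{item}.png")
        ale_df = (
            pd.concat(ale_rows, ignore_index=True)
            if ale_rows
            else pd.DataFrame(columns=["appraisal", "feature", "grid_value", "effect", "n_interval"])
        )
        ale_df.to_csv(out / "ale_profiles.csv", index=False)

        (out / "run_manifest.json").write_text(json.dumps(_manifest(config), indent=2))
    except PhysioAppraisalError as exc:
        raise PhysioAppraisalError(f"stage {stage}: {exc}") from exc

    return {
        "features": table,
        "benchmark": bench_df,
        "folds": folds,
        "importance": imp_df,
        "ale": ale_df,
        "predictable": predictable,
    }
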