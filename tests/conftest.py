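"""Shared fixtures: small synthetic studies and directly constructed tasks.

The session-scoped ``recovery_runs`` fixture builds ten independently seeded
small studies (15 subjects x 6 videos, 6-9 s videos) whose ratings are
driven by the zygomaticus amplitude latent through a saturating and a
threshold link; several recovery-style tests share it to keep the suite
fast.
"""

import numpy as np
import pandas as pd
import pytest

from physioappraisal import EffectSpec, StudyConfig, generate_study
from physioappraisal.datatypes import FeatureTable, RegressionTask
from physioappraisal.features import build_feature_table
from physioappraisal.preprocess import preprocess_dataset

RECOVERY_SEEDS = tuple(range(10))


def recovery_config(seed: int) -> StudyConfig:
    return StudyConfig(
        n_subjects=15,
        n_videos=6,
        video_duration_s=(6.0, 9.0),
        baseline_duration_s=8.0,
        effect_spec=(
            EffectSpec("pleasantness", "zygomaticus_amplitude", "saturating", 1, 1.0),
            EffectSpec("suddenness", "zygomaticus_amplitude", "threshold", 1, 1.0),
        ),
        items=("pleasantness", "suddenness", "familiarity"),
        missing_rate=0.0,
        noise_sd=0.05,
        seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_runs():
    """seed -> (StudyDataset, FeatureTable) for ten recovery studies."""
    runs = {}
    for seed in RECOVERY_SEEDS:
        dataset = generate_study(recovery_config(seed))
        clean = preprocess_dataset(dataset.recordings, dataset.baselines)
        runs[seed] = (dataset, build_feature_table(clean))
    return runs


@pytest.fixture(scope="session")
def one_recovery_run(recovery_runs):
    return recovery_runs[RECOVERY_SEEDS[0]]


def make_block_task(
    seed: int,
    n_subjects: int = 20,
    rows_per_subject: int = 6,
    block_sizes: dict | None = None,
    signal_block: str = "zyg",
    link: str = "linear",
    noise_sd: float = 0.1,
    appraisal_id: str = "item",
) -> RegressionTask:
    """Directly constructed task: Gaussian feature blocks, y driven by the
    first column of ``signal_block`` (or pure noise when ``signal_block`` is
    None)."""
    if block_sizes is None:
        block_sizes = {"zyg": 8, "corr": 8, "front": 8, "eda": 6, "hrv": 4}
    rng = np.random.default_rng(seed)
    n = n_subjects * rows_per_subject
    cols, blocks = [], {}
    data = {}
    for ch, size in block_sizes.items():
        names = tuple(f"{ch}.f{i}" for i in range(size))
        blocks[ch] = names
        for name in names:
            data[name] = rng.standard_normal(n)
        cols.extend(names)
    X = pd.DataFrame(data, columns=cols)
    groups = np.repeat([f"s{i:03d}" for i in range(n_subjects)], rows_per_subject)
    if signal_block is None:
        y = rng.standard_normal(n)
    else:
        driver = X[blocks[signal_block][0]].to_numpy()
        if link == "linear":
            y = driver.copy()
        elif link == "threshold":
            y = np.where(driver > 0, 1.0, -1.0)
        else:
            y = np.tanh(driver)
        y = y + noise_sd * rng.standard_normal(n)
    return RegressionTask(appraisal_id=appraisal_id, X=X, y=y, groups=groups, blocks=blocks)


def table_from_task(task: RegressionTask) -> FeatureTable:
    df = task.X.copy()
    videos = []
    counts = {}
    for g in task.groups:
        counts[g] = counts.get(g, 0) + 1
        videos.append(f"v{counts[g]:02d}")
    df.index = pd.MultiIndex.from_arrays([task.groups, videos], names=["subject", "video"])
    return FeatureTable(data=df, blocks=dict(task.blocks))
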