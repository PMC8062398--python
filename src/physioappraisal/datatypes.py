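"""In-memory containers shared across the pipeline stages.

Signals are plain 1-D numpy arrays; tables are pandas DataFrames. A
``Recording`` is one (subject, video) unit holding three facial-EMG series
(zygomaticus, corrugator, frontalis sites), one electrodermal series and the
RR-interval series observed during that video.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: Channel blocks, in canonical order.  ``zyg``/``corr``/``front`` are the
#: three facial EMG sites, ``eda`` electrodermal activity, ``hrv`` the
#: RR-interval series.
EMG_SITES = ("zyg", "corr", "front")
CHANNELS = ("zyg", "corr", "front", "eda", "hrv")


@dataclass
class Recording:
    """Physiological signals of one subject watching one video."""

    subject: str
    video: str
    emg: dict[str, np.ndarray]  # site -> series (mV)
    eda: np.ndarray  # microsiemens
    rr_ms: np.ndarray  # RR intervals in ms, in beat order
    emg_fs_hz: float
    eda_fs_hz: float

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject, self.video)

    def channels_present(self) -> list[str]:
        out = [s for s in EMG_SITES if s in self.emg and self.emg[s].size > 0]
        if self.eda is not None and self.eda.size > 0:
            out.append("eda")
        if self.rr_ms is not None and self.rr_ms.size > 0:
            out.append("hrv")
        return out


@dataclass
class BaselineRecording:
    """Per-subject resting baseline (2 minutes in the study protocol)."""

    subject: str
    emg: dict[str, np.ndarray]
    eda: np.ndarray
    rr_ms: np.ndarray
    emg_fs_hz: float
    eda_fs_hz: float


@dataclass
class RawSubjectStream:
    """Continuous per-subject acquisition: baseline then videos with gaps.

    Sampled channels share a common time origin (t = 0 at stream start);
    ``rr_ms`` covers the whole stream, with beat k terminating at
    ``cumsum(rr_ms)[k] / 1000`` seconds.
    """

    subject: str
    emg: dict[str, np.ndarray]
    eda: np.ndarray
    rr_ms: np.ndarray
    emg_fs_hz: float
    eda_fs_hz: float


@dataclass(frozen=True)
class Segment:
    """Half-open [onset_s, offset_s) window of one video within a stream."""

    subject: str
    video: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.onset_s < self.offset_s):
            raise ValueError(
                f"Segment({self.subject}, {self.video}): need 0 <= onset < offset"
            )


@dataclass
class StudyDataset:
    """Everything one synthetic study produces.

    ``truth`` carries the effect specification and the realized latent values
    so parameter-recovery tests have a ground truth to recover.
    """

    recordings: dict[tuple[str, str], Recording]
    baselines: dict[str, BaselineRecording]
    appraisals: pd.DataFrame  # columns: subject, video, <item...>
    truth: "GroundTruth"
    streams: dict[str, RawSubjectStream] = field(default_factory=dict)
    segments: tuple[Segment, ...] = ()


@dataclass
class GroundTruth:
    effect_spec: tuple
    latents: pd.DataFrame  # columns: subject, video, <latent...>


@dataclass
class FeatureTable:
    """Rows keyed by (subject, video); 134 named feature columns.

    ``blocks`` maps each channel to its column names
    (zyg/corr/front: 32 each, eda: 30, hrv: 8).
    """

    data: pd.DataFrame  # index: MultiIndex (subject, video)
    blocks: dict[str, tuple[str, ...]]

    @property
    def feature_columns(self) -> list[str]:
        return list(self.data.columns)

    def block_columns(self, channel: str) -> list[str]:
        return list(self.blocks[channel])


@dataclass
class RegressionTask:
    """One appraisal item as a prediction target over the feature table."""

    appraisal_id: str
    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray  # subject id per row
    blocks: dict[str, tuple[str, ...]]

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class CVResult:
    """Benchmark outcome for one (appraisal, learner) pair."""

    appraisal_id: str
    learner: str
    fold_scores: np.ndarray  # repetitions x folds values, flattened
    aggregate: float
    q15: float
    robust: bool
    n: int
    n_skipped_folds: int = 0


@dataclass
class BlockImportanceResult:
    """One channel-importance measure for one appraisal."""

    appraisal_id: str
    block: str
    measure: str  # "R2_B" or "dR2_B"
    iteration_values: np.ndarray
    mean: float
    robust: bool


@dataclass
class ALEProfile:
    """First-order accumulated-local-effects profile of one feature."""

    feature_id: str
    grid: np.ndarray  # K+1 increasing boundaries within [q05, q95]
    effects: np.ndarray  # centered accumulated effect at each boundary
    n_per_interval: np.ndarray  # K interval occupancies


def sort_key(keys: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    return sorted(keys)
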