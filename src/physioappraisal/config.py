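"""Configuration objects for the synthetic study, filters, learners and resampling.

Every tunable default that is an assumption rather than a stated fact of the
analysis protocol is marked ``assumed`` in :data:`ASSUMED_DEFAULTS`, and the
CLI echoes that list into the run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ConfigError

#: The five ground-truth latent channel properties the generator can wire
#: appraisal items to.
LATENTS = (
    "zygomaticus_amplitude",
    "corrugator_amplitude",
    "frontalis_amplitude",
    "eda_phasic_rate",
    "rr_variability",
)

#: Monotone link shapes available to the rating model.
LINKS = ("linear", "saturating", "threshold")

#: The 21 appraisal dimensions of the rating questionnaire (Component Process
#: Model dimensions; four rated both from the viewer's and the video
#: protagonist's perspective, cause agent split into three items).
APPRAISAL_ITEMS = (
    "pleasantness",
    "internal_standards",
    "conduciveness_protagonist",
    "external_standards",
    "cause_motive",
    "urgency_protagonist",
    "cause_agent_protagonist",
    "adjustment_protagonist",
    "suddenness",
    "conduciveness_self",
    "cause_agent_other",
    "goal_need_importance_protagonist",
    "familiarity",
    "discrepancy_from_expectation",
    "cause_agent_nature",
    "adjustment_self",
    "predictability",
    "outcome_probability",
    "control",
    "goal_need_importance_self",
    "urgency_self",
)

#: Rating code for a "does not apply" answer (outside the 1..5 scale).
MISSING_CODE = 0


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth link between one appraisal item and one latent property.

    ``strength`` in [0, 1] scales the monotone link; ``direction`` flips it.
    Items without an EffectSpec are generated as pure noise.
    """

    appraisal_id: str
    latent: str
    link: str = "saturating"
    direction: int = 1
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.latent not in LATENTS:
            raise ConfigError(f"EffectSpec.latent: unknown latent {self.latent!r}")
        if self.link not in LINKS:
            raise ConfigError(f"EffectSpec.link: unknown link {self.link!r}")
        if self.direction not in (-1, 1):
            raise ConfigError("EffectSpec.direction: must be +1 or -1")
        if not 0.0 <= self.strength <= 1.0:
            raise ConfigError("EffectSpec.strength: must lie in [0, 1]")


def default_effects() -> tuple[EffectSpec, ...]:
    """Study-shaped default ground truth.

    Directions mirror the qualitative pattern the appraisal literature
    reports (smiling-muscle activity up with conduciveness, frowning-muscle
    activity up with unpleasantness, electrodermal and heart-period
    variability tied to urgency-type appraisals); the remaining items are
    pure noise.
    """
    return (
        EffectSpec("pleasantness", "corrugator_amplitude", "saturating", -1, 0.8),
        EffectSpec("conduciveness_protagonist", "zygomaticus_amplitude", "saturating", 1, 0.7),
        EffectSpec("internal_standards", "zygomaticus_amplitude", "linear", 1, 0.6),
        EffectSpec("suddenness", "frontalis_amplitude", "threshold", 1, 0.6),
        EffectSpec("urgency_protagonist", "eda_phasic_rate", "saturating", 1, 0.5),
        EffectSpec("external_standards", "rr_variability", "linear", 1, 0.5),
    )


@dataclass
class StudyConfig:
    """Shape and ground truth of one synthetic study.

    Defaults reproduce the study conditions: 157 subjects x 10 videos of
    10.5-30.5 s, a 2-minute baseline, 1000 Hz sampling for EMG/EDA, and an
    average item-level missing rate of ~14%.
    """

    n_subjects: int = 157
    n_videos: int = 10
    video_duration_s: tuple[float, float] = (10.5, 30.5)
    baseline_duration_s: float = 120.0
    emg_fs_hz: float = 1000.0
    eda_fs_hz: float = 1000.0
    mean_rr_ms: float = 800.0
    rr_sd_ms: float = 40.0
    effect_spec: tuple[EffectSpec, ...] = field(default_factory=default_effects)
    items: tuple[str, ...] = APPRAISAL_ITEMS
    missing_rate: float = 0.14
    noise_sd: float = 0.5
    movement_artifact_mv: float = 0.05
    line_noise_mv: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("StudyConfig.n_subjects: must be a positive integer")
        if self.n_videos < 1:
            raise ConfigError("StudyConfig.n_videos: must be a positive integer")
        lo, hi = self.video_duration_s
        if not (0 < lo <= hi):
            raise ConfigError("StudyConfig.video_duration_s: need 0 < low <= high")
        if self.baseline_duration_s <= 0:
            raise ConfigError("StudyConfig.baseline_duration_s: must be > 0")
        if self.emg_fs_hz <= 0:
            raise ConfigError("StudyConfig.emg_fs_hz: must be > 0")
        if self.eda_fs_hz <= 0:
            raise ConfigError("StudyConfig.eda_fs_hz: must be > 0")
        if self.mean_rr_ms <= 0:
            raise ConfigError("StudyConfig.mean_rr_ms: must be > 0")
        if self.rr_sd_ms < 0:
            raise ConfigError("StudyConfig.rr_sd_ms: must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("StudyConfig.missing_rate: must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("StudyConfig.noise_sd: must be >= 0")
        seen: set[str] = set()
        for eff in self.effect_spec:
            if eff.appraisal_id in seen:
                raise ConfigError(
                    f"StudyConfig.effect_spec: duplicate appraisal_id {eff.appraisal_id!r}"
                )
            seen.add(eff.appraisal_id)
            if eff.appraisal_id not in self.items:
                raise ConfigError(
                    f"StudyConfig.effect_spec: appraisal_id {eff.appraisal_id!r} not in items"
                )


@dataclass(frozen=True)
class FilterSpec:
    """One stage of a filter chain.

    ``cutoff_hz`` is a single edge for high-/low-pass and a
    ``(center, total stop-band width)`` pair for the notch.
    """

    kind: str  # highpass | lowpass | notch
    cutoff_hz: float | tuple[float, float]
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass", "notch"):
            raise ConfigError(f"FilterSpec.kind: unknown kind {self.kind!r}")
        if self.order < 1:
            raise ConfigError("FilterSpec.order: must be a positive integer")


def default_emg_chain() -> tuple[FilterSpec, ...]:
    """High-pass 40 Hz -> 50 Hz notch (0.5 Hz wide) -> low-pass 250 Hz."""
    return (
        FilterSpec("highpass", 40.0, 4),
        FilterSpec("notch", (50.0, 0.5), 2),
        FilterSpec("lowpass", 250.0, 4),
    )


def default_eda_chain() -> tuple[FilterSpec, ...]:
    """High-pass 0.5 Hz, removing the tonic skin-conductance level."""
    return (FilterSpec("highpass", 0.5, 4),)


@dataclass
class CVScheme:
    """Repeated k-fold cross-validation blocked by subject (default 20 x 5)."""

    repetitions: int = 20
    folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.repetitions < 1:
            raise ConfigError("CVScheme.repetitions: must be >= 1")
        if self.folds < 2:
            raise ConfigError("CVScheme.folds: must be >= 2")


@dataclass
class LearnerSettings:
    """Hyperparameters of the three learners.

    The random-forest defaults follow the de-facto regression defaults
    (500 trees, floor(p/3) candidate features per split, minimum node size 5,
    unlimited depth); the ridge penalty is lambda = 1 on standardized
    features with the 3-SD outlier elimination + empirical imputation step.
    """

    rf_n_estimators: int = 500
    rf_min_samples_leaf: int = 5
    rf_max_depth: int | None = None
    ridge_alpha: float = 1.0
    outlier_z: float = 3.0

    @staticmethod
    def rf_max_features(n_features: int) -> int:
        return max(1, n_features // 3)


@dataclass
class ImportanceSettings:
    """Blocked-importance resampling: 100 iterations of 60/40 subject splits."""

    n_iter: int = 100
    train_fraction: float = 0.6

    def validate(self) -> None:
        if self.n_iter < 1:
            raise ConfigError("ImportanceSettings.n_iter: must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("ImportanceSettings.train_fraction: must lie in (0, 1)")


@dataclass
class InterpretSettings:
    """Single-feature models and ALE profiles."""

    n_intervals: int = 20
    tree_depth: int = 3
    quantile_range: tuple[float, float] = (0.05, 0.95)

    def validate(self) -> None:
        if self.n_intervals < 1:
            raise ConfigError("InterpretSettings.n_intervals: must be >= 1")
        q_lo, q_hi = self.quantile_range
        if not 0.0 <= q_lo < q_hi <= 1.0:
            raise ConfigError("InterpretSettings.quantile_range: need 0 <= lo < hi <= 1")


#: Defaults that are methodological assumptions (the protocol names only the
#: construct, not the number); echoed into every run manifest.
ASSUMED_DEFAULTS = {
    "filter.butterworth_order": 4,
    "filter.zero_phase": True,
    "features.tmav_window_ms": 100.0,
    "features.myopulse_threshold_mv": 0.016,
    "features.wilson_threshold_mv": 0.005,
    "learners.rf_n_estimators": 500,
    "learners.rf_max_features": "floor(p/3)",
    "learners.rf_min_samples_leaf": 5,
    "learners.ridge_alpha": 1.0,
    "interpret.ale_intervals": 20,
}


def config_as_dict(obj) -> dict:
    """Dataclass -> plain dict for manifests (tuples become lists)."""
    return asdict(obj)
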