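"""Synthetic study generator.

Emulates the structure of a video-viewing psychophysiology session: per
subject a 2-minute resting baseline followed by a sequence of videos with
short inter-video pauses, with four sampled channels (three facial-EMG sites
and EDA) and a continuous RR-interval series.  Each (subject, video) pair
carries five latent properties — the three EMG burst amplitudes, the
electrodermal phasic event rate and the RR variability — and appraisal
ratings are noisy monotone functions of those latents, so downstream
benchmark and importance stages have a recoverable ground truth.

The generator is deterministic given ``StudyConfig.seed``; every random
stream is keyed by (seed, subject index, purpose) so outputs do not depend
on generation order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import LATENTS, MISSING_CODE, EffectSpec, StudyConfig
from .datatypes import (
    BaselineRecording,
    EMG_SITES,
    GroundTruth,
    RawSubjectStream,
    Recording,
    Segment,
    StudyDataset,
)
from .errors import ConfigError

_EMG_AMP_MV = 0.05  # burst amplitude scale (mV) multiplying the amplitude latent
_EMG_BAND = (60.0, 250.0)  # carrier band, survives the 40/250 Hz filter chain
_EDA_LEVEL_US = 5.0  # tonic skin-conductance level (microsiemens)
_RR_PHI = 0.6  # AR(1) coefficient of the RR series
_RR_REFLECT = (300.0, 2000.0)  # physiological range, reflection bounds (ms)


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *map(int, tags)])


def _quantize_ms(x: float) -> float:
    return round(float(x) * 1000.0) / 1000.0


# ---------------------------------------------------------------------------
# latents

def draw_latents(config: StudyConfig) -> pd.DataFrame:
    """Per-(subject, video) latent channel properties with subject effects."""
    rows = []
    for si in range(config.n_subjects):
        rng = _rng(config.seed, 1, si)
        subj = f"s{si + 1:03d}"
        subj_eff = rng.normal(0.0, 0.2, size=5)
        for vi in range(config.n_videos):
            vid = f"v{vi + 1:02d}"
            amp = np.exp(subj_eff[:3] + rng.normal(0.0, 0.45, size=3))
            rate = float(np.clip(0.12 * np.exp(subj_eff[3] + rng.normal(0.0, 0.4)), 0.02, 0.6))
            rr_var = float(np.clip(config.rr_sd_ms * np.exp(subj_eff[4] + rng.normal(0.0, 0.4)), 5.0, 150.0))
            rows.append(
                {
                    "subject": subj,
                    "video": vid,
                    "zygomaticus_amplitude": float(amp[0]),
                    "corrugator_amplitude": float(amp[1]),
                    "frontalis_amplitude": float(amp[2]),
                    "eda_phasic_rate": rate,
                    "rr_variability": rr_var,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signal pieces

def _bandlimited_noise(rng, n, fs, band):
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / max(rms, 1e-12)


def _lowpass_noise(rng, n, fs, cutoff):
    x = rng.standard_normal(n)
    sos = sps.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / max(rms, 1e-12)


def _burst_envelope(rng, n, fs, resting=False):
    """0.3 resting tone plus Hann-window activity bursts, capped at 1."""
    if resting or n == 0:
        return np.full(n, 0.3)
    dur = n / fs
    env = np.zeros(n)
    n_bursts = 1 + rng.poisson(dur / 5.0)
    for _ in range(n_bursts):
        width = rng.uniform(0.5, 2.0)
        center = rng.uniform(0.0, dur)
        w = max(int(width * fs), 3)
        i0 = int(center * fs) - w // 2
        win = np.hanning(w)
        a, b = max(i0, 0), min(i0 + w, n)
        if a < b:
            env[a:b] += win[a - i0 : b - i0]
    return 0.3 + 0.7 * np.clip(env, 0.0, 1.0)


def _emg_piece(rng, n, fs, amplitude, config: StudyConfig, dc=0.0, resting=False):
    carrier = _bandlimited_noise(rng, n, fs, _EMG_BAND)
    env = _burst_envelope(rng, n, fs, resting=resting)
    t = np.arange(n) / fs
    x = _EMG_AMP_MV * amplitude * carrier * env
    if config.movement_artifact_mv > 0:
        x = x + config.movement_artifact_mv * _lowpass_noise(rng, n, fs, 10.0)
    if config.line_noise_mv > 0:
        x = x + config.line_noise_mv * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    return x + dc


def _scr_kernel(fs, rise=0.7, decay=2.0, length_s=8.0):
    t = np.arange(int(length_s * fs)) / fs
    h = np.exp(-t / decay) - np.exp(-t / rise)
    peak = h.max()
    return h / max(peak, 1e-12)


def _eda_piece(rng, n, fs, phasic_rate, level):
    t = np.arange(n) / fs
    dur = n / fs
    drift = 0.3 * np.sin(2 * np.pi * rng.uniform(0.02, 0.05) * t + rng.uniform(0, 2 * np.pi))
    x = level + drift + 0.005 * rng.standard_normal(n)
    kernel = _scr_kernel(fs)
    n_events = rng.poisson(phasic_rate * dur)
    for _ in range(n_events):
        onset = int(rng.uniform(0.0, dur) * fs)
        amp = rng.exponential(0.4)
        seg = kernel[: n - onset]
        x[onset : onset + seg.size] += amp * seg
    return x


def _rr_stream(rng, pieces, mean_rr_ms):
    """One continuous AR(1) RR series over a piecewise-variability timeline.

    ``pieces`` is a list of (duration_s, sd_ms); the innovation scale of each
    interval follows the piece its terminating beat falls in.  Values are
    reflected into the physiological range [300, 2000] ms.
    """
    bounds = np.cumsum([d for d, _ in pieces])
    total = bounds[-1]
    sds = [sd for _, sd in pieces]
    lo, hi = _RR_REFLECT
    out = []
    t = 0.0
    dev = 0.0  # deviation from mean
    while t < total:
        idx = int(np.searchsorted(bounds, t, side="right"))
        sd = sds[min(idx, len(sds) - 1)]
        innov_sd = sd * np.sqrt(1.0 - _RR_PHI**2)
        dev = _RR_PHI * dev + rng.normal(0.0, innov_sd)
        rr = mean_rr_ms + dev
        if rr < lo:
            rr = lo + (lo - rr)
        if rr > hi:
            rr = hi - (rr - hi)
        rr = float(np.clip(rr, lo, hi))
        out.append(rr)
        t += rr / 1000.0
    return np.asarray(out)


def assign_rr(rr_ms: np.ndarray, onset_s: float, offset_s: float) -> np.ndarray:
    """Intervals whose terminating beat falls inside [onset, offset)."""
    beats = np.cumsum(rr_ms) / 1000.0
    mask = (beats >= onset_s) & (beats < offset_s)
    return rr_ms[mask]


# ---------------------------------------------------------------------------
# appraisals

def _link(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z / 2.0
    if name == "saturating":
        return np.tanh(z)
    if name == "threshold":
        return np.where(z > 0, 1.0, -1.0)
    raise ConfigError(f"unknown link {name!r}")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def generate_appraisals(
    latents: pd.DataFrame,
    effect_spec: tuple[EffectSpec, ...],
    noise_sd: float,
    missing_rate: float,
    seed: int,
    items: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Ratings on a 1-5 scale as noisy monotone functions of the latents.

    The continuous score ``3 + 2 * direction * strength * link(z)`` (z the
    standardized latent) plus Gaussian noise is rounded half-up and clipped
    to {1..5}; items without an effect are uniform noise; each entry is
    independently replaced by :data:`MISSING_CODE` with ``missing_rate``.
    """
    if items is None:
        items = tuple(e.appraisal_id for e in effect_spec)
    by_item = {e.appraisal_id: e for e in effect_spec}
    for e in effect_spec:
        if e.latent not in latents.columns:
            raise ConfigError(f"EffectSpec.latent: {e.latent!r} not present in latents")
        if e.appraisal_id not in items:
            raise ConfigError(f"EffectSpec.appraisal_id: {e.appraisal_id!r} not in items")
    n = len(latents)
    out = latents[["subject", "video"]].copy()
    rng = _rng(seed, 2)
    for item in items:
        eff = by_item.get(item)
        if eff is None:
            ratings = rng.integers(1, 6, size=n).astype(float)
        else:
            col = latents[eff.latent].to_numpy(float)
            sd = col.std()
            z = (col - col.mean()) / (sd if sd > 0 else 1.0)
            score = 3.0 + 2.0 * eff.direction * eff.strength * _link(eff.link, z)
            score = score + rng.normal(0.0, noise_sd, size=n)
            ratings = np.clip(_round_half_up(score), 1, 5)
        if missing_rate > 0:
            miss = rng.random(n) < missing_rate
            ratings = np.where(miss, MISSING_CODE, ratings)
        out[item] = ratings.astype(int)
    return out


# ---------------------------------------------------------------------------
# whole study

def generate_study(config: StudyConfig, include_streams: bool = False) -> StudyDataset:
    """Generate a full study-shaped dataset.

    With ``include_streams=True`` the continuous per-subject acquisition
    streams (baseline, inter-video gaps, videos) are also materialized so the
    on-disk layout and the segmentation stage can be exercised end to end;
    the segmented recordings are identical either way.
    """
    config.validate()
    latents = draw_latents(config)
    lat_idx = latents.set_index(["subject", "video"])

    recordings: dict[tuple[str, str], Recording] = {}
    baselines: dict[str, BaselineRecording] = {}
    streams: dict[str, RawSubjectStream] = {}
    segments: list[Segment] = []

    gap_s = 3.0
    emg_fs, eda_fs = config.emg_fs_hz, config.eda_fs_hz
    for si in range(config.n_subjects):
        subj = f"s{si + 1:03d}"
        rng = _rng(config.seed, 3, si)
        dc = {site: rng.normal(0.0, 0.1) for site in EMG_SITES}
        resting_amp = {site: float(np.exp(rng.normal(0.0, 0.2))) for site in EMG_SITES}
        resting_rate = 0.03
        subj_rr_sd = float(np.clip(config.rr_sd_ms * np.exp(rng.normal(0.0, 0.3)), 5.0, 150.0))

        # timeline: baseline, then (gap, video) per video
        durations = [("baseline", _quantize_ms(config.baseline_duration_s))]
        for vi in range(config.n_videos):
            vid = f"v{vi + 1:02d}"
            durations.append(("gap", gap_s))
            d = rng.uniform(*config.video_duration_s)
            durations.append((vid, _quantize_ms(d)))

        rr_pieces = []
        onset = 0.0
        piece_meta = []  # (label, onset_s, duration_s)
        for label, d in durations:
            piece_meta.append((label, onset, d))
            if label.startswith("v"):
                rr_pieces.append((d, float(lat_idx.loc[(subj, label), "rr_variability"])))
            else:
                rr_pieces.append((d, subj_rr_sd))
            onset += d
        rr_full = _rr_stream(_rng(config.seed, 4, si), rr_pieces, config.mean_rr_ms)

        emg_parts = {site: [] for site in EMG_SITES}
        eda_parts = []
        for pi, (label, p_onset, d) in enumerate(piece_meta):
            n_emg = int(np.floor(d * emg_fs + 1e-9))
            n_eda = int(np.floor(d * eda_fs + 1e-9))
            prng = _rng(config.seed, 5, si, pi)
            is_video = label.startswith("v")
            if is_video:
                lat = lat_idx.loc[(subj, label)]
                emg = {
                    site: _emg_piece(prng, n_emg, emg_fs, float(lat[f"{name}_amplitude"]), config, dc=dc[site])
                    for site, name in zip(EMG_SITES, ("zygomaticus", "corrugator", "frontalis"))
                }
                eda = _eda_piece(prng, n_eda, eda_fs, float(lat["eda_phasic_rate"]), _EDA_LEVEL_US)
            else:
                emg = {
                    site: _emg_piece(prng, n_emg, emg_fs, resting_amp[site], config, dc=dc[site], resting=True)
                    for site in EMG_SITES
                }
                eda = _eda_piece(prng, n_eda, eda_fs, resting_rate, _EDA_LEVEL_US)
            for site in EMG_SITES:
                emg_parts[site].append(emg[site])
            eda_parts.append(eda)

            if is_video:
                offset = p_onset + d
                segments.append(Segment(subj, label, p_onset, offset))
                recordings[(subj, label)] = Recording(
                    subject=subj,
                    video=label,
                    emg={site: emg[site] for site in EMG_SITES},
                    eda=eda,
                    rr_ms=assign_rr(rr_full, p_onset, offset),
                    emg_fs_hz=emg_fs,
                    eda_fs_hz=eda_fs,
                )
            elif label == "baseline":
                baselines[subj] = BaselineRecording(
                    subject=subj,
                    emg={site: emg[site] for site in EMG_SITES},
                    eda=eda,
                    rr_ms=assign_rr(rr_full, p_onset, p_onset + d),
                    emg_fs_hz=emg_fs,
                    eda_fs_hz=eda_fs,
                )
        if include_streams:
            streams[subj] = RawSubjectStream(
                subject=subj,
                emg={site: np.concatenate(emg_parts[site]) for site in EMG_SITES},
                eda=np.concatenate(eda_parts),
                rr_ms=rr_full,
                emg_fs_hz=emg_fs,
                eda_fs_hz=eda_fs,
            )

    appraisals = generate_appraisals(
        latents,
        config.effect_spec,
        config.noise_sd,
        config.missing_rate,
        config.seed,
        items=config.items,
    )
    return StudyDataset(
        recordings=recordings,
        baselines=baselines,
        appraisals=appraisals,
        truth=GroundTruth(effect_spec=tuple(config.effect_spec), latents=latents),
        streams=streams,
        segments=tuple(segments),
    )
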