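"""The 134-feature set: 32 per EMG site, 30 for EDA, 8 for HRV.

Time-domain features follow the surface-EMG feature family (mean absolute
value and robust trimmed variants, square integral, waveform-length and
slope-change statistics, thresholded pulse counts, Yule-Walker
autoregressive coefficients); frequency-domain features come from a single
one-sided periodogram of the detrended segment.  All sums are expressed as
per-sample means, per-transition percentages or spectral integrals so every
feature is independent of segment length for a stationary signal.

HRV features are the standard short-term set: SDNN, RMSSD, pNN50, LF/HF
band-power ratio from a Lomb-Scargle periodogram of the beat series, TINN,
the Poincare SD2/SD1 ratio, and the triangular indices of the RR and
relative-RR histograms (bin widths 1/128 s and 1%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy import stats as spstats
from statsmodels.regression.linear_model import yule_walker

from .datatypes import CHANNELS, EMG_SITES, FeatureTable, Recording
from .errors import MissingChannelError

MIN_SAMPLES = 64
MIN_RR_INTERVALS = 4
RR_VALID_MS = (200.0, 3000.0)
RR_BIN_MS = 7.8125  # 1/128 s, the conventional RR histogram resolution
REL_RR_BIN = 0.01
_LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class FeatureParams:
    """Thresholds and windows of the thresholded/smoothed features (mV / ms)."""

    zc_threshold_mv: float = 0.005
    myopulse_threshold_mv: float = 0.016
    wamp_threshold_mv: float = 0.005
    tmav_window_ms: float = 100.0
    trim_fraction: float = 0.2  # removed from each tail
    rmssd_on_successive_diffs: bool = True  # False: RMS of the raw intervals


#: Sampled-channel feature names in canonical order (32 entries).  The two
#: names marked EMG-only are dropped for EDA (zero variance on that channel).
SAMPLED_FEATURES = (
    "mav",
    "mav_trim20",
    "tmav",
    "ssi",
    "var",
    "abs_moment3",
    "abs_moment4",
    "abs_moment5",
    "ar1",
    "ar2",
    "ar3",
    "ar4",
    "rms",
    "log_detector",
    "pct_wavelength",
    "avg_amp_change",
    "dasdv",
    "pct_zc",
    "pct_zc_thresh",  # EMG only
    "pct_ssc",
    "pct_myopulse",
    "pct_wamp",  # EMG only
    "mdf_amp",
    "mnf_amp",
    "mdf_pow",
    "mnf_pow",
    "peak_freq",
    "mean_power",
    "total_power",
    "sm1",
    "sm2",
    "sm3",
)
EMG_ONLY_FEATURES = ("pct_zc_thresh", "pct_wamp")
EDA_FEATURES = tuple(f for f in SAMPLED_FEATURES if f not in EMG_ONLY_FEATURES)
HRV_FEATURES = (
    "sdnn",
    "rmssd",
    "pnn50",
    "lf_hf",
    "tinn",
    "sd2_sd1",
    "tri_index",
    "rel_rr_tri_index",
)


def _moving_trimmed_mean(absx: np.ndarray, window: int, trim: float) -> np.ndarray:
    window = min(max(window, 1), absx.size)
    views = sliding_window_view(absx, window)
    return spstats.trim_mean(views, trim, axis=1)


def _ar_coefficients(x: np.ndarray, order: int = 4) -> np.ndarray:
    if np.var(x) <= 0:
        return np.zeros(order)
    rho, _sigma = yule_walker(x, order=order, method="mle")
    return np.asarray(rho, dtype=float)


def _median_frequency(freqs: np.ndarray, mass: np.ndarray) -> float:
    total = mass.sum()
    if total <= 0:
        return 0.0
    cum = np.cumsum(mass)
    idx = int(np.searchsorted(cum, 0.5 * total))
    return float(freqs[min(idx, freqs.size - 1)])


def _mean_frequency(freqs: np.ndarray, mass: np.ndarray) -> float:
    total = mass.sum()
    if total <= 0:
        return 0.0
    return float(np.sum(freqs * mass) / total)


def sampled_channel_features(
    series: np.ndarray,
    fs: float,
    include_emg_only: bool = True,
    params: FeatureParams = FeatureParams(),
) -> dict[str, float]:
    """Feature map for one sampled channel (32 values for EMG, 30 for EDA)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < MIN_SAMPLES:
        raise ValueError(f"sampled_channel_features: need a 1-D series of >= {MIN_SAMPLES} samples")
    if fs <= 0:
        raise ValueError("sampled_channel_features: fs must be > 0")
    n = x.size
    absx = np.abs(x)
    dx = np.diff(x)

    out: dict[str, float] = {}
    out["mav"] = float(absx.mean())
    out["mav_trim20"] = float(spstats.trim_mean(absx, params.trim_fraction))
    window = int(round(params.tmav_window_ms * fs / 1000.0))
    out["tmav"] = float(_moving_trimmed_mean(absx, window, params.trim_fraction).mean())
    out["ssi"] = float(np.mean(x**2))
    out["var"] = float(np.var(x, ddof=1))
    for k in (3, 4, 5):
        out[f"abs_moment{k}"] = float(abs(np.mean(x**k)))
    ar = _ar_coefficients(x, 4)
    for k in range(4):
        out[f"ar{k + 1}"] = float(ar[k])
    out["rms"] = float(np.sqrt(np.mean(x**2)))
    out["log_detector"] = float(np.exp(np.mean(np.log(np.maximum(absx, _LOG_FLOOR)))))
    out["pct_wavelength"] = float(np.sum(np.abs(dx)) / (n - 1))
    out["avg_amp_change"] = float(np.sum(np.abs(dx)) / (n - 1))
    out["dasdv"] = float(np.sqrt(np.sum(dx**2) / (n - 1)))

    cross = x[:-1] * x[1:] < 0
    out["pct_zc"] = float(100.0 * np.count_nonzero(cross) / (n - 1))
    if include_emg_only:
        out["pct_zc_thresh"] = float(
            100.0 * np.count_nonzero(cross & (np.abs(dx) >= params.zc_threshold_mv)) / (n - 1)
        )
    ssc = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) > 0
    out["pct_ssc"] = float(100.0 * np.count_nonzero(ssc) / (n - 2))
    out["pct_myopulse"] = float(100.0 * np.count_nonzero(absx >= params.myopulse_threshold_mv) / n)
    if include_emg_only:
        out["pct_wamp"] = float(
            100.0 * np.count_nonzero(np.abs(dx) > params.wamp_threshold_mv) / (n - 1)
        )

    freqs, power = sps.periodogram(x, fs=fs, detrend="constant")
    amp = np.sqrt(power)
    df = float(freqs[1] - freqs[0]) if freqs.size > 1 else 1.0
    out["mdf_amp"] = _median_frequency(freqs, amp)
    out["mnf_amp"] = _mean_frequency(freqs, amp)
    out["mdf_pow"] = _median_frequency(freqs, power)
    out["mnf_pow"] = _mean_frequency(freqs, power)
    out["peak_freq"] = float(freqs[int(np.argmax(power))]) if power.max() > 0 else 0.0
    out["mean_power"] = float(power.mean())
    out["total_power"] = float(power.sum() * df)
    for k in (1, 2, 3):
        out[f"sm{k}"] = float(np.sum(power * freqs**k) * df)

    order = SAMPLED_FEATURES if include_emg_only else EDA_FEATURES
    return {name: out[name] for name in order}


# ---------------------------------------------------------------------------
# HRV

def _anchored_histogram(values: np.ndarray, width: float) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with bins anchored at zero (edges at integer multiples)."""
    lo = np.floor(values.min() / width)
    hi = np.floor(values.max() / width) + 1
    edges = np.arange(lo, hi + 1) * width
    counts, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts.astype(float), centers


def _tinn(counts: np.ndarray, centers: np.ndarray, width: float) -> float:
    """Base width of the least-squares triangle over the RR histogram."""
    occupied = np.nonzero(counts)[0]
    if occupied.size < 2:
        return 0.0
    m = int(np.argmax(counts))
    peak = counts[m]
    # candidate triangle feet on the bin-center grid, extended one bin past
    # the occupied range on each side
    left_candidates = [centers[m] - width * k for k in range(1, m + 2)]
    right_candidates = [centers[m] + width * k for k in range(1, counts.size - m + 1)]
    best = np.inf
    best_nm = (centers[m] - width, centers[m] + width)
    for nfoot in left_candidates:
        for mfoot in right_candidates:
            tri = np.zeros_like(counts)
            up = (centers >= nfoot) & (centers <= centers[m])
            down = (centers > centers[m]) & (centers <= mfoot)
            tri[up] = peak * (centers[up] - nfoot) / (centers[m] - nfoot)
            tri[down] = peak * (mfoot - centers[down]) / (mfoot - centers[m])
            sse = float(np.sum((counts - tri) ** 2))
            if sse < best - 1e-12:
                best = sse
                best_nm = (nfoot, mfoot)
    return float(best_nm[1] - best_nm[0])


def _lf_hf_ratio(rr_ms: np.ndarray) -> float:
    """LF (0.04-0.15 Hz) over HF (0.15-0.40 Hz) band power from a
    Lomb-Scargle periodogram of the beat-time series."""
    t = np.cumsum(rr_ms) / 1000.0
    x = rr_ms - rr_ms.mean()
    if np.allclose(x, 0):
        return 0.0
    lf_grid = np.linspace(0.04, 0.15, 60)
    hf_grid = np.linspace(0.15, 0.40, 60)
    lf_p = sps.lombscargle(t, x, 2 * np.pi * lf_grid)
    hf_p = sps.lombscargle(t, x, 2 * np.pi * hf_grid)
    lf = float(np.trapezoid(lf_p, lf_grid))
    hf = float(np.trapezoid(hf_p, hf_grid))
    return max(lf, 0.0) / max(hf, _LOG_FLOOR)


def hrv_features(
    rr_ms: np.ndarray, params: FeatureParams = FeatureParams()
) -> dict[str, float]:
    """The 8 heart-rate-variability features of one RR-interval series."""
    rr = np.asarray(rr_ms, dtype=float)
    if rr.ndim != 1 or rr.size < MIN_RR_INTERVALS:
        raise ValueError(f"hrv_features: need >= {MIN_RR_INTERVALS} RR intervals")
    lo, hi = RR_VALID_MS
    if np.any(rr <= lo) or np.any(rr >= hi):
        raise ValueError(f"hrv_features: RR intervals must lie in ({lo}, {hi}) ms")
    n = rr.size
    d = np.diff(rr)

    out: dict[str, float] = {}
    out["sdnn"] = float(np.std(rr, ddof=1))
    if params.rmssd_on_successive_diffs:
        out["rmssd"] = float(np.sqrt(np.mean(d**2)))
    else:
        out["rmssd"] = float(np.sqrt(np.mean(rr**2)))
    out["pnn50"] = float(100.0 * np.count_nonzero(np.abs(d) > 50.0) / (n - 1))
    out["lf_hf"] = _lf_hf_ratio(rr)

    counts, centers = _anchored_histogram(rr, RR_BIN_MS)
    out["tinn"] = _tinn(counts, centers, RR_BIN_MS)

    var_d = float(np.var(d, ddof=1)) if d.size > 1 else 0.0
    sd1_sq = 0.5 * var_d
    sd2_sq = max(2.0 * float(np.var(rr, ddof=1)) - 0.5 * var_d, 0.0)
    out["sd2_sd1"] = float(np.sqrt(sd2_sq) / max(np.sqrt(sd1_sq), 1e-9))

    out["tri_index"] = float(n / counts.max())
    rel = 2.0 * d / (rr[1:] + rr[:-1])
    rel_counts, _ = _anchored_histogram(rel, REL_RR_BIN)
    out["rel_rr_tri_index"] = float(rel.size / rel_counts.max())
    return {name: out[name] for name in HRV_FEATURES}


# ---------------------------------------------------------------------------
# table assembly

def feature_vector(
    recording: Recording, params: FeatureParams = FeatureParams()
) -> dict[str, float]:
    """All 134 features of one complete recording, keyed ``<channel>.<name>``."""
    missing = [c for c in CHANNELS if c not in recording.channels_present()]
    if missing:
        raise MissingChannelError(
            f"recording {recording.key}: missing channel(s) {', '.join(missing)}"
        )
    out: dict[str, float] = {}
    for site in EMG_SITES:
        vals = sampled_channel_features(
            recording.emg[site], recording.emg_fs_hz, include_emg_only=True, params=params
        )
        out.update({f"{site}.{k}": v for k, v in vals.items()})
    eda_vals = sampled_channel_features(
        recording.eda, recording.eda_fs_hz, include_emg_only=False, params=params
    )
    out.update({f"eda.{k}": v for k, v in eda_vals.items()})
    hrv_vals = hrv_features(recording.rr_ms, params=params)
    out.update({f"hrv.{k}": v for k, v in hrv_vals.items()})
    return out


def feature_blocks() -> dict[str, tuple[str, ...]]:
    blocks: dict[str, tuple[str, ...]] = {}
    for site in EMG_SITES:
        blocks[site] = tuple(f"{site}.{name}" for name in SAMPLED_FEATURES)
    blocks["eda"] = tuple(f"eda.{name}" for name in EDA_FEATURES)
    blocks["hrv"] = tuple(f"hrv.{name}" for name in HRV_FEATURES)
    return blocks


def build_feature_table(
    recordings, params: FeatureParams = FeatureParams()
) -> FeatureTable:
    """One row of 134 features per (subject, video); rows sorted by key.

    Recordings missing any channel are rejected collectively with their keys
    listed, mirroring the exclusion of incomplete observations.
    """
    recs = recordings.values() if isinstance(recordings, dict) else recordings
    recs = sorted(recs, key=lambda r: r.key)
    bad = [r.key for r in recs if set(CHANNELS) - set(r.channels_present())]
    if bad:
        raise MissingChannelError(
            "incomplete recordings (missing channels): " + ", ".join(map(str, bad))
        )
    rows = {r.key: feature_vector(r, params) for r in recs}
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.index = pd.MultiIndex.from_tuples(data.index, names=["subject", "video"])
    blocks = feature_blocks()
    ordered = [col for cols in blocks.values() for col in cols]
    return FeatureTable(data=data[ordered], blocks=blocks)
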