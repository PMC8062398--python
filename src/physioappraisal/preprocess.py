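"""Segmentation and filtering of the raw physiological streams.

The sampled channels go through Butterworth chains applied forward-backward
(zero phase): EMG gets high-pass 40 Hz -> 50 Hz notch (0.5 Hz wide) ->
low-pass 250 Hz and a baseline correction subtracting the mean level of the
(identically filtered) resting baseline; EDA gets a 0.5 Hz high-pass that
removes the tonic skin-conductance level.  RR intervals pass through
untouched; an interval belongs to a video when its terminating beat falls
inside the video's half-open [onset, offset) window.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .config import FilterSpec, default_eda_chain, default_emg_chain
from .datatypes import (
    BaselineRecording,
    EMG_SITES,
    RawSubjectStream,
    Recording,
    Segment,
)
from .errors import ConfigError, SegmentError
from .synthetic import assign_rr


def _design(spec: FilterSpec, fs: float):
    nyq = fs / 2.0
    if spec.kind == "notch":
        center, width = spec.cutoff_hz
        if not 0 < center < nyq:
            raise ConfigError(f"FilterSpec.cutoff_hz: notch center {center} not inside (0, {nyq})")
        if width <= 0:
            raise ConfigError("FilterSpec.cutoff_hz: notch width must be > 0")
        b, a = sps.iirnotch(center, center / width, fs=fs)
        return ("ba", b, a)
    cutoff = float(spec.cutoff_hz)
    if not 0 < cutoff < nyq:
        raise ConfigError(f"FilterSpec.cutoff_hz: cutoff {cutoff} not inside (0, {nyq})")
    sos = sps.butter(spec.order, cutoff, btype=spec.kind, fs=fs, output="sos")
    return ("sos", sos)


def apply_chain(series: np.ndarray, fs: float, chain) -> np.ndarray:
    """Apply a filter chain in order, each stage forward-backward."""
    x = np.asarray(series, dtype=float)
    for spec in chain:
        design = _design(spec, fs)
        if design[0] == "sos":
            x = sps.sosfiltfilt(design[1], x)
        else:
            x = sps.filtfilt(design[1], design[2], x)
    return x


def filter_emg(series: np.ndarray, fs: float, chain=None) -> np.ndarray:
    """EMG chain: high-pass 40 Hz -> notch 50 Hz (0.5 Hz wide) -> low-pass 250 Hz."""
    return apply_chain(series, fs, default_emg_chain() if chain is None else chain)


def filter_eda(series: np.ndarray, fs: float, chain=None) -> np.ndarray:
    """EDA chain: high-pass 0.5 Hz (tonic-level removal)."""
    return apply_chain(series, fs, default_eda_chain() if chain is None else chain)


def remove_dc_bias(series: np.ndarray, baseline_series: np.ndarray) -> np.ndarray:
    """Subtract the mean level of activation during the baseline measurement."""
    baseline_series = np.asarray(baseline_series, dtype=float)
    if baseline_series.size == 0:
        raise ValueError("remove_dc_bias: baseline series is empty")
    return np.asarray(series, dtype=float) - float(baseline_series.mean())


def _slice(x: np.ndarray, fs: float, onset_s: float, offset_s: float, key: str) -> np.ndarray:
    i0 = int(round(onset_s * fs))
    n = int(np.floor((offset_s - onset_s) * fs + 1e-9))
    if i0 < 0 or i0 + n > x.size:
        raise SegmentError(
            f"segment {key}: [{onset_s}, {offset_s}) s outside recording of {x.size / fs:.3f} s"
        )
    return x[i0 : i0 + n]


def segment_recordings(
    streams: dict[str, RawSubjectStream],
    segments,
    baseline_window: tuple[float, float],
) -> tuple[dict[tuple[str, str], Recording], dict[str, BaselineRecording]]:
    """Cut per-subject streams into per-(subject, video) recordings.

    ``baseline_window`` is the [onset, offset) of the resting baseline,
    shared across subjects (it opens each acquisition).  Within one subject,
    video segments must not overlap.
    """
    by_subject: dict[str, list[Segment]] = {}
    for seg in segments:
        by_subject.setdefault(seg.subject, []).append(seg)
    for subj, segs in by_subject.items():
        segs.sort(key=lambda s: s.onset_s)
        for a, b in zip(segs, segs[1:]):
            if b.onset_s < a.offset_s:
                raise SegmentError(f"subject {subj}: segments {a.video} and {b.video} overlap")

    recordings: dict[tuple[str, str], Recording] = {}
    baselines: dict[str, BaselineRecording] = {}
    b_on, b_off = baseline_window
    for subj, segs in by_subject.items():
        if subj not in streams:
            raise SegmentError(f"segment index names unknown subject {subj}")
        stream = streams[subj]
        baselines[subj] = BaselineRecording(
            subject=subj,
            emg={
                site: _slice(stream.emg[site], stream.emg_fs_hz, b_on, b_off, f"{subj}/baseline")
                for site in EMG_SITES
            },
            eda=_slice(stream.eda, stream.eda_fs_hz, b_on, b_off, f"{subj}/baseline"),
            rr_ms=assign_rr(stream.rr_ms, b_on, b_off),
            emg_fs_hz=stream.emg_fs_hz,
            eda_fs_hz=stream.eda_fs_hz,
        )
        for seg in segs:
            key = f"{subj}/{seg.video}"
            recordings[(subj, seg.video)] = Recording(
                subject=subj,
                video=seg.video,
                emg={
                    site: _slice(stream.emg[site], stream.emg_fs_hz, seg.onset_s, seg.offset_s, key)
                    for site in EMG_SITES
                },
                eda=_slice(stream.eda, stream.eda_fs_hz, seg.onset_s, seg.offset_s, key),
                rr_ms=assign_rr(stream.rr_ms, seg.onset_s, seg.offset_s),
                emg_fs_hz=stream.emg_fs_hz,
                eda_fs_hz=stream.eda_fs_hz,
            )
    return recordings, baselines


def preprocess_recording(
    recording: Recording,
    baseline: BaselineRecording,
    emg_chain=None,
    eda_chain=None,
) -> Recording:
    """Filter one segmented recording and baseline-correct the EMG channels.

    The baseline series is passed through the same EMG chain before its mean
    is taken, so the correction is on the scale of the corrected signal.
    """
    emg = {}
    for site in EMG_SITES:
        filtered = filter_emg(recording.emg[site], recording.emg_fs_hz, emg_chain)
        base = filter_emg(baseline.emg[site], baseline.emg_fs_hz, emg_chain)
        emg[site] = remove_dc_bias(filtered, base)
    return Recording(
        subject=recording.subject,
        video=recording.video,
        emg=emg,
        eda=filter_eda(recording.eda, recording.eda_fs_hz, eda_chain),
        rr_ms=np.asarray(recording.rr_ms, dtype=float),
        emg_fs_hz=recording.emg_fs_hz,
        eda_fs_hz=recording.eda_fs_hz,
    )


def preprocess_dataset(recordings, baselines, emg_chain=None, eda_chain=None):
    """Apply :func:`preprocess_recording` to every (subject, video) unit."""
    out = {}
    for key, rec in recordings.items():
        out[key] = preprocess_recording(rec, baselines[rec.subject], emg_chain, eda_chain)
    return out
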