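"""Plain-text on-disk layout for raw studies and result tables.

Layout of a study directory::

    manifest.json                 sampling rates + baseline window
    segments.csv                  subject,video,onset_s,offset_s
    appraisals.csv                subject,video,<21 item columns>
    signals/<subject>/zyg.txt     two columns: time_s  value (mV)
    signals/<subject>/corr.txt
    signals/<subject>/front.txt
    signals/<subject>/eda.txt     two columns: time_s  value (uS)
    signals/<subject>/rr.txt      one RR interval per line, ms

Values are written with full float precision so a write -> read round trip
reproduces the arrays exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EMG_SITES, RawSubjectStream, Segment, StudyDataset
from .errors import ParseError

_SAMPLED_FILES = {"zyg": "zyg.txt", "corr": "corr.txt", "front": "front.txt", "eda": "eda.txt"}


@dataclass
class ReadResult:
    streams: dict[str, RawSubjectStream]
    segments: tuple[Segment, ...]
    baseline_window: tuple[float, float]
    appraisals: pd.DataFrame | None
    incomplete: dict[str, list[str]] = field(default_factory=dict)


def write_dataset(dataset: StudyDataset, out_dir) -> None:
    """Write a generated study (with streams) to the plain-text layout."""
    if not dataset.streams:
        raise ValueError("write_dataset: dataset has no streams; generate with include_streams=True")
    out = Path(out_dir)
    (out / "signals").mkdir(parents=True, exist_ok=True)
    any_stream = next(iter(dataset.streams.values()))
    baseline_dur = next(iter(dataset.baselines.values())).emg["zyg"].size / any_stream.emg_fs_hz
    manifest = {
        "emg_fs_hz": any_stream.emg_fs_hz,
        "eda_fs_hz": any_stream.eda_fs_hz,
        "baseline_window_s": [0.0, baseline_dur],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    seg_df = pd.DataFrame(
        [
            {"subject": s.subject, "video": s.video, "onset_s": s.onset_s, "offset_s": s.offset_s}
            for s in dataset.segments
        ]
    )
    seg_df.to_csv(out / "segments.csv", index=False)
    dataset.appraisals.to_csv(out / "appraisals.csv", index=False)

    for subj, stream in dataset.streams.items():
        sdir = out / "signals" / subj
        sdir.mkdir(parents=True, exist_ok=True)
        for site in EMG_SITES:
            _write_sampled(sdir / _SAMPLED_FILES[site], stream.emg[site], stream.emg_fs_hz)
        _write_sampled(sdir / _SAMPLED_FILES["eda"], stream.eda, stream.eda_fs_hz)
        with open(sdir / "rr.txt", "w") as fh:
            for v in stream.rr_ms:
                fh.write(f"{float(v)!r}\n")


def _write_sampled(path: Path, x: np.ndarray, fs: float) -> None:
    t = np.arange(x.size) / fs
    with open(path, "w") as fh:
        for ti, vi in zip(t, x):
            fh.write(f"{ti:.6f}\t{float(vi)!r}\n")


def _read_sampled(path: Path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                values.append(float(parts[1]))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: not a number: {parts[1]!r}") from None
    return np.asarray(values)


def _read_rr(path: Path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: not a number: {line!r}") from None
    return np.asarray(values)


def read_signals(in_dir) -> ReadResult:
    """Read the study layout back into typed in-memory objects.

    Subjects with missing channel files are kept, with the missing files
    listed in ``incomplete`` (their recordings will fail feature-table
    completeness checks downstream, mirroring the study's exclusions).
    """
    root = Path(in_dir)
    sig_root = root / "signals"
    if not sig_root.is_dir() or not any(sig_root.iterdir()):
        raise ParseError(f"{root}: no subjects found under signals/")
    manifest = json.loads((root / "manifest.json").read_text())
    emg_fs = float(manifest["emg_fs_hz"])
    eda_fs = float(manifest["eda_fs_hz"])
    baseline_window = tuple(manifest["baseline_window_s"])

    seg_df = pd.read_csv(root / "segments.csv")
    segments = tuple(
        Segment(str(r.subject), str(r.video), float(r.onset_s), float(r.offset_s))
        for r in seg_df.itertuples()
    )
    appr_path = root / "appraisals.csv"
    appraisals = pd.read_csv(appr_path) if appr_path.exists() else None

    streams: dict[str, RawSubjectStream] = {}
    incomplete: dict[str, list[str]] = {}
    for sdir in sorted(p for p in sig_root.iterdir() if p.is_dir()):
        subj = sdir.name
        missing = [f for f in (*_SAMPLED_FILES.values(), "rr.txt") if not (sdir / f).exists()]
        if missing:
            incomplete[subj] = missing
        emg = {
            site: _read_sampled(sdir / _SAMPLED_FILES[site])
            for site in EMG_SITES
            if (sdir / _SAMPLED_FILES[site]).exists()
        }
        eda_path = sdir / _SAMPLED_FILES["eda"]
        eda = _read_sampled(eda_path) if eda_path.exists() else np.empty(0)
        rr_path = sdir / "rr.txt"
        rr = _read_rr(rr_path) if rr_path.exists() else np.empty(0)
        streams[subj] = RawSubjectStream(
            subject=subj, emg=emg, eda=eda, rr_ms=rr, emg_fs_hz=emg_fs, eda_fs_hz=eda_fs
        )
    return ReadResult(
        streams=streams,
        segments=segments,
        baseline_window=baseline_window,
        appraisals=appraisals,
        incomplete=incomplete,
    )


def write_feature_table(table, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = table.data.reset_index()
    df.to_csv(out / "features.csv", index=False)
    blocks = {ch: list(cols) for ch, cols in table.blocks.items()}
    (out / "feature_blocks.json").write_text(json.dumps(blocks, indent=2))


def read_feature_table(in_dir):
    from .datatypes import FeatureTable

    root = Path(in_dir)
    df = pd.read_csv(root / "features.csv").set_index(["subject", "video"])
    blocks = {
        ch: tuple(cols)
        for ch, cols in json.loads((root / "feature_blocks.json").read_text()).items()
    }
    return FeatureTable(data=df, blocks=blocks)
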