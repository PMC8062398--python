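"""Read the raw layout, preprocess, and extract the 134-feature table.

Segments each subject's stream with the E-Prime-style segment index, applies
the EMG chain (40 Hz high-pass, 0.5 Hz-wide 50 Hz notch, 250 Hz low-pass,
baseline correction) and the 0.5 Hz EDA high-pass, then computes one
134-feature row per (subject, video).  Writes results/features.csv and the
channel-block sidecar.
"""

from pathlib import Path

from physioappraisal.features import build_feature_table
from physioappraisal.io import read_signals, write_feature_table
from physioappraisal.preprocess import preprocess_dataset, segment_recordings

OUT = Path("results")


def main() -> None:
    raw = read_signals(OUT / "raw")
    recordings, baselines = segment_recordings(raw.streams, raw.segments, raw.baseline_window)
    clean = preprocess_dataset(recordings, baselines)
    table = build_feature_table(clean)
    write_feature_table(table, OUT)
    sizes = {ch: len(cols) for ch, cols in table.blocks.items()}
    print(f"feature table: {table.data.shape[0]} recordings x {table.data.shape[1]} features")
    print(f"block sizes: {sizes}")
    print(f"-> {OUT / 'features.csv'}, {OUT / 'feature_blocks.json'}")


if __name__ == "__main__":
    main()
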