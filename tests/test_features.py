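"""Feature definitions against closed forms, hand examples and the
independent direct-summation oracles."""

import numpy as np
import pytest

from physioappraisal.errors import MissingChannelError
from physioappraisal.features import (
    EDA_FEATURES,
    FeatureParams,
    HRV_FEATURES,
    SAMPLED_FEATURES,
    build_feature_table,
    hrv_features,
    sampled_channel_features,
)

from oracles import hrv_features_oracle, sampled_features_oracle

FS = 1000.0


def test_block_cardinalities():
    x = np.random.default_rng(0).standard_normal(512)
    assert len(sampled_channel_features(x, FS, include_emg_only=True)) == 32
    assert len(sampled_channel_features(x, FS, include_emg_only=False)) == 30
    assert len(SAMPLED_FEATURES) == 32 and len(EDA_FEATURES) == 30
    assert len(HRV_FEATURES) == 8


def test_constant_series_definitions():
    c = 0.25
    f = sampled_channel_features(np.full(256, c), FS)
    assert f["mav"] == pytest.approx(c)
    assert f["rms"] == pytest.approx(c)
    assert f["var"] == 0.0
    assert f["pct_zc"] == 0.0
    assert f["pct_ssc"] == 0.0
    assert all(np.isfinite(v) for v in f.values())


def test_all_zero_series_stays_finite():
    f = sampled_channel_features(np.zeros(256), FS)
    assert all(np.isfinite(v) for v in f.values())
    assert f["log_detector"] == pytest.approx(1e-12)


def test_sine_rms_and_peak_frequency():
    n = 4000  # 80 whole periods of 20 Hz at 1000 Hz
    t = np.arange(n) / FS
    f = sampled_channel_features(np.sin(2 * np.pi * 20.0 * t), FS)
    assert abs(f["rms"] - 1 / np.sqrt(2)) < 1e-3
    assert abs(f["peak_freq"] - 20.0) <= FS / n + 1e-9


def test_alternating_signal_crosses_every_step():
    x = np.tile([0.3, -0.3], 100)
    f = sampled_channel_features(x, FS)
    assert f["pct_zc"] == pytest.approx(100.0)


def test_short_series_rejected():
    with pytest.raises(ValueError):
        sampled_channel_features(np.ones(10), FS)


@pytest.mark.parametrize("case", range(20))
def test_oracle_equivalence_sampled(case):
    rng = np.random.default_rng(100 + case)
    n = int(rng.integers(100, 400))
    scale = 10.0 ** rng.uniform(-3, 0)
    x = scale * rng.standard_normal(n)
    include = bool(case % 2)
    ours = sampled_channel_features(x, FS, include_emg_only=include)
    ref = sampled_features_oracle(x, FS, include_emg_only=include)
    assert set(ours) == set(ref)
    for name in ours:
        assert ours[name] == pytest.approx(ref[name], rel=1e-10, abs=1e-12), name


@pytest.mark.parametrize("case", range(8))
def test_oracle_equivalence_hrv(case):
    rng = np.random.default_rng(200 + case)
    n = int(rng.integers(8, 40))
    rr = np.clip(800 + 60 * rng.standard_normal(n), 300, 2000)
    ours = hrv_features(rr)
    ref = hrv_features_oracle(rr)
    for name in ours:
        assert ours[name] == pytest.approx(ref[name], rel=1e-10, abs=1e-12), name


def test_hrv_hand_examples():
    f = hrv_features(np.array([800.0, 800.0, 800.0, 800.0]))
    assert f["sdnn"] == 0.0
    assert f["rmssd"] == 0.0
    assert f["pnn50"] == 0.0
    assert f["tri_index"] == pytest.approx(1.0)
    assert all(np.isfinite(v) for v in f.values())

    # successive diffs {60, 5, 85}: two of three exceed 50 ms
    f = hrv_features(np.array([650.0, 710.0, 715.0, 800.0]))
    assert f["pnn50"] == pytest.approx(200.0 / 3.0)

    # diffs of exactly 50 ms do not count; hand-computed SDNN/RMSSD
    f = hrv_features(np.array([800.0, 850.0, 800.0, 850.0]))
    assert f["pnn50"] == 0.0
    assert f["sdnn"] == pytest.approx(np.sqrt(2500.0 / 3.0))
    assert f["rmssd"] == pytest.approx(50.0)
    assert f["tri_index"] == pytest.approx(2.0)
    assert len(f) == 8


def test_hrv_input_validation():
    with pytest.raises(ValueError):
        hrv_features(np.array([800.0, 810.0, 790.0]))  # too few
    with pytest.raises(ValueError):
        hrv_features(np.array([800.0, 810.0, 100.0, 790.0]))  # out of range


def test_rmssd_config_switch():
    rr = np.array([700.0, 800.0, 900.0, 800.0])
    default = hrv_features(rr)["rmssd"]
    raw = hrv_features(rr, FeatureParams(rmssd_on_successive_diffs=False))["rmssd"]
    assert default == pytest.approx(100.0)
    assert raw == pytest.approx(np.sqrt(np.mean(rr**2)))


@pytest.mark.parametrize("scale", [0.01, 3.0])
def test_scale_equivariance(scale):
    rng = np.random.default_rng(4)
    x = rng.standard_normal(500)
    base = sampled_channel_features(x, FS)
    scaled = sampled_channel_features(scale * x, FS)
    for name in ("mav", "mav_trim20", "tmav", "rms", "dasdv", "pct_wavelength"):
        assert scaled[name] == pytest.approx(scale * base[name], rel=1e-9)
    for name in ("var", "ssi", "total_power"):
        assert scaled[name] == pytest.approx(scale**2 * base[name], rel=1e-9)
    for name in ("pct_zc", "pct_ssc"):  # threshold-free percentages
        assert scaled[name] == pytest.approx(base[name])


def test_length_invariance_of_normalized_features():
    """A stationary process gives the same feature values on 10 s and 30 s
    segments up to sampling error (no systematic length trend)."""
    from scipy import signal as sps

    sos = sps.butter(4, (60, 250), btype="bandpass", fs=FS, output="sos")
    names = ("mav", "ssi", "pct_zc", "tmav", "mean_power", "total_power", "mnf_pow")
    short, long = {n: [] for n in names}, {n: [] for n in names}
    for sim in range(50):
        rng = np.random.default_rng(300 + sim)
        x = sps.sosfiltfilt(sos, rng.standard_normal(int(30 * FS)))
        fs_short = sampled_channel_features(x[: int(10 * FS)], FS)
        fs_long = sampled_channel_features(x, FS)
        for n in names:
            short[n].append(fs_short[n])
            long[n].append(fs_long[n])
    for n in names:
        m_short, m_long = np.mean(short[n]), np.mean(long[n])
        assert abs(m_long - m_short) < 0.05 * abs(m_short), n


def test_feature_table_shape_and_order_invariance(one_recovery_run):
    from physioappraisal.preprocess import preprocess_dataset

    dataset, table = one_recovery_run
    assert table.data.shape == (len(dataset.recordings), 134)
    assert {ch: len(cols) for ch, cols in table.blocks.items()} == {
        "zyg": 32, "corr": 32, "front": 32, "eda": 30, "hrv": 8,
    }
    assert table.data.notna().all().all()
    assert np.isfinite(table.data.to_numpy()).all()

    # permuted input order yields the identical table
    clean = preprocess_dataset(dataset.recordings, dataset.baselines)
    subset = {k: clean[k] for k in list(clean)[:8]}
    reversed_subset = dict(reversed(list(subset.items())))
    t1 = build_feature_table(subset)
    t2 = build_feature_table(reversed_subset)
    assert t1.data.equals(t2.data)


def test_incomplete_recording_rejected_with_key(one_recovery_run):
    dataset, _ = one_recovery_run
    key = next(iter(dataset.recordings))
    broken = dict(dataset.recordings)
    import copy

    rec = copy.deepcopy(broken[key])
    rec.rr_ms = np.empty(0)
    broken[key] = rec
    with pytest.raises(MissingChannelError, match=key[0]):
        build_feature_table(broken)
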