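"""Independent direct-summation reference implementations.

Everything here is written with explicit Python loops (plus an O(N^2) DFT
and a dense linear solve), deliberately avoiding the vectorized scipy /
statsmodels code paths the library uses, so agreement is a genuine
cross-check and not a tautology.
"""

import math

import numpy as np


def _trimmed_mean(values, trim):
    s = sorted(values)
    n = len(s)
    cut = int(trim * n)
    kept = s[cut : n - cut]
    return sum(kept) / len(kept)


def _autocov(x, k):
    n = len(x)
    m = sum(x) / n
    total = 0.0
    for t in range(n - k):
        total += (x[t] - m) * (x[t + k] - m)
    return total / n


def _ar4(x):
    if max(x) == min(x):
        return [0.0, 0.0, 0.0, 0.0]
    r = [_autocov(x, k) for k in range(5)]
    R = np.array([[r[abs(i - j)] for j in range(4)] for i in range(4)])
    return list(np.linalg.solve(R, np.array(r[1:5])))


def _dft_periodogram(x, fs):
    """One-sided PSD of the demeaned series, explicit DFT sums."""
    n = len(x)
    m = sum(x) / n
    xm = [v - m for v in x]
    n_bins = n // 2 + 1
    freqs, power = [], []
    for k in range(n_bins):
        re = im = 0.0
        for t in range(n):
            ang = -2.0 * math.pi * k * t / n
            re += xm[t] * math.cos(ang)
            im += xm[t] * math.sin(ang)
        p = (re * re + im * im) / (fs * n)
        if k not in (0, n // 2 if n % 2 == 0 else -1):
            p *= 2.0
        freqs.append(k * fs / n)
        power.append(p)
    return freqs, power


def sampled_features_oracle(x, fs, include_emg_only=True, zc_threshold=0.005,
                            myopulse_threshold=0.016, wamp_threshold=0.005,
                            tmav_window_ms=100.0, trim=0.2):
    x = [float(v) for v in x]
    n = len(x)
    absx = [abs(v) for v in x]
    out = {}
    out["mav"] = sum(absx) / n
    out["mav_trim20"] = _trimmed_mean(absx, trim)
    window = min(max(int(round(tmav_window_ms * fs / 1000.0)), 1), n)
    smoothed = [_trimmed_mean(absx[i : i + window], trim) for i in range(n - window + 1)]
    out["tmav"] = sum(smoothed) / len(smoothed)
    out["ssi"] = sum(v * v for v in x) / n
    mean = sum(x) / n
    out["var"] = sum((v - mean) ** 2 for v in x) / (n - 1)
    for k in (3, 4, 5):
        out[f"abs_moment{k}"] = abs(sum(v**k for v in x) / n)
    ar = _ar4(x)
    for k in range(4):
        out[f"ar{k + 1}"] = ar[k]
    out["rms"] = math.sqrt(sum(v * v for v in x) / n)
    out["log_detector"] = math.exp(sum(math.log(max(a, 1e-12)) for a in absx) / n)
    wl = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    out["pct_wavelength"] = wl / (n - 1)
    out["avg_amp_change"] = wl / (n - 1)
    out["dasdv"] = math.sqrt(sum((x[i + 1] - x[i]) ** 2 for i in range(n - 1)) / (n - 1))
    zc = zc_t = wamp = 0
    for i in range(n - 1):
        if x[i] * x[i + 1] < 0:
            zc += 1
            if abs(x[i] - x[i + 1]) >= zc_threshold:
                zc_t += 1
        if abs(x[i] - x[i + 1]) > wamp_threshold:
            wamp += 1
    out["pct_zc"] = 100.0 * zc / (n - 1)
    if include_emg_only:
        out["pct_zc_thresh"] = 100.0 * zc_t / (n - 1)
    ssc = sum(
        1 for i in range(1, n - 1) if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > 0
    )
    out["pct_ssc"] = 100.0 * ssc / (n - 2)
    out["pct_myopulse"] = 100.0 * sum(1 for a in absx if a >= myopulse_threshold) / n
    if include_emg_only:
        out["pct_wamp"] = 100.0 * wamp / (n - 1)

    freqs, power = _dft_periodogram(x, fs)
    amp = [math.sqrt(p) for p in power]
    df = freqs[1] - freqs[0]

    def median_freq(mass):
        total = sum(mass)
        if total <= 0:
            return 0.0
        cum = 0.0
        for f, m in zip(freqs, mass):
            cum += m
            if cum >= 0.5 * total:
                return f
        return freqs[-1]

    def mean_freq(mass):
        total = sum(mass)
        if total <= 0:
            return 0.0
        return sum(f * m for f, m in zip(freqs, mass)) / total

    out["mdf_amp"] = median_freq(amp)
    out["mnf_amp"] = mean_freq(amp)
    out["mdf_pow"] = median_freq(power)
    out["mnf_pow"] = mean_freq(power)
    peak_i = max(range(len(power)), key=lambda i: power[i])
    out["peak_freq"] = freqs[peak_i] if power[peak_i] > 0 else 0.0
    out["mean_power"] = sum(power) / len(power)
    out["total_power"] = sum(power) * df
    for k in (1, 2, 3):
        out[f"sm{k}"] = sum(p * f**k for f, p in zip(freqs, power)) * df
    return out


# ---------------------------------------------------------------------------
# HRV

def _hist_anchored(values, width):
    lo = math.floor(min(values) / width)
    hi = math.floor(max(values) / width) + 1
    counts = {}
    for v in values:
        b = min(math.floor(v / width), hi - 1)
        counts[b] = counts.get(b, 0) + 1
    bins = list(range(lo, hi))
    return [counts.get(b, 0) for b in bins], [(b + 0.5) * width for b in bins]


def _lomb_power(t, y, freq_hz):
    w = 2.0 * math.pi * freq_hz
    s2 = sum(math.sin(2 * w * ti) for ti in t)
    c2 = sum(math.cos(2 * w * ti) for ti in t)
    tau = math.atan2(s2, c2) / (2 * w)
    cc = ss = yc = ys = 0.0
    for ti, yi in zip(t, y):
        c = math.cos(w * (ti - tau))
        s = math.sin(w * (ti - tau))
        cc += c * c
        ss += s * s
        yc += yi * c
        ys += yi * s
    return 0.5 * (yc * yc / cc + ys * ys / ss)


def _trapz(ys, xs):
    total = 0.0
    for i in range(len(xs) - 1):
        total += 0.5 * (ys[i] + ys[i + 1]) * (xs[i + 1] - xs[i])
    return total


def _tinn_oracle(counts, centers, width):
    occupied = [i for i, c in enumerate(counts) if c > 0]
    if len(occupied) < 2:
        return 0.0
    m = max(range(len(counts)), key=lambda i: counts[i])
    peak = counts[m]
    best_sse, best = None, (centers[m] - width, centers[m] + width)
    for kl in range(1, m + 2):
        nfoot = centers[m] - width * kl
        for kr in range(1, len(counts) - m + 1):
            mfoot = centers[m] + width * kr
            sse = 0.0
            for c, ctr in zip(counts, centers):
                if nfoot <= ctr <= centers[m]:
                    tri = peak * (ctr - nfoot) / (centers[m] - nfoot)
                elif centers[m] < ctr <= mfoot:
                    tri = peak * (mfoot - ctr) / (mfoot - centers[m])
                else:
                    tri = 0.0
                sse += (c - tri) ** 2
            if best_sse is None or sse < best_sse - 1e-12:
                best_sse, best = sse, (nfoot, mfoot)
    return best[1] - best[0]


def hrv_features_oracle(rr):
    rr = [float(v) for v in rr]
    n = len(rr)
    d = [rr[i + 1] - rr[i] for i in range(n - 1)]
    mean = sum(rr) / n
    out = {}
    out["sdnn"] = math.sqrt(sum((v - mean) ** 2 for v in rr) / (n - 1))
    out["rmssd"] = math.sqrt(sum(v * v for v in d) / len(d))
    out["pnn50"] = 100.0 * sum(1 for v in d if abs(v) > 50.0) / (n - 1)

    t = []
    acc = 0.0
    for v in rr:
        acc += v / 1000.0
        t.append(acc)
    y = [v - mean for v in rr]
    if max(rr) == min(rr):
        out["lf_hf"] = 0.0
    else:
        lf_grid = [0.04 + i * (0.15 - 0.04) / 59 for i in range(60)]
        hf_grid = [0.15 + i * (0.40 - 0.15) / 59 for i in range(60)]
        lf = _trapz([_lomb_power(t, y, f) for f in lf_grid], lf_grid)
        hf = _trapz([_lomb_power(t, y, f) for f in hf_grid], hf_grid)
        out["lf_hf"] = max(lf, 0.0) / max(hf, 1e-12)

    counts, centers = _hist_anchored(rr, 7.8125)
    out["tinn"] = _tinn_oracle(counts, centers, 7.8125)

    md = sum(d) / len(d)
    var_d = sum((v - md) ** 2 for v in d) / (len(d) - 1) if len(d) > 1 else 0.0
    sd1 = math.sqrt(0.5 * var_d)
    sd2 = math.sqrt(max(2.0 * sum((v - mean) ** 2 for v in rr) / (n - 1) - 0.5 * var_d, 0.0))
    out["sd2_sd1"] = sd2 / max(sd1, 1e-9)

    out["tri_index"] = n / max(counts)
    rel = [2.0 * (rr[i + 1] - rr[i]) / (rr[i + 1] + rr[i]) for i in range(n - 1)]
    rel_counts, _ = _hist_anchored(rel, 0.01)
    out["rel_rr_tri_index"] = len(rel) / max(rel_counts)
    return out
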