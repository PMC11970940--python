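"""Independent brute-force reference implementations.

Every function here recomputes an HRV statistic from first principles —
explicit loops, textbook formulas, manual FFT bookkeeping — sharing no code
path with the package, so agreement is evidence of correctness rather than
of shared bugs. Kept deliberately slow and literal.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.interpolate import CubicSpline


def oracle_time_domain(rr: np.ndarray) -> dict[str, float]:
    rr = [float(v) for v in rr]
    n = len(rr)
    mean = sum(rr) / n
    srt = sorted(rr)
    median = srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2])
    sdnn = math.sqrt(sum((v - mean) ** 2 for v in rr) / (n - 1))
    d = [rr[i + 1] - rr[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(v**2 for v in d) / len(d))
    dmean = sum(d) / len(d)
    sdsd = math.sqrt(sum((v - dmean) ** 2 for v in d) / (len(d) - 1))
    m2 = sum((v - mean) ** 2 for v in rr) / n
    m3 = sum((v - mean) ** 3 for v in rr) / n
    m4 = sum((v - mean) ** 4 for v in rr) / n
    if m2 > 0:
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    else:
        skew = kurt = 0.0
    return {
        "mean_rr": mean,
        "median_rr": median,
        "sdnn": sdnn,
        "rmssd": rmssd,
        "sdsd": sdsd,
        "sdnn_rmssd": sdnn / rmssd if rmssd > 0 else 0.0,
        "hr": 60000.0 / mean,
        "pnn25": 100.0 * sum(1 for v in d if abs(v) > 25.0) / len(d),
        "pnn50": 100.0 * sum(1 for v in d if abs(v) > 50.0) / len(d),
        "kurt": kurt,
        "skew": skew,
    }


def oracle_relative_time_domain(rr: np.ndarray) -> dict[str, float]:
    rr = [float(v) for v in rr]
    n = len(rr)
    mean_rr = sum(rr) / n
    u = [v / mean_rr - 1.0 for v in rr]
    mean = sum(u) / n
    srt = sorted(u)
    median = srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2])
    sdnn = math.sqrt(sum((v - mean) ** 2 for v in u) / (n - 1))
    d = [u[i + 1] - u[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(v**2 for v in d) / len(d))
    dmean = sum(d) / len(d)
    sdsd = math.sqrt(sum((v - dmean) ** 2 for v in d) / (len(d) - 1))
    m2 = sum((v - mean) ** 2 for v in u) / n
    m3 = sum((v - mean) ** 3 for v in u) / n
    m4 = sum((v - mean) ** 4 for v in u) / n
    return {
        "rel_mean_rr": mean,
        "rel_median_rr": median,
        "rel_sdnn": sdnn,
        "rel_rmssd": rmssd,
        "rel_sdsd": sdsd,
        "rel_sdnn_rmssd": sdnn / rmssd if rmssd > 0 else 0.0,
        "rel_kurt": m4 / m2**2 - 3.0 if m2 > 0 else 0.0,
        "rel_skew": m3 / m2**1.5 if m2 > 0 else 0.0,
    }


def oracle_poincare(rr: np.ndarray) -> tuple[float, float]:
    """SD1/SD2 by literally rotating the lag-1 scatter by 45 degrees."""
    rr = np.asarray(rr, dtype=float)
    x, y = rr[:-1], rr[1:]
    u = (y - x) / math.sqrt(2.0)  # perpendicular to identity line
    sd1 = float(np.std(u, ddof=1))
    sdnn = float(np.std(rr, ddof=1))
    sdsd = float(np.std(np.diff(rr), ddof=1))
    sd2 = math.sqrt(max(2.0 * sdnn**2 - 0.5 * sdsd**2, 0.0))
    return sd1, sd2


def oracle_sampen(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """O(n^2) literal template counting (ordered pairs, i != j, dist < r)."""
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    r = r_factor * sd

    def count(length: int) -> int:
        total = 0
        for i in range(n - m):
            for j in range(n - m):
                if i == j:
                    continue
                if all(abs(x[i + k] - x[j + k]) < r for k in range(length)):
                    total += 1
        return total

    b = count(m)
    if b == 0:
        return float("inf")
    a = count(m + 1)
    if a == 0:
        return float("inf")
    return -math.log(a / b)


def oracle_higuchi(x: np.ndarray, kmax: int = 8) -> float:
    """Literal Higuchi curve-length construction with a hand-rolled fit."""
    x = [float(v) for v in x]
    n = len(x)
    log_k, log_l = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m0 in range(k):
            idx = list(range(m0, n, k))
            if len(idx) < 2:
                continue
            dist = sum(abs(x[idx[i]] - x[idx[i - 1]]) for i in range(1, len(idx)))
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(dist * norm / k)
        log_k.append(math.log(k))
        log_l.append(math.log(sum(lengths) / len(lengths)))
    nk = len(log_k)
    mx = sum(log_k) / nk
    my = sum(log_l) / nk
    slope = sum((a - mx) * (b - my) for a, b in zip(log_k, log_l)) / sum(
        (a - mx) ** 2 for a in log_k
    )
    return -slope


def oracle_psd(
    rr_ms: np.ndarray, beat_times_s: np.ndarray, resample_hz: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD rebuilt by hand: explicit segments, periodic Hann, rfft.

    Shares only the tachogram resampling definition (cubic spline on the
    cumulative beat times) with the implementation; the spectral estimate
    itself is recomputed from scratch.
    """
    t = np.asarray(beat_times_s, dtype=float)
    x = np.asarray(rr_ms, dtype=float)
    cs = CubicSpline(t, x)
    grid = np.arange(t[0], t[-1] + 0.5 / resample_hz, 1.0 / resample_hz)
    grid = grid[grid <= t[-1]]
    y = cs(grid)
    y = y - np.mean(y)
    n = y.size
    nperseg = min(n, int(round(120.0 * resample_hz)))
    noverlap = nperseg // 2
    step = nperseg - noverlap
    k = np.arange(nperseg)
    w = 0.5 - 0.5 * np.cos(2 * np.pi * k / nperseg)  # periodic Hann
    scale = 1.0 / (resample_hz * np.sum(w**2))
    psds = []
    for start in range(0, n - nperseg + 1, step):
        seg = y[start : start + nperseg] * w
        spec = np.abs(np.fft.rfft(seg)) ** 2 * scale
        spec[1:] *= 2.0
        if nperseg % 2 == 0:
            spec[-1] /= 2.0
        psds.append(spec)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / resample_hz)
    return freqs, np.mean(psds, axis=0)


def oracle_band_power(
    freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float
) -> float:
    """Trapezoid integral with linearly interpolated band edges, by loop."""
    f = list(map(float, freqs))
    p = list(map(float, psd))
    if hi <= f[0] or lo >= f[-1]:
        return 0.0
    lo = max(lo, f[0])
    hi = min(hi, f[-1])

    def interp(x0):
        for i in range(len(f) - 1):
            if f[i] <= x0 <= f[i + 1]:
                if f[i + 1] == f[i]:
                    return p[i]
                frac = (x0 - f[i]) / (f[i + 1] - f[i])
                return p[i] + frac * (p[i + 1] - p[i])
        raise AssertionError("edge outside grid")

    xs = [lo] + [fv for fv in f if lo < fv < hi] + [hi]
    ys = [interp(lo)] + [p[i] for i, fv in enumerate(f) if lo < fv < hi] + [interp(hi)]
    total = 0.0
    for i in range(len(xs) - 1):
        total += 0.5 * (ys[i] + ys[i + 1]) * (xs[i + 1] - xs[i])
    return total


def oracle_frequency_domain(
    rr_ms: np.ndarray,
    beat_times_s: np.ndarray,
    bands=((0.003, 0.04), (0.04, 0.15), (0.15, 0.4)),
    resample_hz: float = 4.0,
) -> dict[str, float]:
    freqs, psd = oracle_psd(rr_ms, beat_times_s, resample_hz)
    vlf = oracle_band_power(freqs, psd, *bands[0])
    lf = oracle_band_power(freqs, psd, *bands[1])
    hf = oracle_band_power(freqs, psd, *bands[2])
    tf = vlf + lf + hf
    denom = tf - vlf
    return {
        "vlf": vlf,
        "lf": lf,
        "hf": hf,
        "tf": tf,
        "vlf_pct": 100.0 * vlf / tf if tf > 0 else 0.0,
        "lf_pct": 100.0 * lf / tf if tf > 0 else 0.0,
        "hf_pct": 100.0 * hf / tf if tf > 0 else 0.0,
        "lf_nu": 100.0 * lf / denom if denom > 0 else 0.0,
        "hf_nu": 100.0 * hf / denom if denom > 0 else 0.0,
        "lf_hf": lf / hf if hf > 0 else 0.0,
        "hf_lf": hf / lf if lf > 0 else 0.0,
    }


def oracle_all_features(
    rr_ms: np.ndarray, beat_times_s: np.ndarray
) -> dict[str, float]:
    """All 34 parameters via the brute-force routes above."""
    out = oracle_time_domain(rr_ms)
    out.update(oracle_relative_time_domain(rr_ms))
    out.update(oracle_frequency_domain(rr_ms, beat_times_s))
    sd1, sd2 = oracle_poincare(rr_ms)
    out["sd1"], out["sd2"] = sd1, sd2
    out["sampen"] = oracle_sampen(rr_ms)
    out["higuchi"] = oracle_higuchi(rr_ms)
    return out
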