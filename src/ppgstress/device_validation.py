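"""Cross-signal agreement analyses between two beat or PPG sources.

Used to compare a device under test against a reference recording of the
same physiology: RR-interval regression, block-wise Pearson correlation of
the overlaid waveforms, correlation of FFT magnitude spectra, and an STFT
time-frequency map with band-energy summaries for the 2-6 Hz and 6-10 Hz
ranges where PPG harmonic content concentrates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .beat_detection import RRSeries
from .io_formats import PpgRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionReport",
    "Spectrogram",
    "align_rr_pairs",
    "match_rr_by_time",
    "linear_regression",
    "windowed_pearson",
    "spectrum_correlation",
    "stft_spectrogram",
    "band_energy",
]


@dataclass(frozen=True)
class RegressionReport:
    """Ordinary-least-squares fit of y on x with Pearson r and r^2 = r*r."""

    slope: float
    intercept: float
    r: float
    r2: float
    n: int


@dataclass(frozen=True)
class Spectrogram:
    """Hann-windowed STFT magnitude: |S[f, t]|."""

    freqs: np.ndarray
    times: np.ndarray
    magnitude: np.ndarray  # shape (n_freqs, n_times)


def align_rr_pairs(
    a: RRSeries, b: RRSeries, max_lag: int = 5
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair two RR series beat-by-beat after a small integer lag search.

    Two devices rarely start on the same beat; the lag in [-max_lag,
    +max_lag] maximizing the Pearson correlation of the overlapping interval
    sequences is applied to ``b``, both series are truncated to the common
    length, and (a_pairs, b_pairs, lag) is returned. Requires >= 10
    overlapping beats after alignment. Ties prefer the smaller |lag|.
    """
    xa = np.asarray(a.rr_ms, dtype=float)
    xb = np.asarray(b.rr_ms, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both RR series must be non-empty")
    best = None
    for lag in sorted(range(-max_lag, max_lag + 1), key=abs):
        if lag >= 0:
            ov_a, ov_b = xa[: xb.size - lag], xb[lag:][: xa.size]
        else:
            ov_a, ov_b = xa[-lag:][: xb.size], xb[: xa.size + lag]
        n = min(ov_a.size, ov_b.size)
        if n < 3:
            continue
        ov_a, ov_b = ov_a[:n], ov_b[:n]
        if np.std(ov_a) == 0 or np.std(ov_b) == 0:
            score = -np.mean((ov_a - ov_b) ** 2)  # fall back to shape match
        else:
            score = float(np.corrcoef(ov_a, ov_b)[0, 1])
        if best is None or score > best[0]:
            best = (score, lag, ov_a, ov_b)
    if best is None:
        raise ValueError("series too short to align")
    _, lag, ov_a, ov_b = best
    if ov_a.size < 10:
        raise ValueError(
            f"only {ov_a.size} overlapping beats after alignment; need >= 10"
        )
    logger.info("aligned RR series at lag %+d beats (%d pairs)", lag, ov_a.size)
    return ov_a, ov_b, lag


def match_rr_by_time(
    a: RRSeries, b: RRSeries, tol_s: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Pair intervals of two series that share a time base.

    An interval of ``b`` is paired with the interval of ``a`` whose closing
    beat time is nearest, provided both its closing and opening beats lie
    within ``tol_s`` of their counterparts. A dropped beat therefore
    excludes only the affected interval (its opening beat has no
    counterpart) instead of derailing all subsequent index-based pairs —
    the complement of :func:`align_rr_pairs` for sources on one clock.
    """
    ta = np.asarray(a.beat_times_s, dtype=float)
    tb = np.asarray(b.beat_times_s, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both RR series must be non-empty")
    pairs_a, pairs_b = [], []
    idx = np.searchsorted(ta, tb)
    for j, t_close in enumerate(tb):
        candidates = [i for i in (idx[j] - 1, idx[j]) if 0 <= i < ta.size]
        if not candidates:
            continue
        i = min(candidates, key=lambda i: abs(ta[i] - t_close))
        if abs(ta[i] - t_close) > tol_s:
            continue
        open_a = ta[i] - a.rr_ms[i] / 1000.0
        open_b = t_close - b.rr_ms[j] / 1000.0
        if abs(open_a - open_b) > tol_s:
            continue
        pairs_a.append(a.rr_ms[i])
        pairs_b.append(b.rr_ms[j])
    return np.asarray(pairs_a), np.asarray(pairs_b)


def linear_regression(x, y) -> RegressionReport:
    """OLS fit of paired arrays; r is the Pearson correlation, r2 = r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 3:
        raise ValueError(f"need >= 3 pairs, got {x.size}")
    if np.var(x) == 0:
        raise ValueError("x has zero variance; regression undefined")
    res = sp_stats.linregress(x, y)
    return RegressionReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue) ** 2,
        n=int(x.size),
    )


def windowed_pearson(a, b, window: int = 10) -> float:
    """Mean Pearson r over consecutive non-overlapping blocks.

    Blocks in which either signal has zero variance carry no correlation
    information and are skipped (count logged). The default block length of
    10 points follows the reference analysis; the figure-level variant used
    3-point blocks, so the length is a parameter.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("signals must have equal length")
    if window < 3:
        raise ValueError("window must be >= 3 points")
    if a.size < window:
        raise ValueError(f"signals shorter than one window ({a.size} < {window})")
    rs = []
    skipped = 0
    for start in range(0, a.size - window + 1, window):
        xa = a[start : start + window]
        xb = b[start : start + window]
        if np.std(xa) == 0 or np.std(xb) == 0:
            skipped += 1
            continue
        rs.append(float(np.corrcoef(xa, xb)[0, 1]))
    if skipped:
        logger.info("windowed_pearson skipped %d zero-variance block(s)", skipped)
    if not rs:
        raise ValueError("all blocks degenerate; no correlation defined")
    return float(np.mean(rs))


def spectrum_correlation(a: PpgRecord, b: PpgRecord, fmax_hz: float = 10.0) -> float:
    """Pearson correlation of FFT magnitude spectra up to ``fmax_hz``.

    Both records must share a sampling rate and durations within 1%; the
    shorter is zero-padded onto the common frequency grid. Magnitude spectra
    are invariant to time shifts, so this compares spectral content only.
    """
    if a.fs != b.fs:
        raise ValueError(f"sampling rates differ: {a.fs} vs {b.fs} Hz")
    na, nb = a.samples.size, b.samples.size
    if abs(na - nb) > 0.01 * max(na, nb):
        raise ValueError("record durations differ by more than 1%")
    n = max(na, nb)
    mag_a = np.abs(np.fft.rfft(a.samples - np.mean(a.samples), n=n))
    mag_b = np.abs(np.fft.rfft(b.samples - np.mean(b.samples), n=n))
    freqs = np.fft.rfftfreq(n, d=1.0 / a.fs)
    mask = freqs <= fmax_hz
    return float(sp_stats.pearsonr(mag_a[mask], mag_b[mask]).statistic)


def stft_spectrogram(
    rec: PpgRecord, win_s: float = 5.0, overlap: float = 0.5
) -> Spectrogram:
    """Hann-windowed STFT magnitude of a PPG record."""
    nperseg = int(round(win_s * rec.fs))
    if rec.samples.size < 2 * nperseg:
        raise ValueError(
            f"record of {rec.duration_s:.1f} s too short for {win_s:.1f}-s STFT windows"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    hop = max(1, nperseg - int(round(overlap * nperseg)))
    win = sp_signal.windows.hann(nperseg, sym=False)
    sft = sp_signal.ShortTimeFFT(win, hop=hop, fs=rec.fs, scale_to="magnitude")
    S = sft.stft(rec.samples - np.mean(rec.samples))
    times = rec.t0 + sft.t(rec.samples.size)
    return Spectrogram(freqs=sft.f, times=times, magnitude=np.abs(S))


def band_energy(spec: Spectrogram, lo_hz: float, hi_hz: float) -> np.ndarray:
    """Mean squared-magnitude energy in [lo_hz, hi_hz] per STFT segment."""
    mask = (spec.freqs >= lo_hz) & (spec.freqs <= hi_hz)
    if not mask.any():
        raise ValueError(f"no STFT bins inside [{lo_hz}, {hi_hz}] Hz")
    return np.mean(spec.magnitude[mask] ** 2, axis=0)
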