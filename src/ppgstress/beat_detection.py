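"""Systolic peak detection and RR-interval extraction.

After conditioning, each heartbeat appears as a dominant positive peak on a
[-1, 1] scale. A beat is a local maximum with amplitude at or above a fixed
threshold (0.5 by default) and separated from the previous beat by a
refractory period (250 ms, capping heart rate at 240 bpm) so that dicrotic
notches and noise ripples are not double-counted.

RR intervals are plain differences of integer peak sample indices converted
to milliseconds; no sub-sample interpolation is applied, so intervals are
quantized to one sample (10 ms at 100 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocessing import SignalWindow

logger = logging.getLogger(__name__)

__all__ = ["BeatSeries", "RRSeries", "detect_peaks", "peaks_to_rr", "clean_rr"]


@dataclass(frozen=True)
class BeatSeries:
    """Detected beat locations within one window."""

    peak_indices: np.ndarray
    fs: float

    def __post_init__(self):
        idx = np.asarray(self.peak_indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "peak_indices", idx)

    @property
    def peak_times_s(self) -> np.ndarray:
        return self.peak_indices / self.fs

    @property
    def n_beats(self) -> int:
        return int(self.peak_indices.size)


@dataclass(frozen=True)
class RRSeries:
    """Beat-to-beat intervals in ms with the closing beat time of each.

    ``beat_times_s[i]`` is the time of the beat that terminates interval
    ``rr_ms[i]``.
    """

    rr_ms: np.ndarray
    beat_times_s: np.ndarray
    insufficient: bool = False

    def __post_init__(self):
        rr = np.asarray(self.rr_ms, dtype=float)
        t = np.asarray(self.beat_times_s, dtype=float)
        if rr.shape != t.shape:
            raise ValueError("rr_ms and beat_times_s must have equal length")
        if np.any(rr <= 0):
            raise ValueError("RR intervals must be positive")
        object.__setattr__(self, "rr_ms", rr)
        object.__setattr__(self, "beat_times_s", t)

    def __len__(self) -> int:
        return int(self.rr_ms.size)

    @property
    def mean_rr_ms(self) -> float:
        return float(np.mean(self.rr_ms)) if len(self) else float("nan")


def detect_peaks(
    window: SignalWindow,
    threshold: float = 0.5,
    refractory_ms: float = 250.0,
) -> BeatSeries:
    """Find systolic peaks in a normalized window.

    Each peak is a local maximum with amplitude >= ``threshold`` on the
    [-1, 1] normalized scale; consecutive peaks are at least
    ``refractory_ms`` apart. An invalid window yields an empty series with a
    logged warning rather than an exception, so one bad window never aborts
    a session.
    """
    if not window.valid:
        logger.warning("peak detection on invalid window at %.1f s: no beats", window.start_s)
        return BeatSeries(np.array([], dtype=int), fs=window.fs)
    distance = max(1, int(round(refractory_ms / 1000.0 * window.fs)))
    idx, _ = signal.find_peaks(window.samples, height=threshold, distance=distance)
    return BeatSeries(idx, fs=window.fs)


def peaks_to_rr(beats: BeatSeries, fs: float | None = None) -> RRSeries:
    """Convert peak indices to RR intervals in ms.

    ``rr_ms[i] = (idx[i+1] - idx[i]) / fs * 1000``. Fewer than two peaks
    yields an empty series flagged ``insufficient``.
    """
    if fs is None:
        fs = beats.fs
    if beats.n_beats < 2:
        return RRSeries(np.array([]), np.array([]), insufficient=True)
    idx = beats.peak_indices
    rr = np.diff(idx) / fs * 1000.0
    return RRSeries(rr_ms=rr, beat_times_s=idx[1:] / fs)


def clean_rr(
    rr: RRSeries, lo_ms: float = 300.0, hi_ms: float = 2000.0
) -> RRSeries:
    """Drop intervals outside physiologic bounds.

    Defaults span 300-2000 ms (30-200 bpm); pass ``lo_ms=0`` and
    ``hi_ms=np.inf`` to disable. The removal count is logged. The reference
    pipeline applies no artifact rejection, so this step is off by default
    in the end-to-end pipeline.
    """
    if lo_ms == 0 and np.isinf(hi_ms):
        return rr
    keep = (rr.rr_ms >= lo_ms) & (rr.rr_ms <= hi_ms)
    removed = int(np.sum(~keep))
    if removed:
        logger.info("clean_rr removed %d of %d intervals outside [%g, %g] ms",
                    removed, len(rr), lo_ms, hi_ms)
    return RRSeries(rr.rr_ms[keep], rr.beat_times_s[keep], insufficient=rr.insufficient)
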