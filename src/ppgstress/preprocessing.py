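"""PPG conditioning: zero-phase high-pass filtering, normalization, windowing.

The raw optical signal carries a large DC offset (ambient light, skin tone)
and slow baseline wander (respiration, motion). Both sit below ~0.5 Hz while
the cardiac pulse lives around 1-2 Hz, so a 0.5 Hz high-pass Butterworth
filter separates them cleanly. The filter is applied forward-backward
(zero phase) so that pulse peaks are not shifted in time: the peak locations
are the quantity of interest downstream.

The cardiac pulse and its useful harmonics sit below ~10 Hz, while broadband
sensor noise extends to Nyquist; a complementary zero-phase low-pass
(10 Hz by default, disable with ``lowpass_hz=None``) removes the
out-of-band noise that would otherwise jitter integer-sample peak timing.

Analysis proceeds in fixed-length windows (30 s by default). Each window is
filtered and then normalized independently by its maximum absolute value, so
amplitudes lie in [-1, 1] and the fixed 0.5 peak-detection threshold is
meaningful regardless of sensor gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_formats import PpgRecord

logger = logging.getLogger(__name__)

__all__ = ["SignalWindow", "highpass", "lowpass", "condition", "normalize", "window_signal"]


@dataclass(frozen=True)
class SignalWindow:
    """One filtered, normalized analysis window.

    ``valid`` is False for degenerate content (e.g. an all-zero flatline),
    in which case ``samples`` holds the filtered but unnormalized data.
    """

    samples: np.ndarray
    fs: float
    start_s: float
    valid: bool = True

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def highpass(
    samples: np.ndarray, fs: float, cutoff: float = 0.5, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth high-pass filter.

    Forward-backward application (``sosfiltfilt``) doubles the effective
    order and cancels phase distortion; reflective padding suppresses the
    startup transient inside short windows. The DC component is removed
    entirely.
    """
    x = np.asarray(samples, dtype=float)
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2); got {cutoff} at fs={fs}")
    if x.size <= 3 * order:
        raise ValueError(f"input too short for order-{order} filter: {x.size} samples")
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def lowpass(
    samples: np.ndarray, fs: float, cutoff: float = 10.0, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth low-pass; removes out-of-band sensor noise."""
    x = np.asarray(samples, dtype=float)
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2); got {cutoff} at fs={fs}")
    if x.size <= 3 * order:
        raise ValueError(f"input too short for order-{order} filter: {x.size} samples")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def condition(
    samples: np.ndarray,
    fs: float,
    cutoff_hz: float = 0.5,
    lowpass_hz: float | None = 10.0,
    order: int = 2,
) -> np.ndarray:
    """High-pass (DC/wander) plus optional low-pass (broadband noise)."""
    y = highpass(samples, fs, cutoff=cutoff_hz, order=order)
    if lowpass_hz is not None:
        if lowpass_hz <= cutoff_hz:
            raise ValueError("lowpass_hz must exceed the high-pass cutoff")
        y = lowpass(y, fs, cutoff=lowpass_hz, order=order)
    return y


def normalize(samples: np.ndarray) -> np.ndarray:
    """Divide by the maximum absolute value so that max(|x|) == 1.

    Raises ``ValueError`` on an all-zero input; callers working at window
    granularity catch this and mark the window invalid instead.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty array")
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero window")
    return x / peak


def window_signal(
    rec: PpgRecord,
    window_s: float = 30.0,
    step_s: float | None = None,
    cutoff_hz: float = 0.5,
    lowpass_hz: float | None = 10.0,
    filter_order: int = 2,
) -> list[SignalWindow]:
    """Cut a record into left-aligned fixed-length windows and condition each.

    Windows start at ``t0, t0+step, ...``; a trailing partial window is
    dropped. Each window is high-pass filtered and then normalized
    independently of its neighbours, mirroring a 30-s recompute cycle in
    which every window is a self-contained unit of analysis.
    """
    if step_s is None:
        step_s = window_s
    if window_s <= 0 or step_s <= 0:
        raise ValueError("window_s and step_s must be positive")
    n_win_samples = int(round(window_s * rec.fs))
    n_step = int(round(step_s * rec.fs))
    if rec.samples.size < n_win_samples:
        raise ValueError(
            f"record duration {rec.duration_s:.2f} s is shorter than the "
            f"{window_s:.0f}-s window"
        )
    windows: list[SignalWindow] = []
    start = 0
    while start + n_win_samples <= rec.samples.size:
        chunk = rec.samples[start : start + n_win_samples]
        start_s = rec.t0 + start / rec.fs
        filtered = condition(
            chunk, rec.fs, cutoff_hz=cutoff_hz, lowpass_hz=lowpass_hz,
            order=filter_order,
        )
        try:
            conditioned = normalize(filtered)
            valid = True
        except ValueError:
            logger.warning("window at %.1f s is degenerate (all-zero); marked invalid", start_s)
            conditioned = filtered
            valid = False
        windows.append(SignalWindow(conditioned, fs=rec.fs, start_s=start_s, valid=valid))
        start += n_step
    return windows
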