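"""Synthetic RR series, PPG waveforms, labeled feature sets and sessions.

Every pipeline input can be generated here with no hardware and no external
dataset, with full seed reproducibility.

The RR model is sinusoid-plus-noise: the k-th interval is

    rr_k = mean + lf_amp*sin(2*pi*lf_freq*t_k) + hf_amp*sin(2*pi*hf_freq*t_k)
           + N(0, noise_sd)   [ms]

with cumulative beat time t advancing until the requested duration is
reached. The two sinusoids place controllable power at the LF (default
0.1 Hz, Mayer-wave range) and HF (default 0.25 Hz, respiratory range)
modulation frequencies that the spectral features must recover. This is a
direct band-power construction, not a physiological pulse-frequency
modulation model; see the methods note for what that does and does not
emulate.

PPG rendering places a gamma-shaped pulse (fast rise, slow decay) with unit
peak amplitude at each beat time, then adds DC offset, sinusoidal baseline
wander and white noise, emulating a raw fingertip recording.

Stress classes are encoded through the two most robust directions of real
stress responses: shorter mean RR and a higher LF/HF amplitude ratio with
increasing stress. All other features vary as consequences, as in real
data. Default class centres: class 0 (no stress) mean 800 ms, LF 20 ms,
HF 40 ms; class 1 (moderate) 760/35/30; class 2 (severe) 720/50/18; RR
noise 10 ms throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .beat_detection import RRSeries
from .hrv_features import FEATURE_NAMES, extract_features
from .io_formats import PpgRecord, RunConfig

logger = logging.getLogger(__name__)

__all__ = [
    "RRGenSpec",
    "ClassProfile",
    "PhasePlan",
    "PhaseAnnotation",
    "generate_rr",
    "render_ppg",
    "generate_labeled_features",
    "generate_session",
    "default_profiles",
    "default_plan",
    "dass_linked_profile",
]


@dataclass(frozen=True)
class RRGenSpec:
    """Parameters of one synthetic RR stretch."""

    duration_s: float
    mean_rr_ms: float = 800.0
    lf_amp_ms: float = 0.0
    lf_freq_hz: float = 0.1
    hf_amp_ms: float = 0.0
    hf_freq_hz: float = 0.25
    noise_sd_ms: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        # keep every drawn interval safely physiologic
        floor = self.mean_rr_ms - (
            self.lf_amp_ms + self.hf_amp_ms + 4.0 * self.noise_sd_ms
        )
        if floor <= 250.0:
            raise ValueError(
                f"spec risks non-physiologic intervals: mean - (amps + 4*sd) "
                f"= {floor:.0f} ms must exceed 250 ms"
            )


@dataclass(frozen=True)
class ClassProfile:
    """Uniform draw ranges of RR parameters for one stress class."""

    label: int
    mean_rr_range: tuple[float, float]
    lf_amp_range: tuple[float, float]
    hf_amp_range: tuple[float, float]
    noise_sd_range: tuple[float, float] = (10.0, 10.0)
    lf_freq_hz: float = 0.1
    hf_freq_hz: float = 0.25

    def draw(self, duration_s: float, rng: np.random.Generator) -> RRGenSpec:
        return RRGenSpec(
            duration_s=duration_s,
            mean_rr_ms=float(rng.uniform(*self.mean_rr_range)),
            lf_amp_ms=float(rng.uniform(*self.lf_amp_range)),
            lf_freq_hz=self.lf_freq_hz,
            hf_amp_ms=float(rng.uniform(*self.hf_amp_range)),
            hf_freq_hz=self.hf_freq_hz,
            noise_sd_ms=float(rng.uniform(*self.noise_sd_range)),
            seed=int(rng.integers(2**31)),
        )


@dataclass(frozen=True)
class PhaseAnnotation:
    name: str
    start_s: float
    end_s: float
    label: int


@dataclass(frozen=True)
class PhasePlan:
    """Ordered experiment phases: (name, duration_s, class profile)."""

    phases: tuple[tuple[str, float, ClassProfile], ...]

    def __post_init__(self):
        names = [p[0] for p in self.phases]
        if len(set(names)) != len(names):
            raise ValueError("phase names must be unique")
        if any(p[1] <= 0 for p in self.phases):
            raise ValueError("phase durations must be positive")

    @property
    def duration_s(self) -> float:
        return float(sum(p[1] for p in self.phases))


def default_profiles() -> tuple[ClassProfile, ClassProfile, ClassProfile]:
    """Class centres 800/20/40, 760/35/30, 720/50/18 ms with mild draw jitter.

    The centre ordering encodes the stress direction: mean RR falls and the
    LF/HF amplitude ratio rises from class 0 to class 2. Ranges are +/-30 ms
    on the mean and +/-10% on the modulation amplitudes.
    """
    def rng10(c):  # +/-10% relative range
        return (0.9 * c, 1.1 * c)

    return (
        ClassProfile(0, (770.0, 830.0), rng10(20.0), rng10(40.0)),
        ClassProfile(1, (730.0, 790.0), rng10(35.0), rng10(30.0)),
        ClassProfile(2, (690.0, 750.0), rng10(50.0), rng10(18.0)),
    )


def default_plan(
    rest: ClassProfile | None = None,
    stroop1: ClassProfile | None = None,
    stroop2: ClassProfile | None = None,
) -> PhasePlan:
    """The six-phase stress protocol: two 5-min Stroop blocks between rests.

    Rest 1 (300 s), Stroop 1 (300 s, moderate stress), Rest 2 (600 s),
    Stroop 2 (300 s, severe stress), Rest 3 (600 s), Relax (600 s).
    Individual phase profiles can be overridden, e.g. to tie a subject's
    baseline physiology to a questionnaire score.
    """
    p0, p1, p2 = default_profiles()
    rest = rest or p0
    stroop1 = stroop1 or p1
    stroop2 = stroop2 or p2
    return PhasePlan(
        (
            ("Rest 1", 300.0, rest),
            ("Stroop 1", 300.0, stroop1),
            ("Rest 2", 600.0, rest),
            ("Stroop 2", 300.0, stroop2),
            ("Rest 3", 600.0, rest),
            ("Relax", 600.0, rest),
        )
    )


def dass_linked_profile(dass_score: float, max_score: float = 42.0) -> ClassProfile:
    """Baseline (resting) profile tied monotonically to a DASS-21 stress score.

    The stress subscale of the DASS-21 spans 0-42 (doubled 0-21 raw). A
    higher score shifts the resting physiology toward the stressed
    direction: mean RR falls from 800 toward 740 ms and the LF:HF amplitude
    balance shifts from 20:40 toward 40:25 ms at the top of the scale.
    """
    frac = float(np.clip(dass_score / max_score, 0.0, 1.0))
    mean_c = 800.0 - 60.0 * frac
    lf_c = 20.0 + 20.0 * frac
    hf_c = 40.0 - 15.0 * frac
    return ClassProfile(
        0,
        (mean_c - 10.0, mean_c + 10.0),
        (0.95 * lf_c, 1.05 * lf_c),
        (0.95 * hf_c, 1.05 * hf_c),
    )


def generate_rr(spec: RRGenSpec) -> RRSeries:
    """Generate one RR series from the sinusoid-plus-noise model.

    Intervals accumulate while the cumulative beat time stays within
    ``duration_s``; a constant 800 ms spec over 30 s therefore yields
    floor(30000/800) = 37 intervals. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rr: list[float] = []
    times: list[float] = []
    t = 0.0
    while True:
        interval = (
            spec.mean_rr_ms
            + spec.lf_amp_ms * np.sin(2 * np.pi * spec.lf_freq_hz * t)
            + spec.hf_amp_ms * np.sin(2 * np.pi * spec.hf_freq_hz * t)
            + rng.normal(0.0, spec.noise_sd_ms)
        )
        t_next = t + interval / 1000.0
        if t_next > spec.duration_s:
            break
        rr.append(interval)
        times.append(t_next)
        t = t_next
    return RRSeries(np.asarray(rr), np.asarray(times))


def _gamma_pulse(width_s: float, fs: float, shape: float = 2.5) -> tuple[np.ndarray, int]:
    """Unit-peak gamma-shaped pulse and the sample offset of its peak."""
    theta = width_s / 6.0
    u = np.arange(0.0, width_s, 1.0 / fs)
    g = (u / theta) ** (shape - 1.0) * np.exp(-u / theta)
    g = g / g.max()
    peak_idx = int(np.argmax(g))
    return g, peak_idx


def render_ppg(
    rr: RRSeries,
    fs: float = 100.0,
    pulse_width_s: float = 0.35,
    wander_amp: float = 0.0,
    wander_freq_hz: float = 0.05,
    noise_sd: float = 0.0,
    dc_offset: float = 0.0,
    seed: int = 0,
) -> PpgRecord:
    """Render an RR series as a raw PPG waveform.

    One gamma-shaped pulse with unit peak amplitude is centred (peak) at
    each beat time; DC offset, sinusoidal baseline wander and white noise
    are added on top. Deterministic given ``seed``.
    """
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz for pulse morphology")
    if len(rr) == 0:
        raise ValueError("cannot render an empty RR series")
    if pulse_width_s * 1000.0 >= float(np.min(rr.rr_ms)):
        raise ValueError(
            f"pulse width {pulse_width_s * 1000:.0f} ms >= shortest interval "
            f"{np.min(rr.rr_ms):.0f} ms; pulses would merge"
        )
    # reconstruct the full beat list, including the beat opening interval 0
    beat_times = np.concatenate(
        ([rr.beat_times_s[0] - rr.rr_ms[0] / 1000.0], rr.beat_times_s)
    )
    template, peak_idx = _gamma_pulse(pulse_width_s, fs)
    # lead in by the pulse rise time so the first pulse sits fully inside
    beat_times = beat_times - beat_times[0] + peak_idx / fs
    n = int(np.ceil((beat_times[-1] + pulse_width_s) * fs)) + 1
    x = np.zeros(n)
    for tb in beat_times:
        start = int(round(tb * fs)) - peak_idx
        lo, hi = max(start, 0), min(start + template.size, n)
        if hi > lo:
            x[lo:hi] += template[lo - start : hi - start]
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    x = x + dc_offset + wander_amp * np.sin(2 * np.pi * wander_freq_hz * t)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)
    return PpgRecord(x, fs=fs)


def generate_labeled_features(
    profiles: tuple[ClassProfile, ...] | None = None,
    n_per_class: int = 200,
    window_s: float = 30.0,
    seed: int = 0,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Emulate a labeled 3-class HRV training table.

    For each class, RR windows are drawn from the class profile and run
    through the real feature extractor, so every one of the 34 features
    carries the class structure only through the generated physiology. A
    window that comes out invalid is redrawn (at most 10 attempts).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    profiles = profiles or default_profiles()
    cfg = cfg or RunConfig()
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    for profile in profiles:
        for _ in range(n_per_class):
            for attempt in range(10):
                spec = profile.draw(window_s, rng)
                feats = extract_features(generate_rr(spec), cfg)
                if feats.valid:
                    rows.append(feats.values)
                    labels.append(profile.label)
                    break
            else:
                raise RuntimeError(
                    f"class {profile.label} produced 10 invalid windows in a row"
                )
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    table["label"] = labels
    return table


def generate_session(
    plan: PhasePlan | None = None,
    fs: float = 100.0,
    seed: int = 0,
    ppg_noise_sd: float = 0.05,
    wander_amp: float = 0.2,
    wander_freq_hz: float = 0.05,
    dc_offset: float = 1.0,
) -> tuple[PpgRecord, list[PhaseAnnotation]]:
    """Render a full multi-phase protocol session as one PPG record.

    Each phase draws an RR spec from its class profile, renders it, and is
    trimmed/padded to exactly ``duration * fs`` samples so annotations line
    up with sample indices. Returns the concatenated record and per-phase
    annotations (name, start, end, true class).
    """
    plan = plan or default_plan()
    rng = np.random.default_rng(seed)
    chunks = []
    annotations = []
    t_cursor = 0.0
    for name, duration, profile in plan.phases:
        spec = profile.draw(duration, rng)
        rr = generate_rr(spec)
        rec = render_ppg(
            rr,
            fs=fs,
            wander_amp=wander_amp,
            wander_freq_hz=wander_freq_hz,
            noise_sd=ppg_noise_sd,
            dc_offset=dc_offset,
            seed=int(rng.integers(2**31)),
        )
        n_target = int(round(duration * fs))
        x = rec.samples
        if x.size >= n_target:
            x = x[:n_target]
        else:
            x = np.concatenate([x, np.full(n_target - x.size, dc_offset)])
        chunks.append(x)
        annotations.append(
            PhaseAnnotation(name, t_cursor, t_cursor + duration, profile.label)
        )
        t_cursor += duration
    return PpgRecord(np.concatenate(chunks), fs=fs), annotations
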