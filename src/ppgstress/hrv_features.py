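"""The 34 heart-rate-variability parameters computed per RR window.

Four families:

* 11 time-domain statistics of the RR intervals (ms): mean, median, SDNN,
  RMSSD, SDSD, SDNN/RMSSD, heart rate, pNN25, pNN50, kurtosis, skewness.
* 8 relative time-domain statistics of the unit-mean-centred intervals
  ``u_i = rr_i / mean(rr) - 1``, which remove between-subject differences in
  baseline heart rate.
* 11 frequency-domain quantities from the power spectral density of the RR
  tachogram: absolute and percentage power in the VLF (0.003-0.04 Hz),
  LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands, normalized-unit LF and HF,
  total power, LF/HF and HF/LF. LF reflects mixed sympathetic/vagal
  modulation, HF respiratory vagal modulation; their ratio is the usual
  sympathovagal balance index.
* 4 nonlinear measures: Poincare SD1/SD2, sample entropy, and Higuchi's
  fractal dimension.

Conventions (documented because HRV tooling varies): SDNN/SDSD use the
sample standard deviation (denominator n-1); kurtosis is Fisher excess
(normal -> 0); skewness/kurtosis use the biased moment estimators; the
tachogram is cubic-spline resampled at 4 Hz against cumulative beat times
before Welch estimation; total power is defined as VLF+LF+HF so band
percentages sum to 100; sample entropy excludes self-matches and uses a
strict ``< r`` Chebyshev criterion with m=2, r=0.2*SD; Higuchi is applied to
the beat-indexed RR sequence with kmax=8.

Inside a 30-s window the spectral resolution (~0.033 Hz) cannot resolve the
VLF band; VLF is integrated anyway for fidelity to the windowed pipeline and
the vector is flagged ``vlf_unresolved``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .beat_detection import RRSeries
from .io_formats import RunConfig

logger = logging.getLogger(__name__)

#: Canonical feature order; feature CSVs and model inputs use exactly this.
FEATURE_NAMES: tuple[str, ...] = (
    "mean_rr", "median_rr", "sdnn", "rmssd", "sdsd", "sdnn_rmssd", "hr",
    "pnn25", "pnn50", "kurt", "skew",
    "rel_mean_rr", "rel_median_rr", "rel_sdnn", "rel_rmssd", "rel_sdsd",
    "rel_sdnn_rmssd", "rel_kurt", "rel_skew",
    "vlf", "vlf_pct", "lf", "lf_pct", "lf_nu", "hf", "hf_pct", "hf_nu",
    "tf", "lf_hf", "hf_lf",
    "sd1", "sd2", "sampen", "higuchi",
)

__all__ = [
    "FEATURE_NAMES",
    "HrvFeatures",
    "SpectralEstimate",
    "time_domain",
    "relative_time_domain",
    "estimate_psd",
    "frequency_domain",
    "poincare",
    "sample_entropy",
    "higuchi_fd",
    "extract_features",
    "HrvFeatureExtractor",
]


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided PSD of the resampled RR tachogram (ms^2/Hz)."""

    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.psd, dtype=float)
        if f.shape != p.shape:
            raise ValueError("freqs and psd must have equal length")
        if np.any(np.diff(f) <= 0) or np.any(f < 0):
            raise ValueError("freqs must be non-negative and increasing")
        if np.any(p < -1e-12):
            raise ValueError("psd must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "psd", np.maximum(p, 0.0))


@dataclass
class HrvFeatures:
    """The 34 named parameters for one window, with validity and flags."""

    values: dict[str, float]
    valid: bool = True
    flags: tuple[str, ...] = ()

    def to_array(self) -> np.ndarray:
        return np.array([self.values[name] for name in FEATURE_NAMES], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def time_domain(rr: RRSeries | np.ndarray) -> dict[str, float]:
    """The 11 time-domain parameters.

    Requires at least 4 intervals (skewness and kurtosis are meaningless
    below that). For a constant series the dispersion statistics are 0 and
    the moment shape statistics are reported as 0; ``extract_features``
    attaches the corresponding flags.
    """
    x = np.asarray(rr.rr_ms if isinstance(rr, RRSeries) else rr, dtype=float)
    if x.size < 4:
        raise ValueError(f"need >= 4 intervals, got {x.size}")
    d = np.diff(x)
    mean_rr = float(np.mean(x))
    sdnn = _sd(x)
    rmssd = float(np.sqrt(np.mean(d**2)))
    out = {
        "mean_rr": mean_rr,
        "median_rr": float(np.median(x)),
        "sdnn": sdnn,
        "rmssd": rmssd,
        "sdsd": _sd(d),
        "sdnn_rmssd": sdnn / rmssd if rmssd > 0 else 0.0,
        "hr": 60000.0 / mean_rr,
        "pnn25": 100.0 * float(np.mean(np.abs(d) > 25.0)),
        "pnn50": 100.0 * float(np.mean(np.abs(d) > 50.0)),
    }
    if sdnn > 0:
        out["kurt"] = float(sp_stats.kurtosis(x, fisher=True, bias=True))
        out["skew"] = float(sp_stats.skew(x, bias=True))
    else:
        out["kurt"] = 0.0
        out["skew"] = 0.0
    return out


def relative_time_domain(rr: RRSeries | np.ndarray) -> dict[str, float]:
    """The 8 relative parameters, computed on ``u = rr/mean(rr) - 1``.

    The centring makes ``rel_mean_rr`` identically 0 and the remaining
    statistics scale-free, reducing between-individual variability.
    """
    x = np.asarray(rr.rr_ms if isinstance(rr, RRSeries) else rr, dtype=float)
    if x.size < 4:
        raise ValueError(f"need >= 4 intervals, got {x.size}")
    mean_rr = float(np.mean(x))
    if mean_rr <= 0:
        raise ValueError("mean RR must be positive")
    u = x / mean_rr - 1.0
    d = np.diff(u)
    rel_sdnn = _sd(u)
    rel_rmssd = float(np.sqrt(np.mean(d**2)))
    out = {
        "rel_mean_rr": float(np.mean(u)),
        "rel_median_rr": float(np.median(u)),
        "rel_sdnn": rel_sdnn,
        "rel_rmssd": rel_rmssd,
        "rel_sdsd": _sd(d),
        "rel_sdnn_rmssd": rel_sdnn / rel_rmssd if rel_rmssd > 0 else 0.0,
    }
    if rel_sdnn > 0:
        out["rel_kurt"] = float(sp_stats.kurtosis(u, fisher=True, bias=True))
        out["rel_skew"] = float(sp_stats.skew(u, bias=True))
    else:
        out["rel_kurt"] = 0.0
        out["rel_skew"] = 0.0
    return out


def estimate_psd(rr: RRSeries, resample_hz: float = 4.0) -> SpectralEstimate:
    """Welch PSD of the RR tachogram.

    The irregularly sampled tachogram (rr_ms against its cumulative beat
    times) is cubic-spline interpolated onto a uniform grid at
    ``resample_hz``, mean-removed, and fed to a Hann-windowed Welch
    estimator: a single full-length segment for short (30-s) windows, 120-s
    segments with 50% overlap for long records. The integral of the density
    over [0, Nyquist] approximates the tachogram variance.
    """
    t = np.asarray(rr.beat_times_s, dtype=float)
    x = np.asarray(rr.rr_ms, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 beats for spectral estimation")
    span = t[-1] - t[0]
    if span < 10.0:
        raise ValueError(f"series spans {span:.1f} s; need >= 10 s")
    cs = CubicSpline(t, x)
    grid = np.arange(t[0], t[-1] + 0.5 / resample_hz, 1.0 / resample_hz)
    grid = grid[grid <= t[-1]]
    y = cs(grid)
    y = y - np.mean(y)
    nperseg = min(y.size, int(round(120.0 * resample_hz)))
    freqs, psd = sp_signal.welch(
        y,
        fs=resample_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        scaling="density",
    )
    return SpectralEstimate(freqs, psd)


def band_power(spec: SpectralEstimate, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi].

    Band edges falling between grid points are included by linear
    interpolation of the density at the exact edge, so adjacent bands
    partition the integral without gap or overlap.
    """
    f, p = spec.freqs, spec.psd
    if hi <= f[0] or lo >= f[-1]:
        return 0.0
    lo = max(lo, float(f[0]))
    hi = min(hi, float(f[-1]))
    inner = (f > lo) & (f < hi)
    fs_band = np.concatenate(([lo], f[inner], [hi]))
    ps_band = np.concatenate(
        ([np.interp(lo, f, p)], p[inner], [np.interp(hi, f, p)])
    )
    return float(np.trapezoid(ps_band, fs_band))


def frequency_domain(
    spec: SpectralEstimate, cfg: RunConfig | None = None
) -> tuple[dict[str, float], tuple[str, ...]]:
    """The 11 frequency-domain parameters from a spectral estimate.

    Total power TF is defined as VLF+LF+HF (the 0.003-0.4 Hz integral), so
    the three percentage features sum to 100. Normalized units divide by
    TF - VLF: ``lf_nu = 100*lf/(tf - vlf)`` and likewise for HF, hence
    ``lf_nu + hf_nu == 100`` whenever LF+HF power is present.
    """
    cfg = cfg or RunConfig()
    if spec.freqs[-1] < cfg.hf_band[1]:
        raise ValueError(
            f"spectrum reaches only {spec.freqs[-1]:.3f} Hz; needs to cover "
            f"the HF band up to {cfg.hf_band[1]} Hz"
        )
    flags: list[str] = []
    vlf = band_power(spec, *cfg.vlf_band)
    lf = band_power(spec, *cfg.lf_band)
    hf = band_power(spec, *cfg.hf_band)
    tf = vlf + lf + hf
    out = {"vlf": vlf, "lf": lf, "hf": hf, "tf": tf}
    if tf > 0:
        out["vlf_pct"] = 100.0 * vlf / tf
        out["lf_pct"] = 100.0 * lf / tf
        out["hf_pct"] = 100.0 * hf / tf
    else:
        flags.append("zero_total_power")
        out["vlf_pct"] = out["lf_pct"] = out["hf_pct"] = 0.0
    denom = tf - vlf
    if denom > 0:
        out["lf_nu"] = 100.0 * lf / denom
        out["hf_nu"] = 100.0 * hf / denom
    else:
        out["lf_nu"] = out["hf_nu"] = 0.0
        if "zero_total_power" not in flags:
            flags.append("zero_lf_hf_power")
    out["lf_hf"] = lf / hf if hf > 0 else 0.0
    if hf == 0:
        flags.append("lf_hf_undefined")
    out["hf_lf"] = hf / lf if lf > 0 else 0.0
    if lf == 0:
        flags.append("hf_lf_undefined")
    return out, tuple(flags)


def poincare(rr: RRSeries | np.ndarray) -> tuple[float, float]:
    """Poincare descriptors (SD1, SD2) of the (rr_i, rr_{i+1}) scatter.

    SD1 is the dispersion perpendicular to the identity line
    (= SDSD / sqrt(2)); SD2 the dispersion along it,
    ``sqrt(2*SDNN^2 - SDSD^2/2)`` (clipped at 0 against round-off).
    """
    x = np.asarray(rr.rr_ms if isinstance(rr, RRSeries) else rr, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 intervals, got {x.size}")
    sdsd = _sd(np.diff(x))
    sdnn = _sd(x)
    sd1 = sdsd / np.sqrt(2.0)
    sd2_sq = 2.0 * sdnn**2 - 0.5 * sdsd**2
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    return float(sd1), sd2


def sample_entropy(
    rr: RRSeries | np.ndarray, m: int = 2, r_factor: float = 0.2
) -> float:
    """Sample entropy of the RR sequence, in nats.

    SampEn = -ln(A/B) where B counts ordered template pairs (i != j) whose
    length-``m`` embeddings are within Chebyshev distance strictly less than
    ``r = r_factor * sample SD``, and A counts the same at length m+1. Both
    counts run over the same n-m templates (the Richman-Moorman
    construction). A == 0 yields +inf; a zero-variance series raises.
    """
    x = np.asarray(rr.rr_ms if isinstance(rr, RRSeries) else rr, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"need >= m+2 = {m + 2} intervals, got {n}")
    sd = _sd(x)
    if sd == 0:
        raise ValueError("sample entropy undefined for a zero-variance series")
    r = r_factor * sd

    def _count(length: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, length)[: n - m]
        dist = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        return int(np.sum(dist < r)) - (n - m)  # drop self-matches

    b = _count(m)
    if b == 0:
        return float("inf")
    a = _count(m + 1)
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def higuchi_fd(rr: RRSeries | np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension of the beat-indexed RR sequence.

    For each coarse-graining factor k the mean curve length L(k), averaged
    over the k possible offsets, scales as k^-FD; FD is the negative slope
    of the least-squares fit of ln L(k) on ln k. A smooth curve gives
    FD -> 1, uncorrelated noise FD -> 2. A series shorter than 2*kmax
    reduces kmax to floor(n/2) with a warning.
    """
    x = np.asarray(rr.rr_ms if isinstance(rr, RRSeries) else rr, dtype=float)
    n = x.size
    if n < 2 * kmax:
        new_kmax = max(2, n // 2)
        warnings.warn(
            f"series of length {n} too short for kmax={kmax}; using {new_kmax}",
            stacklevel=2,
        )
        kmax = new_kmax
    lk = []
    ks = []
    for k in range(1, kmax + 1):
        lengths = []
        for m0 in range(k):
            pts = x[m0::k]
            n_seg = pts.size - 1
            if n_seg < 1:
                continue
            curve = np.sum(np.abs(np.diff(pts))) * (n - 1) / (n_seg * k) / k
            lengths.append(curve)
        if lengths:
            lk.append(np.mean(lengths))
            ks.append(k)
    lk = np.asarray(lk)
    ks = np.asarray(ks, dtype=float)
    if np.any(lk <= 0):
        raise ValueError("degenerate curve lengths; fractal dimension undefined")
    slope = np.polyfit(np.log(ks), np.log(lk), 1)[0]
    return float(-slope)


def extract_features(rr: RRSeries, cfg: RunConfig | None = None) -> HrvFeatures:
    """Compute all 34 parameters for one window.

    A window needs at least 10 beats (9 intervals); otherwise it is returned
    invalid with no values rather than as a NaN-filled row. Degenerate
    sub-computations (constant series, zero band power) set their features
    to 0 and attach flags instead of propagating NaN.
    """
    cfg = cfg or RunConfig()
    n_beats = len(rr) + 1 if len(rr) else 0
    if rr.insufficient or n_beats < 10:
        return HrvFeatures(values={}, valid=False, flags=("too_few_beats",))
    flags: list[str] = []
    values = time_domain(rr)
    values.update(relative_time_domain(rr))
    if values["sdnn"] == 0:
        flags.append("constant_series")
    if values["rmssd"] == 0 and "constant_series" not in flags:
        flags.append("zero_rmssd")

    try:
        spec = estimate_psd(rr, resample_hz=cfg.resample_hz)
    except ValueError as exc:
        logger.warning("spectral estimation failed: %s", exc)
        return HrvFeatures(values={}, valid=False, flags=("spectral_failure",))
    fd_values, fd_flags = frequency_domain(spec, cfg)
    values.update(fd_values)
    flags.extend(fd_flags)
    span = rr.beat_times_s[-1] - rr.beat_times_s[0]
    if span < 1.0 / cfg.vlf_band[0]:  # shorter than one cycle at the VLF floor
        flags.append("vlf_unresolved")

    sd1, sd2 = poincare(rr)
    values["sd1"], values["sd2"] = sd1, sd2
    try:
        se = sample_entropy(rr, m=cfg.sampen_m, r_factor=cfg.sampen_r_factor)
        if not np.isfinite(se):
            flags.append("sampen_no_matches")
            se = 0.0
    except ValueError:
        flags.append("sampen_undefined")
        se = 0.0
    values["sampen"] = se
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values["higuchi"] = higuchi_fd(rr, kmax=cfg.higuchi_kmax)
    except ValueError:
        flags.append("higuchi_undefined")
        values["higuchi"] = 1.0
    ordered = {name: float(values[name]) for name in FEATURE_NAMES}
    return HrvFeatures(values=ordered, valid=True, flags=tuple(flags))


class HrvFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping RR series to the 34-feature matrix.

    ``transform`` accepts a sequence of :class:`RRSeries` and returns a
    DataFrame with one canonical-order row per valid series; invalid series
    (too few beats) are dropped and their positions logged. The class exists
    so feature extraction composes with scikit-learn pipelines; all
    behaviour is parameterized by the same constants as
    :func:`extract_features`.
    """

    def __init__(
        self,
        resample_hz: float = 4.0,
        sampen_m: int = 2,
        sampen_r_factor: float = 0.2,
        higuchi_kmax: int = 8,
    ):
        self.resample_hz = resample_hz
        self.sampen_m = sampen_m
        self.sampen_r_factor = sampen_r_factor
        self.higuchi_kmax = higuchi_kmax

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X):
        import pandas as pd

        cfg = RunConfig(
            resample_hz=self.resample_hz,
            sampen_m=self.sampen_m,
            sampen_r_factor=self.sampen_r_factor,
            higuchi_kmax=self.higuchi_kmax,
        )
        rows = []
        for i, rr in enumerate(X):
            feats = extract_features(rr, cfg)
            if feats.valid:
                rows.append(feats.values)
            else:
                logger.info("dropping invalid RR series at position %d (%s)", i, feats.flags)
        return pd.DataFrame(rows, columns=list(FEATURE_NAMES))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
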