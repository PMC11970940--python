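"""File formats and run configuration.

All interchange formats are plain CSV with ``.`` decimals:

* PPG: one numeric column (amplitude, arbitrary ADC units) or two columns
  (time in seconds, amplitude). An optional single header line is tolerated.
* RR: one column of beat-to-beat intervals in milliseconds.
* Feature tables: the 34 canonical HRV column names (see
  :data:`ppgstress.hrv_features.FEATURE_NAMES`), optionally followed by a
  ``label`` column with values in {0, 1, 2}; the header row is mandatory.

The run configuration collects every pipeline constant (30-s windows, 0.5 Hz
high-pass cutoff, 0.5 peak threshold, 100 Hz sampling, spectral band edges,
entropy/fractal settings and tree hyperparameters) in one validated object.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParseError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "PpgRecord",
    "RunConfig",
    "read_ppg_csv",
    "write_ppg_csv",
    "read_rr_csv",
    "write_rr_csv",
    "read_feature_csv",
    "write_feature_csv",
    "load_config",
]


@dataclass(frozen=True)
class PpgRecord:
    """Uniformly sampled PPG amplitudes.

    Parameters
    ----------
    samples : ndarray
        Raw amplitudes in arbitrary ADC units; must be finite and non-empty.
    fs : float
        Sampling rate in Hz (> 0). The reference hardware streams at 100 Hz.
    t0 : float
        Start time of the record in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class RunConfig:
    """Pipeline constants with the reference-system defaults."""

    window_s: float = 30.0
    step_s: float = 30.0
    cutoff_hz: float = 0.5
    lowpass_hz: float | None = 10.0
    filter_order: int = 2
    peak_threshold: float = 0.5
    refractory_ms: float = 250.0
    fs: float = 100.0
    vlf_band: tuple[float, float] = (0.003, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.4)
    resample_hz: float = 4.0
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    higuchi_kmax: int = 8
    max_depth: int = 10
    min_samples_split: int = 10
    min_samples_leaf: int = 5
    split_criterion: str = "gini"
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.window_s > 0:
            raise ConfigError("window_s must be > 0")
        if not self.step_s > 0:
            raise ConfigError("step_s must be > 0")
        if not self.fs > 0:
            raise ConfigError("fs must be > 0")
        if not 0 < self.cutoff_hz < self.fs / 2:
            raise ConfigError(
                f"cutoff_hz must satisfy 0 < cutoff < fs/2 "
                f"(got cutoff={self.cutoff_hz}, fs={self.fs})"
            )
        if self.lowpass_hz is not None and not (
            self.cutoff_hz < self.lowpass_hz < self.fs / 2
        ):
            raise ConfigError(
                f"lowpass_hz must satisfy cutoff < lowpass < fs/2 "
                f"(got {self.lowpass_hz})"
            )
        edges = [*self.vlf_band, *self.lf_band, *self.hf_band]
        lo = (self.vlf_band[0], self.lf_band[0], self.hf_band[0])
        hi = (self.vlf_band[1], self.lf_band[1], self.hf_band[1])
        ok = all(a < b for a, b in zip(lo, hi)) and (
            self.vlf_band[1] <= self.lf_band[0] and self.lf_band[1] <= self.hf_band[0]
        )
        if not ok:
            raise ConfigError(f"band edges must be strictly increasing, got {edges}")
        if not self.resample_hz > 2 * self.hf_band[1]:
            raise ConfigError("resample_hz must exceed twice the HF upper edge")
        if self.sampen_m < 1:
            raise ConfigError("sampen_m must be >= 1")
        if not self.sampen_r_factor > 0:
            raise ConfigError("sampen_r_factor must be > 0")
        if self.higuchi_kmax < 2:
            raise ConfigError("higuchi_kmax must be >= 2")
        if self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1")
        if self.min_samples_split < 2:
            raise ConfigError("min_samples_split must be >= 2")
        if self.min_samples_leaf < 1:
            raise ConfigError("min_samples_leaf must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config file; unspecified keys take the pipeline defaults.

    Unknown keys and out-of-range values raise :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    for band in ("vlf_band", "lf_band", "hf_band"):
        if band in raw:
            val = raw[band]
            if not (isinstance(val, (list, tuple)) and len(val) == 2):
                raise ConfigError(f"{band} must be a [lo, hi] pair")
            raw[band] = (float(val[0]), float(val[1]))
    return RunConfig(**raw)


def _numeric_frame(path: Path, n_cols_allowed: tuple[int, ...]) -> tuple[pd.DataFrame, int]:
    """Parse a small CSV into a numeric frame; returns (frame, header_offset)."""
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    offset = 1  # CSV lines are reported 1-based
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().all() and df.iloc[0].notna().all():
        df = df.iloc[1:].reset_index(drop=True)
        offset = 2
        if df.empty:
            raise ParseError(f"{path}: no data rows after header")
    if df.shape[1] not in n_cols_allowed:
        raise ParseError(
            f"{path}: expected {n_cols_allowed} column(s), found {df.shape[1]}"
        )
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + offset
        raise ParseError(f"{path}: non-numeric or missing value at line {line}")
    return num.astype(float), offset


def read_ppg_csv(path: str | Path, fs: float | None = None) -> PpgRecord:
    """Read a PPG CSV (amplitude column, or time + amplitude columns).

    When a time column is present, ``fs`` is inferred from the median sample
    spacing and the spacing is required to be regular to within 1%. With a
    single column, ``fs`` must be supplied.
    """
    path = Path(path)
    num, _ = _numeric_frame(path, (1, 2))
    if num.shape[1] == 1:
        if fs is None:
            raise ParseError(f"{path}: single-column PPG file requires an explicit fs")
        return PpgRecord(num.iloc[:, 0].to_numpy(), fs=fs)
    t = num.iloc[:, 0].to_numpy()
    amp = num.iloc[:, 1].to_numpy()
    if t.size < 2:
        raise ParseError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise ParseError(f"{path}: time column must be strictly increasing")
    if np.max(np.abs(dt - med)) > 0.01 * med:
        raise ParseError(f"{path}: irregular sampling (jitter above 1% of {med:g} s)")
    fs_inferred = 1.0 / med
    if fs is not None and abs(fs - fs_inferred) > 0.01 * fs_inferred:
        raise ParseError(
            f"{path}: supplied fs={fs} disagrees with inferred {fs_inferred:g} Hz"
        )
    return PpgRecord(amp, fs=fs_inferred, t0=float(t[0]))


def write_ppg_csv(rec: PpgRecord, path: str | Path, include_time: bool = False) -> None:
    """Write a PPG record; with ``include_time`` a leading seconds column."""
    path = Path(path)
    if include_time:
        df = pd.DataFrame({"t": rec.times, "amp": rec.samples})
    else:
        df = pd.DataFrame({"amp": rec.samples})
    df.to_csv(path, index=False, header=False)


def read_rr_csv(path: str | Path):
    """Read a one-column RR CSV (ms) into an :class:`RRSeries`."""
    from .beat_detection import RRSeries

    num, _ = _numeric_frame(Path(path), (1,))
    rr = num.iloc[:, 0].to_numpy()
    if np.any(rr <= 0):
        raise ParseError(f"{path}: RR intervals must be positive")
    return RRSeries(rr_ms=rr, beat_times_s=np.cumsum(rr) / 1000.0)


def write_rr_csv(rr, path: str | Path) -> None:
    """Write RR intervals, one per line, in milliseconds."""
    np.savetxt(Path(path), np.asarray(rr.rr_ms, dtype=float), fmt="%.6f")


def _feature_names() -> list[str]:
    from .hrv_features import FEATURE_NAMES

    return list(FEATURE_NAMES)


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table in the canonical 34-column order (+ label)."""
    names = _feature_names()
    cols = list(table.columns)
    extra = sorted(set(cols) - set(names) - {"label"})
    missing = sorted(set(names) - set(cols))
    if missing or extra:
        raise SchemaError(
            f"feature table schema mismatch: missing={missing}, unexpected={extra}"
        )
    order = names + (["label"] if "label" in cols else [])
    table[order].to_csv(Path(path), index=False, float_format="%.17g")


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Read a canonical feature CSV; validates the 34-name schema strictly."""
    path = Path(path)
    df = pd.read_csv(path)
    names = _feature_names()
    cols = list(df.columns)
    missing = sorted(set(names) - set(cols))
    extra = sorted(set(cols) - set(names) - {"label"})
    if missing or extra:
        raise SchemaError(
            f"{path}: feature table schema mismatch: missing={missing}, "
            f"unexpected={extra}"
        )
    num = df[names].apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        bad = num.isna().any(axis=1)
        raise ParseError(f"{path}: non-numeric feature value at data row {int(bad.idxmax())}")
    out = num.copy()
    if "label" in cols:
        lab = pd.to_numeric(df["label"], errors="coerce")
        if lab.isna().any() or not lab.isin([0, 1, 2]).all():
            raise SchemaError(f"{path}: labels must be integers in {{0, 1, 2}}")
        out["label"] = lab.astype(int)
    return out
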