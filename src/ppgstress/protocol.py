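"""End-to-end session scoring and protocol-level statistics.

``run_pipeline`` applies the full chain — window, filter, normalize, detect
beats, RR, 34 features, tree prediction — to every 30-s window of a session
record. Window failures (flatline, too few beats) are carried as invalid
results; one bad window never aborts a session.

Phase scoring sums the per-window stress labels inside each named
experiment phase, both as a raw sum and normalized by the window count
(so the normalized score lives on the same 0-2 scale as a single label).
Questionnaire regressions correlate per-subject phase-score sums against
DASS-21 stress scores; adjacent-phase comparisons use the paired Wilcoxon
signed-rank test by default (HRV quantities are skewed; a paired t-test is
available), with no multiple-testing correction by default and an optional
Holm adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .beat_detection import RRSeries, detect_peaks, peaks_to_rr
from .device_validation import RegressionReport, linear_regression
from .hrv_features import HrvFeatures, extract_features
from .io_formats import PpgRecord, RunConfig
from .preprocessing import window_signal
from .stress_model import StressTreeClassifier
from .synthetic_data import PhaseAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "WindowResult",
    "PhaseScore",
    "PhaseComparison",
    "ppg_to_rr",
    "run_pipeline",
    "phase_scores",
    "dass_regression",
    "phase_comparison",
    "PHASE_SUBSETS",
]

#: Named phase subsets used by the questionnaire regressions.
PHASE_SUBSETS: dict[str, tuple[str, ...]] = {
    "all": ("Rest 1", "Stroop 1", "Rest 2", "Stroop 2", "Rest 3", "Relax"),
    "rest1": ("Rest 1",),
    "stroop": ("Stroop 1", "Stroop 2"),
    "recovery": ("Rest 2", "Rest 3"),
    "relax": ("Relax",),
}


@dataclass(frozen=True)
class WindowResult:
    """Outcome of one 30-s window: features and predicted stress label."""

    start_s: float
    features: HrvFeatures
    label: int | None
    valid: bool


@dataclass(frozen=True)
class PhaseScore:
    """Aggregated stress labels within one protocol phase."""

    phase: str
    sum_score: int
    n_windows: int

    @property
    def normalized_score(self) -> float:
        return self.sum_score / self.n_windows if self.n_windows else float("nan")


@dataclass(frozen=True)
class PhaseComparison:
    """Paired test between two adjacent phases."""

    phase_a: str
    phase_b: str
    statistic: float
    p_value: float
    significant: bool
    method: str


def ppg_to_rr(rec: PpgRecord, cfg: RunConfig | None = None) -> RRSeries:
    """Detect beats over a whole record through the windowed pipeline.

    Each window is conditioned and normalized independently (so a noise
    excursion in one stretch cannot depress the detection threshold
    elsewhere) and the per-window RR series are concatenated on the
    record's time base. No interval spans a window boundary.
    """
    cfg = cfg or RunConfig()
    rr_all: list[np.ndarray] = []
    t_all: list[np.ndarray] = []
    for window in window_signal(
        rec,
        window_s=cfg.window_s,
        step_s=cfg.step_s,
        cutoff_hz=cfg.cutoff_hz,
        lowpass_hz=cfg.lowpass_hz,
        filter_order=cfg.filter_order,
    ):
        if not window.valid:
            continue
        beats = detect_peaks(
            window, threshold=cfg.peak_threshold, refractory_ms=cfg.refractory_ms
        )
        rr = peaks_to_rr(beats)
        if len(rr):
            rr_all.append(rr.rr_ms)
            t_all.append(rr.beat_times_s + window.start_s)
    if not rr_all:
        return RRSeries(np.array([]), np.array([]), insufficient=True)
    return RRSeries(np.concatenate(rr_all), np.concatenate(t_all))


def run_pipeline(
    rec: PpgRecord, model: StressTreeClassifier, cfg: RunConfig | None = None
) -> list[WindowResult]:
    """Score every window of a PPG record with the fitted stress model."""
    cfg = cfg or RunConfig()
    results: list[WindowResult] = []
    for window in window_signal(
        rec,
        window_s=cfg.window_s,
        step_s=cfg.step_s,
        cutoff_hz=cfg.cutoff_hz,
        lowpass_hz=cfg.lowpass_hz,
        filter_order=cfg.filter_order,
    ):
        feats = HrvFeatures(values={}, valid=False, flags=("window_invalid",))
        label = None
        if window.valid:
            beats = detect_peaks(
                window, threshold=cfg.peak_threshold, refractory_ms=cfg.refractory_ms
            )
            rr = peaks_to_rr(beats)
            feats = extract_features(rr, cfg)
            if feats.valid:
                label = int(model.predict(feats.to_array().reshape(1, -1))[0])
        if label is None:
            logger.info(
                "window at %.0f s invalid (%s); carried without a label",
                window.start_s,
                ",".join(feats.flags),
            )
        results.append(
            WindowResult(window.start_s, feats, label, valid=label is not None)
        )
    return results


def phase_scores(
    results: list[WindowResult], annotations: list[PhaseAnnotation]
) -> list[PhaseScore]:
    """Sum per-window labels within each phase, in protocol order.

    A window belongs to the phase containing its start time; invalid
    windows do not contribute to either the sum or the window count.
    Windows outside every phase are excluded with a warning.
    """
    scores = []
    assigned = 0
    for ann in annotations:
        in_phase = [
            r for r in results if ann.start_s <= r.start_s < ann.end_s and r.valid
        ]
        assigned += sum(
            1 for r in results if ann.start_s <= r.start_s < ann.end_s
        )
        scores.append(
            PhaseScore(
                phase=ann.name,
                sum_score=int(sum(r.label for r in in_phase)),
                n_windows=len(in_phase),
            )
        )
    stray = len(results) - assigned
    if stray:
        logger.warning("%d window(s) fall outside all annotated phases; excluded", stray)
    return scores


def dass_regression(
    dass_stress: dict[str, float],
    phase_scores_by_subject: dict[str, list[PhaseScore]],
    phase_subset: str | tuple[str, ...] = "all",
) -> RegressionReport:
    """OLS of per-subject summed phase scores on DASS-21 stress scores.

    ``phase_subset`` is a named preset ("all", "rest1", "stroop",
    "recovery", "relax") or an explicit tuple of phase names; raw sums (not
    normalized scores) are regressed, matching the use of total stress
    values per phase group.
    """
    if isinstance(phase_subset, str):
        try:
            subset = PHASE_SUBSETS[phase_subset]
        except KeyError:
            raise ValueError(
                f"unknown phase subset {phase_subset!r}; "
                f"options: {sorted(PHASE_SUBSETS)}"
            ) from None
    else:
        subset = tuple(phase_subset)
    if set(dass_stress) != set(phase_scores_by_subject):
        raise ValueError(
            "subject ids of DASS scores and phase scores do not match: "
            f"{sorted(set(dass_stress) ^ set(phase_scores_by_subject))}"
        )
    subjects = sorted(dass_stress)
    x = np.array([dass_stress[s] for s in subjects], dtype=float)
    y = []
    for s in subjects:
        names = {ps.phase for ps in phase_scores_by_subject[s]}
        missing = set(subset) - names
        if missing:
            raise ValueError(f"subject {s} lacks phase(s) {sorted(missing)}")
        y.append(
            sum(ps.sum_score for ps in phase_scores_by_subject[s] if ps.phase in subset)
        )
    return linear_regression(x, np.asarray(y, dtype=float))


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    d = b - a
    if np.all(d == 0):
        return 0.0, 1.0, "wilcoxon (all differences zero)"
    method = "exact" if d.size < 6 else "auto"
    res = sp_stats.wilcoxon(a, b, alternative="two-sided", method=method)
    label = "wilcoxon-exact" if method == "exact" else "wilcoxon"
    return float(res.statistic), float(res.pvalue), label


def phase_comparison(
    values_by_phase: dict[str, np.ndarray],
    test: str = "wilcoxon",
    alpha: float = 0.05,
    holm: bool = False,
) -> list[PhaseComparison]:
    """Paired tests between each adjacent pair of phases.

    ``values_by_phase`` maps phase name to one value per subject (phase
    order follows dict insertion order). Default test is the paired
    two-sided Wilcoxon signed-rank; ``test="ttest"`` switches to a paired
    t-test. Fewer than 6 pairs forces the exact Wilcoxon distribution,
    noted in the method string. ``holm=True`` applies a Holm step-down
    correction before flagging significance (off by default).
    """
    names = list(values_by_phase)
    if len(names) < 2:
        raise ValueError("need at least two phases to compare")
    arrays = {n: np.asarray(v, dtype=float) for n, v in values_by_phase.items()}
    n_subj = {a.size for a in arrays.values()}
    if len(n_subj) != 1:
        raise ValueError("all phases must have one value per subject")
    if n_subj.pop() < 2:
        raise ValueError("need at least 2 subjects")
    raw = []
    for a_name, b_name in zip(names[:-1], names[1:]):
        a, b = arrays[a_name], arrays[b_name]
        if test == "wilcoxon":
            stat, p, method = _paired_wilcoxon(a, b)
        elif test == "ttest":
            res = sp_stats.ttest_rel(a, b)
            stat, p, method = float(res.statistic), float(res.pvalue), "paired-t"
        else:
            raise ValueError(f"unknown test {test!r}")
        raw.append((a_name, b_name, stat, p, method))
    significant = [p < alpha for (_, _, _, p, _) in raw]
    if holm:
        order = np.argsort([r[3] for r in raw])
        m = len(raw)
        significant = [False] * m
        for rank, idx in enumerate(order):
            if raw[idx][3] < alpha / (m - rank):
                significant[idx] = True
            else:
                break  # step-down stops at the first non-rejection
    return [
        PhaseComparison(a, b, stat, p, significant=sig, method=method)
        for (a, b, stat, p, method), sig in zip(raw, significant)
    ]
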