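import numpy as np
import pytest

import ppgstress as ps
from ppgstress.hrv_features import HrvFeatures
from ppgstress.protocol import (
    PhaseScore,
    WindowResult,
    dass_regression,
    phase_comparison,
    phase_scores,
    run_pipeline,
)
from ppgstress.synthetic_data import PhaseAnnotation


def _window_results(labels, step_s=30.0):
    """WindowResults with the given labels (None = invalid window)."""
    out = []
    for i, label in enumerate(labels):
        valid = label is not None
        feats = HrvFeatures(values={}, valid=valid)
        out.append(WindowResult(i * step_s, feats, label, valid=valid))
    return out


class TestRunPipeline:
    def test_session_window_bookkeeping(self, trained_model):
        rec, _ = ps.generate_session(seed=21)
        results = run_pipeline(rec, trained_model)
        assert len(results) == 90
        starts = [r.start_s for r in results]
        assert starts == sorted(starts)

    def test_flatline_window_isolated(self, trained_model):
        rec, _ = ps.generate_session(seed=22)
        samples = rec.samples.copy()
        samples[3000:6000] = 0.0  # flatline the second 30-s window
        results = run_pipeline(ps.PpgRecord(samples, fs=rec.fs), trained_model)
        assert not results[1].valid
        assert results[0].valid and results[2].valid

    def test_rest_only_session_mostly_class_zero(self, trained_model):
        p0 = ps.default_profiles()[0]
        plan = ps.synthetic_data.PhasePlan((("Rest only", 900.0, p0),))
        rec, _ = ps.generate_session(plan=plan, seed=23)
        results = run_pipeline(rec, trained_model)
        labels = [r.label for r in results if r.valid]
        assert len(labels) >= 25
        assert np.mean(np.asarray(labels) == 0) >= 0.8


class TestPpgToRr:
    def test_windowed_detection_recovers_generator(self):
        spec = ps.RRGenSpec(duration_s=90.0, mean_rr_ms=800.0, lf_amp_ms=20.0,
                            hf_amp_ms=40.0, noise_sd_ms=10.0, seed=8)
        rr_true = ps.generate_rr(spec)
        rec = ps.render_ppg(rr_true, fs=100.0, noise_sd=0.05, wander_amp=0.2,
                            dc_offset=1.0, seed=9)
        rr_det = ps.ppg_to_rr(rec)
        assert abs(rr_det.mean_rr_ms - rr_true.mean_rr_ms) <= 10.0
        # intervals never span a 30-s window boundary
        opens = rr_det.beat_times_s - rr_det.rr_ms / 1000.0
        assert np.all(np.floor(opens / 30.0) == np.floor(rr_det.beat_times_s / 30.0 - 1e-9))

    def test_empty_on_flatline(self):
        rec = ps.PpgRecord(np.zeros(6000), fs=100.0)
        rr = ps.ppg_to_rr(rec)
        assert rr.insufficient
        assert len(rr) == 0


class TestPhaseScores:
    def _annotations(self):
        return [
            PhaseAnnotation("A", 0.0, 300.0, 0),
            PhaseAnnotation("B", 300.0, 600.0, 1),
        ]

    def test_all_zero_labels_floor(self):
        results = _window_results([0] * 10 + [0] * 10)
        scores = phase_scores(results, self._annotations())
        assert scores[0] == PhaseScore("A", 0, 10)
        assert scores[0].normalized_score == 0.0

    def test_all_two_labels_ceiling(self):
        results = _window_results([2] * 10 + [2] * 10)
        scores = phase_scores(results, self._annotations())
        assert scores[1].sum_score == 20
        assert scores[1].normalized_score == 2.0

    def test_invalid_windows_excluded_from_count(self):
        results = _window_results([1, None, 1, None] + [0] * 6 + [2] * 10)
        scores = phase_scores(results, self._annotations())
        assert scores[0].n_windows == 8
        assert scores[0].sum_score == 2

    def test_windows_outside_phases_warned(self, caplog):
        results = _window_results([0] * 25)  # 750 s of windows, 600 s annotated
        with caplog.at_level("WARNING"):
            scores = phase_scores(results, self._annotations())
        assert sum(s.n_windows for s in scores) == 20
        assert any("outside" in r.message for r in caplog.records)


class TestDassRegression:
    def _scores(self, subjects, factor=2.0):
        by_subject = {}
        for s, dass in subjects.items():
            by_subject[s] = [
                PhaseScore("Rest 1", int(factor * dass), 10),
                PhaseScore("Stroop 1", 5, 10),
            ]
        return by_subject

    def test_exact_linear_relation(self):
        dass = {f"s{i}": float(i) for i in range(10)}
        rep = dass_regression(dass, self._scores(dass), phase_subset="rest1")
        assert rep.r == pytest.approx(1.0)
        assert rep.slope == pytest.approx(2.0)

    def test_subset_sum_includes_named_phases_only(self):
        dass = {f"s{i}": float(i) for i in range(5)}
        rep = dass_regression(
            dass, self._scores(dass), phase_subset=("Rest 1", "Stroop 1")
        )
        # y = 2*dass + 5 -> slope still 2, intercept 5
        assert rep.slope == pytest.approx(2.0)
        assert rep.intercept == pytest.approx(5.0)

    def test_permuted_scores_rarely_significant(self):
        rng = np.random.default_rng(0)
        n = 10
        dass = {f"s{i}": float(i) for i in range(n)}
        crit = 0.632  # 5% two-sided critical |r| for n = 10
        hits = 0
        reps = 400
        for _ in range(reps):
            perm = rng.permutation(n).astype(float)
            scores = {
                f"s{i}": [PhaseScore("Rest 1", int(10 * perm[i]), 10)]
                for i in range(n)
            }
            rep = dass_regression(dass, scores, phase_subset="rest1")
            if abs(rep.r) > crit:
                hits += 1
        assert hits / reps < 0.12

    def test_mismatched_subjects_rejected(self):
        dass = {"a": 1.0, "b": 2.0, "c": 3.0}
        scores = self._scores({"a": 1.0, "b": 2.0, "d": 4.0})
        with pytest.raises(ValueError, match="match"):
            dass_regression(dass, scores)

    def test_unknown_subset_rejected(self):
        dass = {f"s{i}": float(i) for i in range(5)}
        with pytest.raises(ValueError, match="subset"):
            dass_regression(dass, self._scores(dass), phase_subset="bogus")


class TestPhaseComparison:
    def test_identical_phases_p_one(self):
        values = {"A": np.arange(10.0), "B": np.arange(10.0)}
        (cmp,) = phase_comparison(values)
        assert cmp.p_value == 1.0
        assert not cmp.significant

    def test_constant_shift_minimal_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 12)
        values = {"A": a, "B": a + 3.0}
        (cmp,) = phase_comparison(values)
        # two-sided exact Wilcoxon floor at n=12 is 2/2^12
        assert cmp.p_value == pytest.approx(2.0 / 2**12, rel=1e-6)
        assert cmp.significant

    def test_small_n_uses_exact_method(self):
        values = {"A": np.array([1.0, 2, 3, 4]), "B": np.array([2.0, 3, 4, 6])}
        (cmp,) = phase_comparison(values)
        assert "exact" in cmp.method

    def test_adjacent_pairs_in_order(self):
        rng = np.random.default_rng(2)
        values = {k: rng.normal(size=8) for k in ("R1", "S1", "R2")}
        comps = phase_comparison(values)
        assert [(c.phase_a, c.phase_b) for c in comps] == [("R1", "S1"), ("S1", "R2")]

    def test_ttest_variant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 15)
        b = a + 1.0 + rng.normal(0, 0.1, 15)
        comps = phase_comparison({"A": a, "B": b}, test="ttest")
        assert comps[0].method == "paired-t"
        assert comps[0].significant

    def test_holm_correction_reduces_rejections(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 8)
        values = {
            "A": base,
            "B": base + rng.normal(0, 0.4, 8),
            "C": base + rng.normal(0, 0.4, 8),
            "D": base + 5.0,
        }
        raw = phase_comparison(values, holm=False)
        adj = phase_comparison(values, holm=True)
        assert sum(c.significant for c in adj) <= sum(c.significant for c in raw)


class TestEndToEndDirection:
    def test_stroop_scores_exceed_rest(self, trained_model):
        """Group-mean normalized score: Stroop 2 > Stroop 1 > rest phases."""
        by_phase: dict[str, list[float]] = {}
        for subject in range(6):
            rec, ann = ps.generate_session(seed=1000 + subject)
            scores = phase_scores(run_pipeline(rec, trained_model), ann)
            for s in scores:
                by_phase.setdefault(s.phase, []).append(s.normalized_score)
        means = {k: np.mean(v) for k, v in by_phase.items()}
        rest_mean = np.mean([means["Rest 1"], means["Rest 2"], means["Rest 3"]])
        assert means["Stroop 2"] > means["Stroop 1"] > rest_mean
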