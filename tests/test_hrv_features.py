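import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles as orc
import ppgstress as ps
from ppgstress.hrv_features import (
    FEATURE_NAMES,
    HrvFeatureExtractor,
    estimate_psd,
    extract_features,
    frequency_domain,
    higuchi_fd,
    poincare,
    relative_time_domain,
    sample_entropy,
    time_domain,
)
from ppgstress.io_formats import RunConfig


def _series(rr):
    rr = np.asarray(rr, dtype=float)
    return ps.RRSeries(rr, np.cumsum(rr) / 1000.0)


def _random_series(seed, n_lo=40, n_hi=80):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi))
    rr = 800.0 + rng.uniform(-120.0, 120.0, size=n)
    return _series(rr)


class TestTimeDomain:
    def test_constant_series(self):
        td = time_domain(_series([800.0] * 4))
        assert td["mean_rr"] == 800.0
        assert td["sdnn"] == 0.0
        assert td["rmssd"] == 0.0
        assert td["hr"] == pytest.approx(75.0)
        assert td["pnn50"] == 0.0

    def test_hand_arithmetic(self):
        td = time_domain(_series([800.0, 850.0, 780.0, 820.0]))
        assert td["rmssd"] == pytest.approx(np.sqrt((50**2 + 70**2 + 40**2) / 3))
        assert td["pnn25"] == 100.0

    def test_hr_mean_rr_identity(self, random_rr):
        td = time_domain(random_rr)
        assert td["hr"] * td["mean_rr"] == pytest.approx(60000.0, rel=1e-12)

    def test_pnn25_dominates_pnn50(self, random_rr):
        td = time_domain(random_rr)
        assert td["pnn25"] >= td["pnn50"]

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            time_domain(_series([800.0, 810.0, 790.0]))


class TestRelativeTimeDomain:
    def test_centering_identity(self, random_rr):
        rel = relative_time_domain(random_rr)
        assert rel["rel_mean_rr"] == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance_of_sdnn(self, random_rr):
        td = time_domain(random_rr)
        rel = relative_time_domain(random_rr)
        assert rel["rel_sdnn"] == pytest.approx(td["sdnn"] / td["mean_rr"], rel=1e-9)

    def test_hand_value(self):
        rr = [800.0, 850.0, 780.0, 820.0]
        rel = relative_time_domain(_series(rr))
        sdnn = np.std(rr, ddof=1)
        assert rel["rel_sdnn"] == pytest.approx(sdnn / 812.5, rel=1e-12)


class TestSpectral:
    def test_constant_series_near_zero_psd(self):
        rr = _series([800.0] * 40)
        spec = estimate_psd(rr)
        assert np.all(spec.psd[spec.freqs > 0] < 1e-12)

    @pytest.mark.parametrize("freq", [0.1, 0.25])
    def test_modulation_frequency_recovered(self, freq):
        spec_gen = ps.RRGenSpec(
            duration_s=300.0, mean_rr_ms=800.0,
            lf_amp_ms=50.0 if freq == 0.1 else 0.0,
            hf_amp_ms=50.0 if freq == 0.25 else 0.0,
            seed=17,
        )
        rr = ps.generate_rr(spec_gen)
        spec = estimate_psd(rr)
        peak = spec.freqs[np.argmax(spec.psd)]
        assert abs(peak - freq) <= 0.02

    def test_psd_integral_matches_variance(self):
        rng = np.random.default_rng(5)
        rr = 800.0 + rng.normal(0.0, 40.0, size=700)
        series = _series(rr)
        spec = estimate_psd(series)
        total = np.trapezoid(spec.psd, spec.freqs)
        # variance of the resampled tachogram, recomputed the same way
        from scipy.interpolate import CubicSpline

        t = series.beat_times_s
        grid = np.arange(t[0], t[-1] + 0.125, 0.25)
        grid = grid[grid <= t[-1]]
        y = CubicSpline(t, rr)(grid)
        assert total == pytest.approx(np.var(y), rel=0.05)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            estimate_psd(_series([800.0] * 8))


class TestFrequencyDomain:
    def _impulse_spec(self, freq_power):
        freqs = np.arange(0.0, 0.5, 0.01)
        psd = np.zeros_like(freqs)
        for f0, p in freq_power.items():
            psd[np.argmin(np.abs(freqs - f0))] = p
        return ps.hrv_features.SpectralEstimate(freqs, psd)

    def test_all_power_in_hf(self):
        fd, _ = frequency_domain(self._impulse_spec({0.2: 10.0}))
        assert fd["hf_pct"] == pytest.approx(100.0)
        assert fd["lf_nu"] == pytest.approx(0.0)
        assert fd["hf_nu"] == pytest.approx(100.0)

    def test_equal_lf_hf_power(self):
        fd, _ = frequency_domain(self._impulse_spec({0.1: 7.0, 0.3: 7.0}))
        assert fd["lf_hf"] == pytest.approx(1.0)
        assert fd["lf_nu"] == pytest.approx(50.0)
        assert fd["hf_nu"] == pytest.approx(50.0)

    def test_nu_sum_is_100(self, random_rr):
        fd, _ = frequency_domain(estimate_psd(random_rr))
        assert fd["lf_nu"] + fd["hf_nu"] == pytest.approx(100.0, abs=1e-9)

    def test_band_power_recovery_hf(self):
        spec_gen = ps.RRGenSpec(
            duration_s=300.0, mean_rr_ms=800.0, hf_amp_ms=50.0, seed=23
        )
        rr = ps.generate_rr(spec_gen)
        fd, _ = frequency_domain(estimate_psd(rr))
        assert fd["hf"] >= 0.8 * (fd["lf"] + fd["hf"])

    def test_zero_power_flagged(self):
        fd, flags = frequency_domain(self._impulse_spec({}))
        assert fd["lf_hf"] == 0.0
        assert "zero_total_power" in flags


class TestPoincare:
    def test_constant_series_zero(self):
        assert poincare(_series([800.0] * 10)) == (0.0, 0.0)

    def test_sd1_is_sdsd_over_sqrt2(self, random_rr):
        sd1, _ = poincare(random_rr)
        sdsd = np.std(np.diff(random_rr.rr_ms), ddof=1)
        assert sd1 == pytest.approx(sdsd / np.sqrt(2), rel=1e-9)

    def test_matches_rotation_oracle(self):
        rr = np.array([800.0, 850.0, 780.0, 820.0])
        sd1, sd2 = poincare(_series(rr))
        o1, o2 = orc.oracle_poincare(rr)
        assert sd1 == pytest.approx(o1, rel=1e-12)
        assert sd2 == pytest.approx(o2, rel=1e-12)


class TestSampleEntropy:
    def test_strict_alternation_is_zero(self):
        rr = np.tile([800.0, 900.0], 50)
        assert sample_entropy(_series(rr)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        rr = 800.0 + rng.uniform(-100.0, 100.0, size=200)
        got = sample_entropy(_series(rr))
        assert got == pytest.approx(orc.oracle_sampen(rr), abs=1e-12)

    def test_constant_series_undefined(self):
        with pytest.raises(ValueError, match="zero-variance"):
            sample_entropy(_series([800.0] * 20))


class TestHiguchi:
    def test_linear_ramp_dimension_one(self):
        rr = 700.0 + 2.0 * np.arange(200)
        assert higuchi_fd(rr) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_dimension_two(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=1000)
        assert higuchi_fd(x) == pytest.approx(2.0, abs=0.15)

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.normal(800.0, 50.0, size=int(rng.integers(50, 200)))
            assert higuchi_fd(x) == pytest.approx(orc.oracle_higuchi(x), rel=1e-9)

    def test_short_series_reduces_kmax_with_warning(self):
        rng = np.random.default_rng(5)
        with pytest.warns(UserWarning, match="kmax"):
            fd = higuchi_fd(rng.normal(size=10), kmax=8)
        assert 1.0 <= fd <= 2.5


class TestOracleEquivalence:
    """Every parameter equals its brute-force reference on random series."""

    @pytest.mark.parametrize("seed", range(12))
    def test_all_34_features(self, seed):
        rr = _random_series(seed)
        feats = extract_features(rr)
        assert feats.valid
        expected = orc.oracle_all_features(rr.rr_ms, rr.beat_times_s)
        for name in FEATURE_NAMES:
            assert feats[name] == pytest.approx(
                expected[name], rel=1e-9, abs=1e-12
            ), name


class TestScaleEquivariance:
    @given(c=st.floats(min_value=0.5, max_value=2.0))
    @settings(max_examples=20, deadline=None)
    def test_rescaled_rr(self, c):
        rng = np.random.default_rng(99)
        rr = 800.0 + rng.uniform(-120.0, 120.0, size=50)
        base = extract_features(_series(rr))
        scaled = extract_features(_series(c * rr))
        for name in ("mean_rr", "median_rr", "sdnn", "rmssd", "sdsd", "sd1", "sd2"):
            assert scaled[name] == pytest.approx(c * base[name], rel=1e-6)
        for name in ("sdnn_rmssd", "kurt", "skew", "rel_sdnn", "rel_rmssd",
                     "rel_kurt", "rel_skew", "higuchi"):
            assert scaled[name] == pytest.approx(base[name], rel=1e-6, abs=1e-9)
        assert scaled["hr"] == pytest.approx(base["hr"] / c, rel=1e-6)


class TestExtractFeatures:
    def test_valid_window_complete(self):
        spec = ps.RRGenSpec(
            duration_s=30.0, mean_rr_ms=800.0, lf_amp_ms=20.0, hf_amp_ms=40.0,
            noise_sd_ms=10.0, seed=1,
        )
        feats = extract_features(ps.generate_rr(spec))
        assert feats.valid
        arr = feats.to_array()
        assert arr.size == 34
        assert np.isfinite(arr).all()

    def test_too_few_beats_invalid_not_nan(self):
        feats = extract_features(_series([800.0, 810.0, 790.0]))
        assert not feats.valid
        assert feats.values == {}
        assert "too_few_beats" in feats.flags

    def test_constant_window_degenerate_cascade(self):
        feats = extract_features(_series([800.0] * 40))
        assert feats.valid
        assert feats["sdnn"] == 0.0
        assert feats["rmssd"] == 0.0
        assert feats["sdnn_rmssd"] == 0.0
        assert feats["tf"] < 1e-9
        assert "constant_series" in feats.flags
        assert "sampen_undefined" in feats.flags

    def test_vlf_flagged_unresolved_in_short_window(self):
        feats = extract_features(_random_series(2))
        assert "vlf_unresolved" in feats.flags

    def test_stress_direction_in_features(self):
        """Stressed RR regime yields higher LF/HF and lower HF nu medians."""
        rest_profile, _, stress_profile = ps.default_profiles()
        rng = np.random.default_rng(314)
        lf_hf = {0: [], 2: []}
        hf_nu = {0: [], 2: []}
        for profile in (rest_profile, stress_profile):
            for _ in range(50):
                feats = extract_features(ps.generate_rr(profile.draw(30.0, rng)))
                lf_hf[profile.label].append(feats["lf_hf"])
                hf_nu[profile.label].append(feats["hf_nu"])
        assert np.median(lf_hf[2]) > np.median(lf_hf[0])
        assert np.median(hf_nu[2]) < np.median(hf_nu[0])


class TestExtractorEstimator:
    def test_transform_produces_canonical_frame(self):
        series = [_random_series(s) for s in range(5)]
        series.append(_series([800.0, 810.0, 790.0]))  # invalid, dropped
        out = HrvFeatureExtractor().fit(series).transform(series)
        assert list(out.columns) == list(FEATURE_NAMES)
        assert len(out) == 5

    def test_sklearn_param_round_trip(self):
        ext = HrvFeatureExtractor(sampen_m=3)
        assert ext.get_params()["sampen_m"] == 3
        ext.set_params(higuchi_kmax=6)
        assert ext.higuchi_kmax == 6
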