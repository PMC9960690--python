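"""The 61-feature HRV battery: hand-computed examples, spectral oracles and
structural invariants."""

import math

import numpy as np
import pytest

import hrvstress as hs
from hrvstress.data_io import NON_STRESS, STRESS, PipelineConfig
from hrvstress.features import (
    FEATURE_REGISTRY,
    SpectralBands,
    extract_feature_table,
    extract_feature_vector,
    frequency_band_features,
    poincare_features,
    resample_and_psd,
    spectral_shape_features,
    statistical_features,
    time_domain_features,
)
from hrvstress.synthetic_data import SubjectProfile, simulate_rr_segment
from conftest import make_window


def tone_window(freq_hz, amp=0.05, rr0=0.8, duration=300.0, phase=0.0):
    """Deterministic single-tone tachogram built beat by beat."""
    t, rr = [], []
    cur = 0.0
    while True:
        step = rr0 + amp * math.sin(2 * math.pi * freq_hz * cur + phase)
        if cur + step > duration:
            break
        cur += step
        t.append(cur)
        rr.append(step)
    return make_window(rr=np.array(rr), beat_times=np.array(t))


class TestRegistry:
    def test_61_unique_names_in_fixed_order(self):
        assert len(FEATURE_REGISTRY) == 61
        assert len(set(FEATURE_REGISTRY.names)) == 61
        domains = set(FEATURE_REGISTRY.domains.values())
        assert domains == {"time", "frequency", "nonlinear", "statistical",
                           "spectral_shape"}

    def test_band_edges_validated(self):
        with pytest.raises(hs.data_io.ValidationError):
            SpectralBands(vlf=(0.003, 0.05), lf=(0.04, 0.15), hf=(0.15, 0.4))


class TestTimeDomain:
    def test_alternating_diffs_rmssd_nn50(self):
        f = time_domain_features(make_window(rr=[0.8, 0.86, 0.8, 0.86]))
        assert f["rmssd"] == pytest.approx(0.06)
        assert f["nn50"] == 3
        assert f["pnn50"] == 100.0

    def test_two_point_alternation_sdnn(self):
        f = time_domain_features(make_window(rr=[0.8, 0.85, 0.8, 0.85]))
        assert f["sdnn"] == pytest.approx(0.028868, abs=1e-6)

    def test_constant_series(self):
        f = time_domain_features(make_window(rr=np.full(375, 0.8)))
        assert f["sdnn"] == pytest.approx(0.0, abs=1e-12)
        assert f["rmssd"] == 0.0
        assert f["hr_mean"] == pytest.approx(75.0)
        assert f["tinn"] == 0.0
        assert f["tri_index"] == 1.0

    def test_heart_rate_summaries(self):
        f = time_domain_features(make_window(rr=[0.5, 1.0]))
        assert f["hr_max"] == pytest.approx(120.0)
        assert f["hr_min"] == pytest.approx(60.0)
        assert f["nni_count"] == 2
        assert f["nni_max"] == 1.0

    def test_tinn_spans_histogram_for_triangular_data(self):
        rng = np.random.default_rng(0)
        rr = rng.triangular(0.6, 0.8, 1.0, 4000)
        f = time_domain_features(make_window(rr=rr))
        # triangular fit should roughly recover the support width
        assert 0.25 <= f["tinn"] <= 0.55
        assert f["tinn_n"] < f["tinn_m"]
        assert f["tri_index"] > 1


class TestSpectrum:
    def test_single_tone_power_lands_in_hf(self):
        w = tone_window(0.25)
        freqs, psd = resample_and_psd(w)
        bands = frequency_band_features(freqs, psd)
        assert bands["hf_power"] >= 0.95 * bands["total_power"]
        assert bands["hf_nu"] > 90

    def test_single_tone_power_lands_in_lf(self):
        w = tone_window(0.1)
        freqs, psd = resample_and_psd(w)
        bands = frequency_band_features(freqs, psd)
        assert bands["lf_power"] >= 0.95 * bands["total_power"]

    def test_constant_tachogram_zero_power(self):
        w = make_window(rr=np.full(375, 0.8))
        freqs, psd = resample_and_psd(w)
        assert psd.sum() * (freqs[1] - freqs[0]) <= 1e-12

    def test_parseval_on_random_tachograms(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            rr = np.clip(rng.normal(0.85, 0.06, 360), 0.31, 1.29)
            w = make_window(rr=rr)
            freqs, psd = resample_and_psd(w)
            # recompute the detrended variance independently
            from scipy.interpolate import PchipInterpolator
            from scipy.signal import detrend

            n = int(math.floor((w.beat_times[-1] - w.beat_times[0]) * 8)) + 1
            grid = w.beat_times[0] + np.arange(n) / 8
            x = detrend(PchipInterpolator(w.beat_times, w.rr)(grid))
            var = np.var(x)
            assert psd.sum() * (freqs[1] - freqs[0]) == pytest.approx(var, rel=1e-6)

    def test_short_window_rejected(self):
        w = make_window(rr=np.full(20, 0.8))
        with pytest.raises(hs.data_io.ValidationError, match="60"):
            resample_and_psd(w)

    def test_two_tone_band_split(self):
        """Equal-amplitude tones at 0.1 and 0.25 Hz (well beat-sampled at a
        2 Hz heart rate): LF ≈ HF within 5%, each near the a²/2 tone power."""
        a = 0.02
        t, rr = [], []
        cur = 0.0
        while True:
            step = 0.5 + a * (
                math.sin(2 * math.pi * 0.1 * cur) + math.sin(2 * math.pi * 0.25 * cur)
            )
            if cur + step > 300:
                break
            cur += step
            t.append(cur)
            rr.append(step)
        w = make_window(rr=np.array(rr), beat_times=np.array(t))
        freqs, psd = resample_and_psd(w)
        bands = frequency_band_features(freqs, psd)
        assert bands["lf_power"] == pytest.approx(bands["hf_power"], rel=0.05)
        assert 0.95 < bands["lf_hf"] < 1.05
        assert bands["lf_power"] == pytest.approx(a**2 / 2, rel=0.1)


class TestBandFeatures:
    def make_psd(self, power_at):
        freqs = np.arange(0, 4, 0.01)
        psd = np.zeros_like(freqs)
        for f0, p in power_at.items():
            psd[np.argmin(np.abs(freqs - f0))] = p / 0.01
        return freqs, psd

    def test_all_power_in_lf(self):
        freqs, psd = self.make_psd({0.1: 1.0})
        b = frequency_band_features(freqs, psd)
        assert b["lf_nu"] == pytest.approx(100.0)
        assert b["hf_nu"] == 0.0

    def test_equal_bands(self):
        freqs, psd = self.make_psd({0.1: 1.0, 0.25: 1.0})
        b = frequency_band_features(freqs, psd)
        assert b["lf_hf"] == pytest.approx(1.0)
        assert b["lf_nu"] == pytest.approx(50.0)

    def test_band_powers_sum_to_total(self):
        rng = np.random.default_rng(8)
        freqs = np.arange(0, 4, 0.005)
        psd = rng.random(freqs.size)
        b = frequency_band_features(freqs, psd)
        assert b["total_power"] == pytest.approx(
            b["vlf_power"] + b["lf_power"] + b["hf_power"], abs=1e-15
        )

    def test_zero_hf_guarded(self):
        freqs, psd = self.make_psd({0.1: 1.0})
        b = frequency_band_features(freqs, psd)
        assert b["lf_hf"] == np.finfo(np.float64).max


class TestPoincare:
    def test_alternating_diffs(self):
        w = make_window(rr=[0.8, 0.86, 0.8, 0.86, 0.8])
        f = poincare_features(w)
        # successive diffs +0.06/-0.06 alternating: population variance 0.0036
        assert f["sd1"] == pytest.approx(math.sqrt(0.0036 / 2), abs=1e-6)

    def test_constant_guarded(self):
        f = poincare_features(make_window(rr=np.full(10, 0.8)))
        assert (f["sd1"], f["sd2"], f["sd1_sd2"]) == (0.0, 0.0, 0.0)

    def test_iid_limit_ratio_near_one(self):
        rng = np.random.default_rng(12)
        rr = rng.normal(0.8, 0.05, 20000)
        f = poincare_features(make_window(rr=np.clip(rr, 0.31, 1.29)))
        assert f["sd1_sd2"] == pytest.approx(1.0, abs=0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        rr = np.clip(rng.normal(0.8, 0.05, 300), 0.31, 1.29)
        base_t = time_domain_features(make_window(rr=rr))
        base_p = poincare_features(make_window(rr=rr))
        c = 1.17
        scaled_t = time_domain_features(make_window(rr=c * rr))
        scaled_p = poincare_features(make_window(rr=c * rr))
        for key in ("sdnn", "rmssd"):
            assert scaled_t[key] == pytest.approx(c * base_t[key], rel=1e-9)
        for key in ("sd1", "sd2"):
            assert scaled_p[key] == pytest.approx(c * base_p[key], rel=1e-9)


class TestStatistical:
    def test_constant_guards(self):
        f = statistical_features(make_window(rr=np.full(100, 0.8)))
        assert f["rr_std"] == 0.0
        assert f["entropy"] == 0.0
        assert f["slope"] == 0.0
        assert f["kurtosis"] == 0.0 and f["skewness"] == 0.0

    def test_linear_ramp_slope(self):
        rr = 0.5 + 0.001 * np.arange(200)
        f = statistical_features(make_window(rr=rr))
        assert f["slope"] == pytest.approx(0.001, abs=1e-12)

    def test_quantile_convention(self):
        f = statistical_features(make_window(rr=[0.7, 0.8, 0.9]))
        assert f["rr_median"] == pytest.approx(0.8)
        # type-7 quartiles of (0.7, 0.8, 0.9): Q1=0.75, Q3=0.85
        assert f["rr_iqr"] == pytest.approx(0.1)

    def test_energy_and_deviations(self):
        rr = np.array([0.6, 0.8, 1.0])
        f = statistical_features(make_window(rr=rr))
        assert f["abs_energy"] == pytest.approx(0.36 + 0.64 + 1.0)
        assert f["mean_abs_dev"] == pytest.approx(np.mean([0.2, 0.0, 0.2]))
        assert f["median_abs_diff"] == pytest.approx(0.2)


class TestSpectralShape:
    def test_single_tone_centroid_and_rolloff(self):
        w = tone_window(0.25)
        freqs, psd = resample_and_psd(w)
        f = spectral_shape_features(freqs, psd)
        assert f["spectral_centroid"] == pytest.approx(0.25, abs=0.02)
        assert f["spectral_rolloff_95"] == pytest.approx(0.25, abs=0.02)
        assert f["fundamental_frequency"] == pytest.approx(0.25, abs=0.01)

    def test_flat_psd(self):
        freqs = np.linspace(0, 4, 401)
        psd = np.ones_like(freqs)
        f = spectral_shape_features(freqs, psd)
        assert f["spectral_centroid"] == pytest.approx(2.0)
        assert f["spectral_entropy"] == pytest.approx(1.0)

    def test_all_zero_psd_guarded(self):
        freqs = np.linspace(0, 4, 100)
        f = spectral_shape_features(freqs, np.zeros_like(freqs))
        assert all(v == 0.0 for v in f.values())

    def test_random_psd_properties(self):
        rng = np.random.default_rng(21)
        freqs = np.linspace(0, 4, 512)
        for _ in range(50):
            psd = rng.random(512) * rng.random()
            f = spectral_shape_features(freqs, psd)
            assert f["spectral_variance"] >= 0
            assert f["spectral_rolloff_95"] >= f["median_frequency"]
            assert f["spectral_spread"] == pytest.approx(
                math.sqrt(f["spectral_variance"]), rel=1e-12
            )


class TestAssembly:
    def test_vector_has_61_values(self):
        profile = SubjectProfile()
        w_rec = simulate_rr_segment(profile, NON_STRESS, 300.0, seed=5)
        w = make_window(rr=w_rec.rr, beat_times=w_rec.beat_times, label=NON_STRESS)
        vec = extract_feature_vector(w)
        feature_keys = [k for k in vec if k in FEATURE_REGISTRY.names]
        assert len(feature_keys) == 61
        assert all(np.isfinite(vec[k]) for k in feature_keys)

    def test_determinism(self):
        profile = SubjectProfile()
        rec = simulate_rr_segment(profile, STRESS, 300.0, seed=6)
        w1 = make_window(rr=rec.rr, beat_times=rec.beat_times, label=STRESS)
        w2 = make_window(rr=rec.rr.copy(), beat_times=rec.beat_times.copy(), label=STRESS)
        assert extract_feature_vector(w1) == extract_feature_vector(w2)

    def test_failing_window_skipped_not_zero_filled(self):
        good_rec = simulate_rr_segment(SubjectProfile(), STRESS, 300.0, seed=7)
        good = make_window(rr=good_rec.rr, beat_times=good_rec.beat_times,
                           label=STRESS, window_id="good")
        bad = make_window(rr=np.full(30, 0.8), label=STRESS, window_id="bad")
        table = extract_feature_table([good, bad])
        assert list(table["window_id"]) == ["good"]
        assert [wid for wid, _ in table.attrs["skipped"]] == ["bad"]

    def test_stress_modulation_direction(self):
        """Directional check: stress lowers SDNN and HF power, raises LF/HF."""
        sdnn = {c: [] for c in (STRESS, NON_STRESS)}
        lf_hf = {c: [] for c in (STRESS, NON_STRESS)}
        for seed in range(10):
            profile = SubjectProfile()
            for cond in (STRESS, NON_STRESS):
                rec = simulate_rr_segment(profile, cond, 300.0, seed=seed)
                w = make_window(rr=rec.rr, beat_times=rec.beat_times, label=cond)
                vec = extract_feature_vector(w)
                sdnn[cond].append(vec["sdnn"])
                lf_hf[cond].append(vec["lf_hf"])
        assert np.mean(sdnn[STRESS]) < np.mean(sdnn[NON_STRESS])
        assert np.mean(lf_hf[STRESS]) > np.mean(lf_hf[NON_STRESS])
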