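import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiostage import (
    Hypnogram,
    clean_rri,
    compute_feature_epochs,
    detect_body_movements,
    estimate_resp_frequency,
    extract_rsa,
    filter_respiration,
    instantaneous_phase,
    pad_lv,
    phase_coherence,
    resample_rri,
)
from cardiostage.features import count_movement_events, wrap_phase, GRID_HZ
from conftest import make_bundle, simulate_single_stage


class TestCleanRri:
    def test_clean_series_unchanged(self):
        t = np.arange(1, 51, dtype=float)
        r = np.full(50, 1000.0)
        t2, r2 = clean_rri(t, r)
        assert np.array_equal(t2, t) and np.array_equal(r2, r)

    def test_jump_outlier_removed(self):
        r = np.full(20, 1000.0)
        r[10] = 1500.0  # 50 % above the running median
        t = np.cumsum(r) / 1000.0
        _, r2 = clean_rri(t, r)
        assert len(r2) == 19 and np.all(r2 == 1000.0)

    def test_below_physiological_floor_removed(self):
        r = np.full(20, 1000.0)
        r[5] = 250.0
        t = np.cumsum(r) / 1000.0
        _, r2 = clean_rri(t, r)
        assert 250.0 not in r2

    def test_too_few_beats_is_an_error(self):
        with pytest.raises(ValueError, match="insufficient"):
            clean_rri(np.array([1.0, 2.0]), np.array([100.0, 100.0]))

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            clean_rri(np.array([1.0, 1.0, 2.0]), np.full(3, 1000.0))


class TestResampleRri:
    def test_constant_rri_gives_constant_hr(self):
        t = np.cumsum(np.full(30, 1000.0)) / 1000.0
        res = resample_rri(t, np.full(30, 1000.0))
        assert np.allclose(res["hr"], 60.0)
        assert np.allclose(np.diff(res["t"]), 0.1)

    def test_1200ms_gives_50bpm(self):
        t = np.cumsum(np.full(30, 1200.0)) / 1000.0
        res = resample_rri(t, np.full(30, 1200.0))
        assert np.allclose(res["hr"], 50.0)

    def test_spline_interpolates_knots_exactly(self):
        r = np.tile([900.0, 1100.0], 20)
        t = np.cumsum(r) / 1000.0
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(t, r)
        assert np.allclose(spline(t), r, atol=1e-9)

    def test_too_few_beats(self):
        with pytest.raises(ValueError, match="4 beats"):
            resample_rri(np.array([1.0, 2.0, 3.0]), np.full(3, 1000.0))


class TestRespirationFilter:
    def test_passband_tone_preserved(self):
        fs, t = 10.0, np.arange(0, 300, 0.1)
        x = np.sin(2 * np.pi * 0.25 * t)
        y = filter_respiration(x, fs)
        interior = slice(300, -300)
        assert np.max(np.abs(y[interior])) >= 0.9

    def test_stopband_tone_suppressed(self):
        fs = 10.0
        t = np.arange(0, 300, 1 / fs)
        x = np.sin(2 * np.pi * 2.0 * t)
        y = filter_respiration(x, fs)
        assert np.max(np.abs(y[300:-300])) <= 0.1

    def test_zero_in_zero_out(self):
        assert np.allclose(filter_respiration(np.zeros(1000), 10.0), 0.0)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            filter_respiration(np.zeros(5), 10.0)


class TestRespiratoryFrequency:
    def test_pure_tone_identified(self):
        fs = 10.0
        t = np.arange(0, 20, 1 / fs)
        f = estimate_resp_frequency(np.sin(2 * np.pi * 0.25 * t), fs)
        assert 0.24 <= f <= 0.26

    def test_dominant_tone_wins(self):
        fs = 10.0
        t = np.arange(0, 20, 1 / fs)
        x = 1.0 * np.sin(2 * np.pi * 0.2 * t) + 0.3 * np.sin(2 * np.pi * 0.4 * t)
        f = estimate_resp_frequency(x, fs)
        # independent periodogram oracle for the dominant tone
        from scipy.signal import periodogram

        freqs, p = periodogram(x, fs)
        f_oracle = freqs[np.argmax(p)]
        assert abs(f - 0.2) < 0.02 and abs(f_oracle - 0.2) < 0.03

    def test_noise_estimates_stay_in_band(self):
        fs = 10.0
        rng = np.random.default_rng(0)
        for _ in range(100):
            f = estimate_resp_frequency(rng.standard_normal(200), fs)
            assert 0.05 <= f <= 0.6

    def test_flat_window_flagged_missing(self):
        assert np.isnan(estimate_resp_frequency(np.zeros(200), 10.0))


class TestRsa:
    def _rri_df(self, x):
        t = np.arange(len(x)) / GRID_HZ
        return pd.DataFrame({"t": t, "rri": x, "hr": 60000.0 / np.maximum(x, 1)})

    def test_modulation_at_f_r_preserved(self):
        t = np.arange(0, 600, 1 / GRID_HZ)
        x = 1000 + 40 * np.sin(2 * np.pi * 0.25 * t)
        y = extract_rsa(self._rri_df(x), 0.25)
        assert np.max(np.abs(y[1000:-1000])) >= 0.9 * 40

    def test_modulation_off_band_attenuated(self):
        t = np.arange(0, 600, 1 / GRID_HZ)
        x = 1000 + 40 * np.sin(2 * np.pi * 0.625 * t)  # 2.5 x f_R
        y = extract_rsa(self._rri_df(x), 0.25)
        assert np.max(np.abs(y[1000:-1000])) <= 0.2 * 40

    def test_dc_removed(self):
        x = np.full(3000, 1000.0)
        y = extract_rsa(self._rri_df(x), 0.25)
        assert np.max(np.abs(y)) < 1e-6

    def test_band_must_stay_below_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            extract_rsa(self._rri_df(np.full(3000, 1000.0)), 4.0)


class TestInstantaneousPhase:
    def test_pure_tone_phase_slope(self):
        fs, f0 = 10.0, 0.25
        t = np.arange(0, 200, 1 / fs)
        ph = np.unwrap(instantaneous_phase(np.sin(2 * np.pi * f0 * t)))
        interior = slice(len(t) // 10, -len(t) // 10)
        slope = np.polyfit(t[interior], ph[interior], 1)[0]
        assert abs(slope - 2 * np.pi * f0) / (2 * np.pi * f0) < 0.01

    def test_quadrature_pair_offset(self):
        fs, f0 = 10.0, 0.25
        t = np.arange(0, 200, 1 / fs)
        pc = instantaneous_phase(np.cos(2 * np.pi * f0 * t))
        ps = instantaneous_phase(np.sin(2 * np.pi * f0 * t))
        d = wrap_phase(pc - ps)
        interior = slice(len(t) // 10, -len(t) // 10)
        assert np.allclose(d[interior], np.pi / 2, atol=0.05)

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(3)
        x = np.convolve(rng.standard_normal(500), np.ones(20) / 20, mode="same")
        assert np.allclose(instantaneous_phase(x), instantaneous_phase(7.3 * x))


class TestPhaseCoherence:
    def test_constant_phase_difference_gives_one(self):
        lam = phase_coherence(np.full(500, 0.7), 100)
        assert np.allclose(lam[99:], 1.0)

    def test_antipodal_phases_cancel(self):
        psi = np.tile([0.0, np.pi], 250)
        lam = phase_coherence(psi, 100)
        assert np.allclose(lam[99:], 0.0, atol=1e-12)

    def test_iid_uniform_mean_is_one_over_n(self):
        rng = np.random.default_rng(1)
        n, windows = 100, 10_000
        psi = rng.uniform(-np.pi, np.pi, size=n * windows)
        lam = phase_coherence(psi, n)
        vals = lam[n - 1:: n]  # non-overlapping windows
        assert abs(np.mean(vals) - 1 / n) < 0.2 / n

    def test_bounded_on_fuzzed_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            psi = rng.normal(scale=rng.uniform(0.01, 50), size=rng.integers(10, 300))
            lam = phase_coherence(psi, rng.integers(2, len(psi) + 1))
            ok = lam[np.isfinite(lam)]
            assert np.all((ok >= 0) & (ok <= 1))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        psi = rng.normal(size=400)
        a = phase_coherence(psi, 50)
        b = phase_coherence(psi + 1.234, 50)
        assert np.allclose(a[49:], b[49:], atol=1e-12)

    def test_window_longer_than_series(self):
        with pytest.raises(ValueError, match="window"):
            phase_coherence(np.zeros(10), 11)


class TestBodyMovements:
    def test_false_positive_rate_matches_simulation_oracle(self):
        # the oracle applies the identical rule to fresh noise: both sides
        # should see (almost) no flagged windows on pure Gaussian baseline
        fs = 128.0
        rng = np.random.default_rng(0)
        impl = detect_body_movements(rng.standard_normal(int(1000 * 5 * fs)), fs)
        oracle = detect_body_movements(rng.standard_normal(int(1000 * 5 * fs)), fs)
        assert abs(impl.mean() - oracle.mean()) < 0.01
        assert impl.mean() < 0.01

    def test_strong_burst_flags_containing_windows(self):
        fs = 128.0
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(120 * fs))
        i0 = int(60 * fs)
        x[i0: i0 + int(fs)] += 10.0 * rng.standard_normal(int(fs))
        flags = detect_body_movements(x, fs)
        # burst at 60-61 s lies inside windows centred at 55..65 s
        assert flags[10] == 1 or flags[11] == 1
        assert count_movement_events(x, fs) == 1

    def test_weak_excursion_below_threshold_ignored(self):
        fs = 128.0
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(120 * fs))
        i0 = int(60 * fs)
        x[i0: i0 + int(fs)] += 0.5 * rng.standard_normal(int(fs))  # ~1.1x baseline RMS
        flags = detect_body_movements(x, fs)
        assert flags.sum() == 0

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="60 Hz"):
            detect_body_movements(np.zeros(1000), 50.0)


class TestFeatureEpochs:
    def test_five_minute_record_has_ten_rows(self):
        bundle, hyp = simulate_single_stage("N2", minutes=5, seed=8)
        df = compute_feature_epochs(bundle, hyp)
        assert len(df) == 10
        assert list(df["epoch"]) == list(range(10))

    def test_constant_hr_recovered_exactly(self):
        n_beats = 300
        rri = np.full(n_beats, 1000.0)
        t = np.arange(0, 300, 0.1)
        resp = np.sin(2 * np.pi * 0.25 * t)
        rng = np.random.default_rng(0)
        emg = rng.standard_normal(int(300 * 128))
        bundle = make_bundle(rri, resp, emg)
        df = compute_feature_epochs(bundle)
        assert np.allclose(df["hr_bpm"], 60.0, atol=1e-6)
        assert np.allclose(df["rr_brpm"], 15.0, atol=1.0)

    def test_locked_n3_record_has_high_lambda(self):
        bundle, hyp = simulate_single_stage("N3", minutes=20, seed=9,
                                            phase_jitter_sd=0.0)
        df = compute_feature_epochs(bundle, hyp)
        interior = df["lambda"].iloc[3:-3]
        assert np.all(interior >= 0.95)

    def test_lv_epochs_zeroed(self):
        from cardiostage import CohortConfig, simulate_signals

        labels = ["N2"] * 6 + ["LV"] * 4 + ["N2"] * 6
        hyp = Hypnogram(labels)
        bundle = simulate_signals(hyp, CohortConfig(record_minutes=8), seed=4)
        df = compute_feature_epochs(bundle, hyp)
        lv_rows = df[df["stage"] == "LV"]
        assert len(lv_rows) == 4
        assert (lv_rows[["hr_bpm", "rr_brpm", "lambda", "bmf_per_s"]] == 0).all().all()

    @given(st.integers(min_value=4, max_value=14))
    @settings(max_examples=5)
    def test_row_count_equals_hypnogram_length(self, minutes):
        bundle, hyp = simulate_single_stage("N2", minutes=minutes, seed=17)
        df = compute_feature_epochs(bundle, hyp)
        assert len(df) == len(hyp) == minutes * 2


class TestPadLv:
    def _features(self, n):
        return pd.DataFrame({
            "epoch": np.arange(n), "hr_bpm": 60.0, "rr_brpm": 15.0,
            "lambda": 0.9, "bmf_per_s": 0.0, "stage": "N2",
        })

    def test_adds_four_epochs_each_end(self):
        feats, hyp = pad_lv(self._features(10), Hypnogram(["N2"] * 10))
        assert len(feats) == len(hyp) == 18
        zero_rows = feats.iloc[list(range(4)) + list(range(14, 18))]
        assert (zero_rows[["hr_bpm", "rr_brpm", "lambda", "bmf_per_s"]] == 0).all().all()
        assert hyp.labels[:4] == ("LV",) * 4 and hyp.labels[-4:] == ("LV",) * 4
        assert hyp.labels[4:14] == ("N2",) * 10

    def test_double_padding_adds_sixteen(self):
        feats, hyp = pad_lv(self._features(10), Hypnogram(["N2"] * 10))
        feats2, hyp2 = pad_lv(feats, hyp)
        assert len(feats2) == 26 and len(hyp2) == 26

    def test_empty_input_gives_eight_lv_epochs(self):
        feats, hyp = pad_lv(self._features(0), Hypnogram([]))
        assert len(feats) == 8 and hyp.labels == ("LV",) * 8
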