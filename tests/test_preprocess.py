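"""Filtering, isosbestic regression, DF/F and Z-score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fiberflow import (
    DegenerateDataError,
    ISOSBESTIC,
    ParameterError,
    SENSOR_465,
    ValidationError,
    PhotometryRecording,
    SimulationConfig,
    compute_dff,
    fit_isosbestic,
    lowpass_filter,
    preprocess_recording,
    simulate_session,
    zscore_trace,
)
from fiberflow.preprocess import RegressionFit


def butter2_zero_phase_gain(f: float, fc: float) -> float:
    """Analytic magnitude response of an order-2 Butterworth applied
    forward-backward: |H|^2 with |H| = 1/sqrt(1 + (f/fc)^4)."""
    return 1.0 / (1.0 + (f / fc) ** 4)


class TestLowpassFilter:
    def test_dc_gain_is_unity(self):
        out = lowpass_filter(np.full(500, 7.0), sampling_rate=120.0)
        np.testing.assert_allclose(out, 7.0, atol=1e-9)

    @pytest.mark.parametrize(
        "freq, bound, comparator",
        [(1.0, 0.99, np.greater_equal), (50.0, 0.01, np.less_equal)],
    )
    def test_tone_amplitudes_match_analytic_response(self, freq, bound, comparator):
        fs = 120.0
        t = np.arange(int(20 * fs)) / fs
        tone = np.sin(2 * np.pi * freq * t)
        out = lowpass_filter(tone, fs, cutoff=10.0, order=2, zero_phase=True)
        # measure away from the edges
        core = slice(int(2 * fs), int(18 * fs))
        ratio = np.abs(out[core]).max() / np.abs(tone[core]).max()
        assert comparator(ratio, bound)
        # and the analytic oracle agrees with the bound
        assert comparator(butter2_zero_phase_gain(freq, 10.0), bound)

    def test_zero_phase_keeps_pulse_peak_in_place(self):
        fs = 100.0
        t = np.arange(1000) / fs
        pulse = np.exp(-0.5 * ((t - 5.0) / 0.2) ** 2)
        out = lowpass_filter(pulse, fs, zero_phase=True)
        assert np.argmax(out) == np.argmax(pulse)

    def test_single_pass_lags_behind(self):
        fs = 100.0
        t = np.arange(1000) / fs
        pulse = np.exp(-0.5 * ((t - 5.0) / 0.2) ** 2)
        out = lowpass_filter(pulse, fs, zero_phase=False)
        assert np.argmax(out) > np.argmax(pulse)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ParameterError, match="Nyquist"):
            lowpass_filter(np.zeros(100), sampling_rate=20.0, cutoff=10.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ParameterError, match="short"):
            lowpass_filter(np.zeros(6), sampling_rate=100.0, order=2)

    def test_idempotent_in_passband(self):
        fs = 100.0
        t = np.arange(2000) / fs
        slow = np.sin(2 * np.pi * 0.5 * t) + 0.5 * np.cos(2 * np.pi * 1.5 * t)
        once = lowpass_filter(slow, fs)
        twice = lowpass_filter(once, fs)
        rms = np.sqrt(np.mean((twice - once) ** 2)) / np.sqrt(np.mean(once**2))
        assert rms < 0.01


class TestIsosbesticFit:
    def test_identity_sensor_gives_unit_slope(self):
        rng = np.random.default_rng(0)
        iso = 0.6 + 0.01 * rng.standard_normal(500)
        fit = fit_isosbestic(iso, iso)
        assert fit.a == pytest.approx(1.0)
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.fitted, iso, atol=1e-12)

    def test_exact_affine_relation_recovered(self):
        rng = np.random.default_rng(1)
        iso = 0.6 + 0.05 * rng.standard_normal(400)
        fit = fit_isosbestic(2.0 * iso + 3.0, iso)
        assert fit.a == pytest.approx(2.0)
        assert fit.b == pytest.approx(3.0)

    def test_matches_polyfit_on_noisy_data(self):
        rng = np.random.default_rng(2)
        iso = 0.6 + 0.02 * rng.standard_normal(800)
        sensor = 1.5 * iso + 0.2 + 0.01 * rng.standard_normal(800)
        fit = fit_isosbestic(sensor, iso)
        a_ref, b_ref = np.polyfit(iso, sensor, 1)
        assert fit.a == pytest.approx(a_ref, rel=1e-9)
        assert fit.b == pytest.approx(b_ref, rel=1e-9)

    def test_uncorrelated_noise_slope_within_standard_error(self):
        rng = np.random.default_rng(7)
        n = 2000
        iso = 0.6 + 0.02 * rng.standard_normal(n)
        sensor = 1.0 + 0.02 * rng.standard_normal(n)
        fit = fit_isosbestic(sensor, iso)
        se = 0.02 / (0.02 * np.sqrt(n))  # sd(noise) / (sd(iso) sqrt(n))
        assert abs(fit.a) < 4 * se

    def test_constant_isosbestic_is_degenerate(self):
        with pytest.raises(DegenerateDataError, match="constant"):
            fit_isosbestic(np.arange(10.0), np.full(10, 0.6))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError, match="shape"):
            fit_isosbestic(np.zeros(10), np.zeros(9))


class TestDFF:
    def test_exact_cancellation(self):
        fitted = np.full(100, 1.3)
        fit = RegressionFit(a=0.0, b=1.3, fitted=fitted)
        np.testing.assert_array_equal(compute_dff(fitted.copy(), fit), 0.0)

    def test_arithmetic_identity(self):
        fit = RegressionFit(a=0.0, b=1.0, fitted=np.ones(3))
        out = compute_dff(np.array([1.1, 1.0, 0.9]), fit)
        np.testing.assert_allclose(out, [0.1, 0.0, -0.1], atol=1e-15)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(5)
        fitted = 1.0 + 0.1 * rng.random(200)
        filtered = fitted * (1.0 + 0.05 * rng.standard_normal(200))
        base = compute_dff(filtered, RegressionFit(0, 0, fitted))
        scaled = compute_dff(c * filtered, RegressionFit(0, 0, c * fitted))
        np.testing.assert_allclose(scaled, base, rtol=1e-9, atol=1e-12)

    def test_zero_baseline_guard_reports_index(self):
        fitted = np.ones(10)
        fitted[4] = 0.0
        with pytest.raises(DegenerateDataError, match="sample 4"):
            compute_dff(np.ones(10), RegressionFit(0, 0, fitted))


class TestZscore:
    def test_two_point_trace_population_sigma(self):
        z, mu, sigma = zscore_trace(np.array([0.0, 2.0]))
        np.testing.assert_allclose(z, [-1.0, 1.0])
        assert (mu, sigma) == (1.0, 1.0)

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            zscore_trace(np.full(50, 0.3))

    def test_full_window_normalizes_exactly(self):
        rng = np.random.default_rng(11)
        z, _, _ = zscore_trace(rng.standard_normal(5000) * 3 + 2)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=0) - 1.0) < 1e-9

    def test_baseline_window_applies_to_whole_trace(self):
        t = np.arange(1000) / 100.0
        dff = np.where(t < 5.0, np.sin(2 * np.pi * 0.7 * t), 5.0)
        z, mu, sigma = zscore_trace(dff, window=[0.0, 5.0], time=t)
        base = dff[t < 5.0]
        assert mu == pytest.approx(base.mean())
        assert sigma == pytest.approx(base.std(ddof=0))
        assert z.size == dff.size  # whole trace transformed
        assert z[t >= 5.0].mean() > 3  # post-baseline step stays large

    def test_window_outside_span_rejected(self):
        with pytest.raises(ParameterError):
            zscore_trace(np.arange(10.0), window=[100.0, 101.0], time=np.arange(10.0))


class TestPreprocessRecording:
    def test_sensors_share_one_isosbestic_fit(self, small_recording):
        processed = preprocess_recording(small_recording)
        assert set(processed) == set(small_recording.channels)
        iso_filtered = processed[ISOSBESTIC].filtered
        for role in small_recording.sensor_roles():
            ch = processed[role]
            np.testing.assert_allclose(
                ch.fit.fitted, ch.fit.a * iso_filtered + ch.fit.b, atol=1e-12
            )
            assert abs(ch.zscore.mean()) < 1e-9
            assert abs(ch.zscore.std(ddof=0) - 1.0) < 1e-9
        assert processed[ISOSBESTIC].dff is None

    def test_isosbestic_only_recording_rejected(self, small_recording):
        rec = PhotometryRecording(
            time=small_recording.time,
            channels={ISOSBESTIC: small_recording.channels[ISOSBESTIC]},
        )
        with pytest.raises(ValidationError, match="no sensor"):
            preprocess_recording(rec)

    def test_error_annotated_with_channel_role(self, small_recording):
        with pytest.raises(ParameterError, match="sensor|isosbestic"):
            preprocess_recording(small_recording, cutoff=80.0)  # above Nyquist

    def test_shared_artifact_removed_by_regression(self, fast_sim_config):
        from dataclasses import replace

        sess = simulate_session(replace(fast_sim_config, seed=3), include_tracking=False)
        processed = preprocess_recording(sess.recording)
        artifact = sess.ground_truth["artifact"]
        ch = processed[SENSOR_465]
        assert abs(np.corrcoef(ch.raw, artifact)[0, 1]) > 0.5
        assert abs(np.corrcoef(ch.dff, artifact)[0, 1]) < 0.1

    def test_pipeline_is_deterministic(self, small_recording):
        a = preprocess_recording(small_recording)
        b = preprocess_recording(small_recording)
        for role in a:
            if a[role].zscore is not None:
                np.testing.assert_array_equal(a[role].zscore, b[role].zscore)
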