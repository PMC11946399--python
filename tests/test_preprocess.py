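"""Calibration chain: bias removal, gravity alignment, filtering."""

import numpy as np
import pytest

import gaitrel as g
from gaitrel.preprocess import (
    estimate_static_bias,
    filtfilt_gain,
    gravity_alignment,
    lowpass_filter,
    remove_gravity_cc,
)
from gaitrel.types import G


class TestStaticBias:
    def test_constant_gyro_recovered_exactly(self):
        gyro = np.tile([0.01, -0.02, 0.003], (400, 1))
        np.testing.assert_allclose(
            estimate_static_bias(gyro, (0, 400)), [0.01, -0.02, 0.003], rtol=1e-13
        )

    def test_zero_mean_sinusoid_gives_zero_bias(self):
        t = np.arange(384) / 128.0  # integer periods of 2 Hz in 3 s
        gyro = np.column_stack([np.sin(2 * np.pi * 2 * t)] * 3)
        np.testing.assert_allclose(estimate_static_bias(gyro, (0, 384)), 0, atol=1e-14)

    def test_white_noise_bias_within_standard_error(self, rng):
        sigma = 0.01
        gyro = rng.normal(0, sigma, (384, 3))
        bias = estimate_static_bias(gyro, (0, 384))
        assert np.all(np.abs(bias) < 3 * sigma / np.sqrt(384))

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_static_bias(np.zeros((100, 3)), (0, 1))


class TestGravityAlignment:
    @staticmethod
    def _static_acc(mean, n=400):
        return np.tile(np.asarray(mean, float), (n, 1))

    def test_already_aligned_gives_identity(self):
        R = gravity_alignment(self._static_acc([0, 0, G]), (0, 400))
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)

    def test_x_axis_gravity_maps_to_cc(self):
        R = gravity_alignment(self._static_acc([G, 0, 0]), (0, 400))
        np.testing.assert_allclose(R @ [G, 0, 0], [0, 0, G], atol=1e-10)

    def test_tilted_mean_lands_on_cc_with_full_norm(self):
        mean = np.array([0.3, 0.2, 9.7])
        R = gravity_alignment(self._static_acc(mean), (0, 400))
        rotated = R @ mean
        assert abs(rotated[0]) < 1e-10 and abs(rotated[1]) < 1e-10
        assert rotated[2] == pytest.approx(np.linalg.norm(mean), abs=1e-10)

    def test_rotation_is_proper_and_norm_preserving(self, rng):
        mean = np.array([1.5, -0.8, 9.3])
        R = gravity_alignment(self._static_acc(mean), (0, 400))
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)
        v = rng.normal(size=(50, 3))
        np.testing.assert_allclose(
            np.linalg.norm(v @ R.T, axis=1), np.linalg.norm(v, axis=1), rtol=1e-10
        )

    def test_non_static_sensor_rejected(self):
        with pytest.raises(ValueError, match="quasi-static"):
            gravity_alignment(self._static_acc([0, 0, 2.0]), (0, 400))


class TestGravityRemoval:
    def test_constant_gravity_zeroed_and_ap_untouched(self, rng):
        acc = rng.normal(size=(500, 3))
        acc[:, 2] += G
        out = remove_gravity_cc(acc, (0, 500))
        assert np.all(out[:, 0] == acc[:, 0]) and np.all(out[:, 1] == acc[:, 1])
        assert out[:, 2].mean() == pytest.approx(0, abs=1e-12)

    def test_walk_segment_recovers_oscillation(self):
        t = np.arange(1280) / 128.0
        osc = 0.8 * np.sin(2 * np.pi * 1.5 * t)
        acc = np.zeros((1280 + 384, 3))
        acc[:, 2] = G
        acc[384:, 2] += osc
        out = remove_gravity_cc(acc, (0, 384))
        np.testing.assert_allclose(out[384:, 2], osc, atol=1e-12)


class TestLowpass:
    def test_dc_gain_is_unity(self):
        x = np.full(1000, 3.7)
        np.testing.assert_allclose(lowpass_filter(x, 10, 128), x, atol=1e-9)

    @pytest.mark.parametrize(
        "f_sig, expected_gain, tol",
        [(2.0, 1.0, 0.01), (10.0, 0.5, 0.05)],  # passband; −3 dB applied twice
    )
    def test_zero_phase_amplitude_response(self, f_sig, expected_gain, tol):
        fs = 128.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * f_sig * t)
        y = lowpass_filter(x, 10.0, fs)
        core = slice(int(2 * fs), int(18 * fs))  # trim filter transients
        gain = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
        assert gain == pytest.approx(expected_gain, rel=tol)

    def test_passband_filtering_is_nearly_idempotent(self, rng):
        """A signal band-limited below fc/4 passes with < 1 % RMS change."""
        fs = 128.0
        t = np.arange(int(30 * fs)) / fs
        x = sum(np.sin(2 * np.pi * f * t + p) for f, p in [(0.7, 0.3), (1.4, 1.1), (2.2, 2.0)])
        y = lowpass_filter(x, 10.0, fs)
        core = slice(int(2 * fs), int(28 * fs))
        rms_ratio = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
        assert rms_ratio == pytest.approx(1.0, abs=0.01)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(100), 64.0, 128.0)

    def test_filtfilt_gain_matches_measured_attenuation(self):
        """The analytic zero-phase gain agrees with filtering a sinusoid."""
        fs, f_sig = 128.0, 6.5
        t = np.arange(int(40 * fs)) / fs
        x = np.cos(2 * np.pi * f_sig * t)
        y = lowpass_filter(x, 10.0, fs)
        core = slice(int(5 * fs), int(35 * fs))
        measured = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
        predicted = filtfilt_gain(np.array([f_sig]), 10.0, fs)[0]
        assert measured == pytest.approx(predicted, rel=1e-3)


class TestFullChain:
    def test_static_invariants_after_alignment(self, noiseless_subject):
        """Aligned static phase: CC acceleration ≈ 0, gyro bias removed."""
        _, _, trial, _ = noiseless_subject
        aligned = g.align_trial(trial)
        i0, i1 = aligned.static_window
        for sensor in aligned.sensors.values():
            assert abs(sensor.acc_anat[i0:i1, 2].mean()) < 0.05
            assert np.all(np.abs(sensor.gyro_anat[i0 + 64 : i1 - 64].mean(axis=0)) < 1e-9)
            np.testing.assert_allclose(sensor.rotation.T @ sensor.rotation, np.eye(3), atol=1e-10)

    def test_chain_is_deterministic(self, noiseless_subject):
        _, _, trial, _ = noiseless_subject
        a1 = g.align_trial(trial)
        a2 = g.align_trial(trial)
        for site in a1.sensors:
            assert np.array_equal(a1.sensors[site].acc_anat, a2.sensors[site].acc_anat)
            assert np.array_equal(a1.sensors[site].gyro_anat, a2.sensors[site].gyro_anat)

    def test_injected_rotation_recovered(self, noiseless_subject):
        """The generator's known sensor tilt is recovered by alignment."""
        _, _, trial, truth = noiseless_subject
        aligned = g.align_trial(trial)
        np.testing.assert_allclose(
            aligned.sensors[g.SensorSite.PELVIS].rotation, truth["rotation"], atol=1e-6
        )
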