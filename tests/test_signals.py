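"""Signal-conditioning unit and property tests.

Expected values are either forced by definition (constant inputs,
axis-aligned gravity), evaluated analytically (filter responses, the 2A/pi
rectified-sine mean), or frozen from independent brute-force oracles
implemented inline (explicit 3-window median, folded-normal statistics).
"""
import numpy as np
import pytest
from scipy import signal as sps

from icumotion.signals import (
    AccelSignal,
    GravitySeries,
    InvalidSignalError,
    OrientationSeries,
    SmaSeries,
    build_epoch_frame,
    calibrate_supine,
    compute_sma,
    compute_tilt_angles,
    design_gravity_filter,
    extract_gravity,
    median_filter3,
    wrap_angle_deg,
)

RATE = 20.0


def make_signal(data, rate=RATE, site="chest_left", start=0.0):
    return AccelSignal(np.asarray(data, dtype=float), rate=rate, site=site, start_offset=start)


def constant_signal(vec, seconds=10.0, rate=RATE):
    n = int(seconds * rate)
    return make_signal(np.tile(np.asarray(vec, dtype=float), (n, 1)), rate=rate)


# ---------------------------------------------------------------------------
# median filter

class TestMedianFilter:
    def test_constant_signal_unchanged(self):
        sig = constant_signal((0.1, 0.1, 0.1), seconds=2)
        out = median_filter3(sig)
        np.testing.assert_array_equal(out.data, sig.data)

    def test_single_spike_removed_with_edge_replication(self):
        data = np.zeros((3, 3))
        data[1, 0] = 10.0
        out = median_filter3(make_signal(data, rate=3))
        np.testing.assert_array_equal(out.data[:, 0], [0.0, 0.0, 0.0])

    def test_matches_bruteforce_window_sort(self, rng):
        data = rng.normal(0, 1, size=(200, 3))
        out = median_filter3(make_signal(data, rate=RATE))
        padded = np.vstack([data[:1], data, data[-1:]])  # edge replication
        expected = np.stack(
            [np.sort(padded[i:i + 3], axis=0)[1] for i in range(200)]
        )
        np.testing.assert_allclose(out.data, expected)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidSignalError):
            median_filter3(make_signal(np.zeros((2, 3)), rate=2))


# ---------------------------------------------------------------------------
# gravity extraction

class TestExtractGravity:
    def test_dc_passthrough(self):
        sig = constant_signal((0.0, 0.0, 1.0), seconds=60)
        grav = extract_gravity(sig)
        assert np.max(np.abs(grav.data - sig.data)) < 1e-6

    def test_dc_gain_of_design_is_unity(self):
        b, a = design_gravity_filter(RATE)
        _, h = sps.freqz(b, a, worN=[0.0], fs=RATE)
        assert abs(abs(h[0]) - 1.0) < 1e-9

    def test_2hz_ripple_attenuated_20db(self):
        t = np.arange(0, 60, 1 / RATE)
        ripple = 0.5 * np.sin(2 * np.pi * 2.0 * t)
        data = np.column_stack([np.zeros_like(t), np.zeros_like(t), 1.0 + ripple])
        grav = extract_gravity(make_signal(data))
        mid = slice(int(5 * RATE), int(55 * RATE))
        assert np.allclose(grav.data[mid, 2], 1.0, atol=0.05)
        out_amp = np.std(grav.data[mid, 2] - 1.0)
        in_amp = np.std(ripple[mid])
        # analytic forward-backward response at 2 Hz for the 2nd-order design
        w, h = sps.freqz(*design_gravity_filter(RATE), worN=[2.0], fs=RATE)
        expected_gain = abs(h[0]) ** 2
        assert out_amp / in_amp < 0.1  # >= 20 dB
        assert np.isclose(out_amp / in_amp, expected_gain, rtol=0.2)

    def test_slow_drift_passes(self):
        # 0.01 Hz is deep inside the passband: < 5% amplitude error
        t = np.arange(0, 300, 1 / RATE)
        drift = 0.1 * np.sin(2 * np.pi * 0.01 * t)
        data = np.column_stack([np.zeros_like(t), np.zeros_like(t), 1.0 + drift])
        grav = extract_gravity(make_signal(data))
        mid = slice(int(30 * RATE), int(270 * RATE))
        err = np.max(np.abs(grav.data[mid, 2] - data[mid, 2]))
        assert err < 0.05 * 0.1

    def test_cutoff_at_nyquist_rejected(self):
        sig = constant_signal((0, 0, 1), seconds=2)
        with pytest.raises(ValueError):
            extract_gravity(sig, cutoff_hz=10.0)


# ---------------------------------------------------------------------------
# tilt angles

class TestTiltAngles:
    @pytest.mark.parametrize(
        "gvec, theta, psi, phi",
        [
            ((0.0, 0.0, 1.0), 0.0, 0.0, 90.0),       # supine, anterior axis up
            ((1.0, 0.0, 0.0), 0.0, 0.0, 0.0),        # standing, longitudinal up
            ((0.0, np.sqrt(0.5), np.sqrt(0.5)), 45.0, 45.0, 90.0),
        ],
    )
    def test_axis_aligned_and_diagonal_cases(self, gvec, theta, psi, phi):
        grav = GravitySeries(np.tile(gvec, (40, 1)), rate=RATE)
        ang = compute_tilt_angles(grav)
        np.testing.assert_allclose(ang.theta, theta, atol=1e-9)
        np.testing.assert_allclose(ang.psi, psi, atol=1e-9)
        np.testing.assert_allclose(ang.phi, phi, atol=1e-9)
        assert not ang.corrected

    def test_unit_vector_recovery_property(self, rng):
        """theta/phi invert exactly back to the gravity direction."""
        v = rng.normal(size=(1000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        ang = compute_tilt_angles(GravitySeries(v, rate=RATE))
        phi = np.radians(ang.phi)
        theta = np.radians(ang.theta)
        rebuilt = np.column_stack([
            np.cos(phi),
            np.sin(phi) * np.sin(theta),
            np.sin(phi) * np.cos(theta),
        ])
        assert np.max(np.abs(rebuilt - v)) < 1e-9

    def test_zero_magnitude_sample_flagged_and_propagated(self):
        data = np.tile((0.0, 0.0, 1.0), (40, 1))
        data[10] = 0.0
        ang = compute_tilt_angles(GravitySeries(data, rate=RATE))
        assert ang.flagged is not None and ang.flagged[10]
        assert ang.phi[10] == ang.phi[9]


# ---------------------------------------------------------------------------
# baseline correction

def angles_from_constant(theta, psi, phi, seconds=12.0):
    n = int(seconds * RATE)
    return OrientationSeries(
        theta=np.full(n, float(theta)), psi=np.full(n, float(psi)),
        phi=np.full(n, float(phi)), rate=RATE,
    )


class TestCalibrateSupine:
    def test_already_calibrated_identity(self):
        ang = angles_from_constant(0, 0, 90)
        offs, corr = calibrate_supine(ang, (2.0, 8.0))
        assert (offs.d_theta, offs.d_psi, offs.d_phi) == (0.0, 0.0, 0.0)
        np.testing.assert_array_equal(corr.phi, ang.phi)
        assert corr.corrected

    def test_constant_offset_removed(self):
        ang = angles_from_constant(3, -2, 87)
        offs, corr = calibrate_supine(ang, (2.0, 8.0))
        assert np.isclose(offs.d_theta, 3) and np.isclose(offs.d_psi, -2)
        assert np.isclose(offs.d_phi, -3)
        np.testing.assert_allclose(
            [corr.theta.mean(), corr.psi.mean(), corr.phi.mean()], [0, 0, 90], atol=1e-12)

    def test_noisy_window_mean_within_sampling_error(self, rng):
        n = int(20 * RATE)
        ang = OrientationSeries(
            theta=5 + rng.normal(0, 0.5, n), psi=1 + rng.normal(0, 0.5, n),
            phi=92 + rng.normal(0, 0.5, n), rate=RATE)
        window = (2.0, 12.0)  # 10 s -> SE of mean ~ 0.5/sqrt(200) = 0.035 deg
        _, corr = calibrate_supine(ang, window)
        mask = (corr.times >= window[0]) & (corr.times <= window[1])
        assert abs(corr.theta[mask].mean()) < 0.1
        assert abs(corr.psi[mask].mean()) < 0.1
        assert abs(corr.phi[mask].mean() - 90) < 0.1

    def test_idempotent(self):
        ang = angles_from_constant(7, 3, 95)
        _, corr = calibrate_supine(ang, (2.0, 8.0))
        offs2, _ = calibrate_supine(corr, (2.0, 8.0))
        assert abs(offs2.d_theta) < 1e-12
        assert abs(offs2.d_psi) < 1e-12
        assert abs(offs2.d_phi) < 1e-12

    def test_window_outside_series_rejected(self):
        ang = angles_from_constant(0, 0, 90, seconds=5)
        with pytest.raises(InvalidSignalError):
            calibrate_supine(ang, (2.0, 30.0))

    def test_theta_rewrapped_into_range(self):
        ang = angles_from_constant(-170, 0, 90)
        ang.theta[-1] = 175.0  # wraps to -165 after subtracting -170... i.e. 345 -> -15
        _, corr = calibrate_supine(ang, (2.0, 8.0))
        assert np.all(corr.theta > -180.0) and np.all(corr.theta <= 180.0)
        assert np.isclose(corr.theta[-1], -15.0)

    def test_wrap_angle_halfopen_convention(self):
        assert wrap_angle_deg(180.0) == 180.0
        assert wrap_angle_deg(-180.0) == 180.0
        assert np.isclose(wrap_angle_deg(190.0), -170.0)


# ---------------------------------------------------------------------------
# SMA

class TestComputeSma:
    @staticmethod
    def gravity_like(sig):
        return GravitySeries(sig.data.copy(), rate=sig.rate, site=sig.site,
                             start_offset=sig.start_offset)

    def test_zero_body_acceleration(self):
        sig = constant_signal((0.2, -0.3, 0.9), seconds=10)
        sma = compute_sma(sig, self.gravity_like(sig))
        np.testing.assert_array_equal(sma.values, 0.0)
        assert np.all(sma.values >= 0)

    def test_rectified_sine_mean(self):
        # mean of |A sin| over whole cycles is 2A/pi
        a = 0.1
        t = np.arange(0, 30, 1 / RATE)
        body = a * np.sin(2 * np.pi * 2.0 * t)
        grav_data = np.tile((0.0, 0.0, 1.0), (len(t), 1))
        raw = make_signal(grav_data + np.column_stack([body, 0 * t, 0 * t]))
        grav = GravitySeries(grav_data, rate=RATE)
        sma = compute_sma(raw, grav)
        expected = 2 * a / np.pi
        np.testing.assert_allclose(sma.values, expected, rtol=0.01)

    def test_white_noise_stays_below_rest_threshold(self, rng):
        # folded-normal mean per axis sigma*sqrt(2/pi); 3 axes ~ 0.012 g
        sigma = 0.005
        t = np.arange(0, 120, 1 / RATE)
        grav_data = np.tile((0.0, 0.0, 1.0), (len(t), 1))
        raw = make_signal(grav_data + rng.normal(0, sigma, size=(len(t), 3)))
        sma = compute_sma(raw, GravitySeries(grav_data, rate=RATE))
        assert np.mean(sma.values < 0.03) >= 0.99
        assert np.isclose(np.mean(sma.values), 3 * sigma * np.sqrt(2 / np.pi), rtol=0.1)

    def test_shift_invariance(self, rng):
        body = rng.normal(0, 0.05, size=(300, 3))
        grav_data = np.tile((0.0, 0.0, 1.0), (300, 1))
        raw = make_signal(grav_data + body)
        base = compute_sma(raw, GravitySeries(grav_data, rate=RATE))
        shift = np.array([0.3, -1.2, 4.5])
        shifted = compute_sma(
            make_signal(grav_data + body + shift),
            GravitySeries(grav_data + shift, rate=RATE))
        np.testing.assert_allclose(shifted.values, base.values, atol=1e-12)

    def test_scaling_body_acceleration_scales_sma(self, rng):
        body = rng.normal(0, 0.05, size=(300, 3))
        grav_data = np.tile((0.0, 0.0, 1.0), (300, 1))
        k = 3.7
        base = compute_sma(make_signal(grav_data + body), GravitySeries(grav_data, rate=RATE))
        scaled = compute_sma(make_signal(grav_data + k * body), GravitySeries(grav_data, rate=RATE))
        np.testing.assert_allclose(scaled.values, k * base.values, rtol=1e-12)

    def test_output_is_5hz_with_centered_windows(self):
        sig = constant_signal((0, 0, 1), seconds=10)
        sma = compute_sma(sig, self.gravity_like(sig))
        np.testing.assert_allclose(np.diff(sma.times), 0.2)
        assert np.isclose(sma.times[0], 0.5)  # center of the first 1 s window

    def test_mismatched_lengths_rejected(self):
        sig = constant_signal((0, 0, 1), seconds=10)
        grav = GravitySeries(sig.data[:-5].copy(), rate=RATE)
        with pytest.raises(InvalidSignalError):
            compute_sma(sig, grav)


# ---------------------------------------------------------------------------
# epoch frame

def orientation_and_sma(seconds, start=0.0, phi=90.0):
    n = int(seconds * RATE)
    ang = OrientationSeries(
        theta=np.zeros(n), psi=np.zeros(n), phi=np.full(n, phi),
        rate=RATE, start_offset=start)
    m = int((seconds - 1) * 5)
    sma = SmaSeries(values=np.full(m, 0.01), times=start + 0.5 + 0.2 * np.arange(m))
    return ang, sma


class TestEpochFrame:
    def test_full_overlap_epoch_count(self):
        frame = build_epoch_frame(orientation_and_sma(10), orientation_and_sma(10))
        assert len(frame) == 50  # 10 s at 5 Hz
        np.testing.assert_allclose(np.diff(frame["epoch_s"]), 0.2)

    def test_offset_start_truncates_to_overlap(self):
        chest = orientation_and_sma(10, start=1.0)
        thigh = orientation_and_sma(10, start=0.0)
        frame = build_epoch_frame(chest, thigh)
        assert len(frame) == 45  # 9 s overlap at 5 Hz
        assert frame["epoch_s"].iloc[0] == pytest.approx(1.1)

    def test_constant_inputs_pass_through(self):
        chest = orientation_and_sma(10, phi=42.0)
        thigh = orientation_and_sma(10, phi=87.0)
        frame = build_epoch_frame(chest, thigh)
        assert np.all(frame["phi_mc"] == 42.0)
        assert np.all(frame["phi_t"] == 87.0)
        assert np.all(frame["sma_mc"] == 0.01)

    def test_disjoint_series_rejected(self):
        chest = orientation_and_sma(5, start=100.0)
        thigh = orientation_and_sma(5, start=0.0)
        with pytest.raises(InvalidSignalError):
            build_epoch_frame(chest, thigh)
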