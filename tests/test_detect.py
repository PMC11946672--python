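"""Savitzky-Golay velocity, adaptive thresholding and event extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gazerig.detect import (
    NoiseEstimate,
    VelocitySignal,
    detect_saccades,
    estimate_noise_sigma,
    extract_fixations,
    saccade_metrics,
    sg_velocity,
)
from gazerig.geometry import deg_to_px
from gazerig.pipeline import analyze_stream
from gazerig.rig import CALIBRATION_GRID_13, SampleStream, TrialPlan, simulate_trial

from conftest import brute_force_runs


def make_stream(x_px, y_px=None, pupil=None):
    n = len(x_px)
    return SampleStream(
        t_ms=np.arange(n, dtype=np.int64),
        x_px=np.asarray(x_px, float),
        y_px=np.asarray(y_px, float) if y_px is not None else np.full(n, 540.0),
        pupil_au=np.asarray(pupil, float) if pupil is not None else np.full(n, 2888.94),
    )


class TestSgVelocity:
    def test_constant_position_zero_velocity(self):
        v = sg_velocity(make_stream(np.full(100, 960.0)))
        np.testing.assert_allclose(v.vx, 0.0, atol=1e-9)
        np.testing.assert_allclose(v.v, 0.0, atol=1e-9)

    def test_linear_ramp_exact_on_interior(self, screen):
        """A ramp of k deg/ms differentiates to exactly 1000k deg/s."""
        k = 0.003  # deg per ms
        t = np.arange(200)
        x = 960.0 + deg_to_px(k * t, screen)
        v = sg_velocity(make_stream(x), screen=screen)
        np.testing.assert_allclose(v.vx[3:-3], 1000.0 * k, rtol=1e-6)

    def test_cubic_exact_against_analytic(self, screen):
        """SG of order 3 reproduces the derivative of a cubic exactly."""
        t_s = np.arange(300) / 1000.0
        theta = 2.0 * t_s**3 - 0.5 * t_s**2 + 0.3 * t_s
        dtheta = 6.0 * t_s**2 - 1.0 * t_s + 0.3
        x = 960.0 + deg_to_px(theta, screen)
        v = sg_velocity(make_stream(x), screen=screen)
        np.testing.assert_allclose(v.vx[3:-3], dtheta[3:-3], atol=1e-7)

    def test_too_short_stream_raises(self):
        with pytest.raises(ValueError):
            sg_velocity(make_stream(np.zeros(5)))

    def test_offset_invariance_and_scaling(self, rng):
        x = 960.0 + np.cumsum(rng.normal(0, 0.2, 500))
        v1 = sg_velocity(make_stream(x))
        v2 = sg_velocity(make_stream(x + 40.0))
        # adding a constant pixel offset barely changes the angular velocity
        np.testing.assert_allclose(v1.vx, v2.vx, atol=0.5)


class TestNoiseEstimate:
    def test_gaussian_sd_recovered(self, rng):
        s = 8.0
        v = VelocitySignal(np.arange(10_000), rng.normal(0, s, 10_000), np.zeros(10_000))
        est = estimate_noise_sigma(v)
        # |N(0,s)| has SD s*sqrt(1-2/pi); the estimator sees |v|
        expected = s * np.sqrt(1 - 2 / np.pi)
        assert est.sigma_x == pytest.approx(expected, rel=0.10)
        assert est.eta_x == pytest.approx(3 * est.sigma_x)

    def test_robust_to_sparse_saccade_peaks(self, rng):
        base = rng.normal(0, 8.0, 20_000)
        spiky = base.copy()
        spiky[::500] = 400.0  # sparse large peaks
        e0 = estimate_noise_sigma(VelocitySignal(np.arange(base.size), base, np.zeros_like(base)))
        e1 = estimate_noise_sigma(VelocitySignal(np.arange(base.size), spiky, np.zeros_like(base)))
        assert abs(e1.sigma_x - e0.sigma_x) / e0.sigma_x < 0.05

    def test_zero_signal_floored(self):
        v = VelocitySignal(np.arange(100), np.zeros(100), np.zeros(100))
        est = estimate_noise_sigma(v)
        assert est.sigma_x == pytest.approx(1e-6)
        assert est.eta > 0


class TestDetectSaccades:
    def test_matches_brute_force_on_random_signals(self, rng):
        """Equality with an exhaustive run-scan oracle on 1000 random
        small velocity signals."""
        noise = NoiseEstimate(sigma_x=10.0, sigma_y=8.0)
        for _ in range(1000):
            n = rng.integers(10, 60)
            vx = rng.choice([0.0, 50.0], n, p=[0.6, 0.4])
            vy = rng.normal(0, 5.0, n)
            sig = VelocitySignal(np.arange(n), vx, vy)
            got = [(e.onset_ms, e.offset_ms + 1) for e in detect_saccades(sig, noise)]
            assert got == brute_force_runs(sig.v > noise.eta, 6)

    @given(st.lists(st.booleans(), min_size=1, max_size=80), st.integers(1, 8))
    def test_runs_property(self, flags, min_run):
        v = np.where(flags, 100.0, 0.0)
        sig = VelocitySignal(np.arange(len(flags)), v, np.zeros(len(flags)))
        noise = NoiseEstimate(sigma_x=10.0, sigma_y=10.0)
        got = [(e.onset_ms, e.offset_ms + 1) for e in detect_saccades(sig, noise, min_run=min_run)]
        assert got == brute_force_runs(np.asarray(flags), min_run)

    def test_five_sample_burst_not_detected(self):
        v = np.zeros(50)
        v[20:25] = 500.0  # exactly five supra-threshold samples
        sig = VelocitySignal(np.arange(50), v, np.zeros(50))
        assert detect_saccades(sig, NoiseEstimate(sigma_x=10.0, sigma_y=10.0)) == []
        v[25] = 500.0  # six samples: detected
        assert len(detect_saccades(sig, NoiseEstimate(sigma_x=10.0, sigma_y=10.0))) == 1

    def test_constant_fixation_yields_nothing(self):
        sig = VelocitySignal(np.arange(100), np.zeros(100), np.zeros(100))
        assert detect_saccades(sig, NoiseEstimate(sigma_x=1.0, sigma_y=1.0)) == []

    def test_grid_recall_is_complete(self, screen):
        """Every programmed jump of a default-noise grid trial is found."""
        plan = TrialPlan(0, "dark", CALIBRATION_GRID_13)
        stream = simulate_trial(plan, motion_seed=21, noise_seed=22)
        _, _, events, _ = analyze_stream(stream, screen)
        assert len(events) == len(CALIBRATION_GRID_13) - 1


class TestSaccadeMetricsAndFixations:
    def test_noiseless_horizontal_move_metrics(self, screen):
        plan = TrialPlan(0, "dark", np.array([[500.0, 540.0], [1084.0, 540.0]]))  # ~10 deg
        stream = simulate_trial(plan, noise_sd_deg=0.0, pupil_noise_au=0.0,
                                motion_seed=1, noise_seed=1)
        vel, noise, events, fix = analyze_stream(stream, screen)
        assert len(events) == 1
        ev = events[0]
        true_amp = abs(np.subtract(*np.degrees(np.arctan(
            (np.array([500.0, 1084.0]) - 960.0) * screen.pitch_mm / 927.0))))
        assert ev.amplitude_deg == pytest.approx(true_amp, abs=0.4)  # quantization + clipping
        assert ev.peak_velocity_dps == pytest.approx(np.max(vel.v), abs=1e-9)
        assert -5 < ev.direction_deg < 5  # rightward

    def test_upward_move_direction(self, screen):
        plan = TrialPlan(0, "dark", np.array([[960.0, 800.0], [960.0, 300.0]]))
        stream = simulate_trial(plan, noise_sd_deg=0.0, pupil_noise_au=0.0,
                                motion_seed=1, noise_seed=1)
        _, _, events, _ = analyze_stream(stream, screen)
        assert events[0].direction_deg == pytest.approx(90.0, abs=2.0)

    def test_bell_shaped_event_velocity(self, screen):
        """Within each detected saccade of a noiseless single-axis
        recording the speed rises to a single maximum and falls again
        (oblique moves with unequal axis durations are legitimately
        multi-phased, so the bell shape is asserted on axis-pure moves;
        a small tolerance absorbs SG ringing at the profile corners)."""
        plan = TrialPlan(0, "dark", np.array([[300.0, 540.0], [900.0, 540.0], [350.0, 540.0]]))
        stream = simulate_trial(plan, noise_sd_deg=0.0, pupil_noise_au=0.0,
                                motion_seed=2, noise_seed=2)
        vel, _, events, _ = analyze_stream(stream, screen)
        assert len(events) == 2
        for ev in events:
            seg = vel.v[ev.onset_ms : ev.offset_ms + 1]
            k = int(np.argmax(seg))
            assert np.all(np.diff(seg[: k + 1]) >= -0.5)
            assert np.all(np.diff(seg[k:]) <= 0.5)

    def test_fixation_windows_complete_and_disjoint(self, screen):
        plan = TrialPlan(0, "dark", CALIBRATION_GRID_13)
        stream = simulate_trial(plan, motion_seed=5, noise_seed=6)
        _, _, events, fix = analyze_stream(stream, screen)
        assert len(fix) == 13
        for w in fix:
            for ev in events:
                assert w.end_ms <= ev.onset_ms or w.start_ms > ev.offset_ms

    def test_guard_trims_window_edges(self):
        stream = simulate_trial(TrialPlan(0, "d", CALIBRATION_GRID_13[:3]),
                                motion_seed=1, noise_seed=1)
        vel = sg_velocity(stream)
        noise = estimate_noise_sigma(vel)
        events = detect_saccades(vel, noise)
        f20 = extract_fixations(stream, events, guard_ms=20)
        f0 = extract_fixations(stream, events, guard_ms=0)
        assert all(a.n_samples <= b.n_samples for a, b in zip(f20, f0))
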