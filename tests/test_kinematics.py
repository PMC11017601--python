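"""The ten mobility parameters: integration oracles, closed forms, recovery."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid
from scipy.signal import detrend

import tugkit as tk
from tugkit.kinematics import (
    IntegrationConfig,
    double_integrate_fft,
    excursion_p90,
    jerk_range,
    pendulum_displacement,
    timing_parameters,
    transition_power,
)
from tugkit.signal_model import BodyFrameSignals, G

RATE = 100.0
PROTOCOL_EVENTS = (30.0, 31.0, 34.0, 35.0, 38.0, 41.0, 43.0, 43.0, 46.0)


def _body(ml=None, ap=None, cc=None, n=None, rate=RATE):
    n = n if n is not None else len(next(x for x in (ml, ap, cc) if x is not None))
    zero = np.zeros(n)
    return BodyFrameSignals(
        ML=ml if ml is not None else zero.copy(),
        AP=ap if ap is not None else zero.copy(),
        CC=cc if cc is not None else zero.copy(),
        yaw_rate=zero.copy(),
        rate=rate,
    )


class TestDoubleIntegration:
    def test_sinusoid_amplitude_recovered(self):
        # acc of a 10 mm, 1 Hz displacement sinusoid
        t = np.arange(0, 10, 1 / RATE)
        amp_mm, f = 10.0, 1.0
        acc = -(amp_mm / 1000) * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t)
        disp = double_integrate_fft(acc, RATE)
        assert np.abs(disp).max() == pytest.approx(amp_mm, rel=0.01)

    def test_zero_acceleration_gives_zero_displacement(self):
        np.testing.assert_allclose(double_integrate_fft(np.zeros(500), RATE), 0.0)

    def test_agrees_with_trapezoid_detrend_oracle(self):
        """Band-limited (0.3-5 Hz) noise: FFT route vs cumulative trapezoid."""
        rng = np.random.default_rng(21)
        n = 3000
        spec = np.fft.rfft(rng.normal(0, 1, n))
        f = np.fft.rfftfreq(n, 1 / RATE)
        spec[(f < 0.3) | (f > 5.0)] = 0.0
        acc = np.fft.irfft(spec, n=n)
        fft_mm = double_integrate_fft(acc, RATE, highpass=0.1)
        vel = cumulative_trapezoid(acc, dx=1 / RATE, initial=0.0)
        vel -= vel.mean()
        oracle = 1000 * detrend(cumulative_trapezoid(vel, dx=1 / RATE, initial=0.0))
        # both reconstructions are defined modulo the integration-constant
        # line; compare after removing each route's own fitted line
        rms_diff = np.sqrt(np.mean(detrend(fft_mm - oracle) ** 2))
        assert rms_diff < 0.02 * np.sqrt(np.mean(oracle**2))

    def test_scaling_linearity(self):
        rng = np.random.default_rng(2)
        acc = rng.normal(0, 1, 600)
        d1 = double_integrate_fft(acc, RATE)
        d3 = double_integrate_fft(3.0 * acc, RATE)
        np.testing.assert_allclose(d3, 3.0 * d1, atol=1e-9)

    def test_empty_segment_rejected(self):
        with pytest.raises(tk.DataError):
            double_integrate_fft(np.array([]), RATE)
        with pytest.raises(tk.DataError):
            double_integrate_fft(np.zeros(50), RATE)  # < 1 s


class TestExcursion:
    def test_constant_series_zero(self):
        assert excursion_p90(np.full(100, 4.2)) == 0.0

    def test_sinusoid_closed_form(self):
        # 90th-percentile excursion of A sin(u) is A sin(0.9 pi / 2) ~ 0.988 A
        u = np.linspace(0, 2 * np.pi, 100_000, endpoint=False)
        a = 7.3
        assert excursion_p90(a * np.sin(u)) == pytest.approx(
            a * np.sin(0.45 * np.pi), rel=0.01
        )

    def test_ramp_enumeration(self):
        assert excursion_p90(np.linspace(0.0, 10.0, 11)) == pytest.approx(4.5)

    def test_translation_invariant_scale_equivariant(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 2, 500)
        base = excursion_p90(x)
        assert excursion_p90(x + 123.4) == pytest.approx(base, abs=1e-9)
        assert excursion_p90(2.5 * x) == pytest.approx(2.5 * base, rel=1e-12)


class TestStanceDisplacement:
    def test_zero_sway_gives_zero(self, subject):
        n = 3000
        body = _body(n=n)
        body.CC[:] = -G
        ev = tk.apply_manual_events(PROTOCOL_EVENTS)
        ml, ap = tk.stance_displacement(body, ev, subject)
        assert ml == pytest.approx(0.0, abs=1e-6)
        assert ap == pytest.approx(0.0, abs=1e-6)

    def test_pitch_oscillation_recovers_pendulum_geometry(self):
        """theta0 = 0.5 deg on a 0.9 m pendulum -> AP excursion ~ L * theta0."""
        L = 0.9
        theta0 = np.radians(0.5)
        f = 0.3
        t = np.arange(0, 30, 1 / RATE)
        x = L * theta0 * np.sin(2 * np.pi * f * t)  # COM displacement
        acc = np.gradient(np.gradient(x, 1 / RATE), 1 / RATE) + (G / L) * x
        disp = pendulum_displacement(acc, RATE, L)
        expected = 0.988 * L * theta0  # sinusoid quantile of the 7.85 mm amplitude
        assert excursion_p90(1000 * disp) == pytest.approx(1000 * expected, rel=0.10)

    def test_pure_tone_ml_sway_recovered(self, tone_profile, subject):
        """5 mm COM sway sinusoid at 0.3 Hz -> MLDisp within 10% of 0.988*5."""
        rec, gt = tk.simulate_test(tone_profile, subject, seed=0)
        params = tk.compute_all_parameters(rec, gt.events, subject)
        assert params.MLDisp == pytest.approx(0.988 * 5.0, rel=0.10)

    def test_short_stance_rejected(self, subject):
        body = _body(n=3000)
        ev = tk.apply_manual_events(PROTOCOL_EVENTS, cue_time=30.0)
        short = dataclasses.replace(body)
        with pytest.raises(tk.DataError, match="short"):
            tk.stance_displacement(short, ev, subject, start_time=25.0)


class TestGaitRanges:
    def test_identical_phases_average_to_single_value(self, subject):
        n = 4700
        t = np.arange(n) / RATE
        cc = np.zeros(n)
        for a, b in ((31.0, 34.0), (43.0, 46.0)):
            m = (t >= a) & (t < b)
            cc[m] = -0.025 * (2 * np.pi * 2.0) ** 2 * np.sin(2 * np.pi * 2.0 * (t[m] - a))
        body = _body(cc=cc)
        ev = tk.apply_manual_events(PROTOCOL_EVENTS)
        cc_range, _ = tk.gait_ranges(body, ev)
        # both phases identical -> mean equals either; 25 mm amplitude recovered
        assert cc_range == pytest.approx(2 * 0.988 * 25.0, rel=0.10)

    def test_generator_cc_oscillation_recovered(self, quiet_profile, subject):
        rec, gt = tk.simulate_test(quiet_profile, subject, seed=2)
        params = tk.compute_all_parameters(rec, gt.events, subject)
        assert params.CCrange == pytest.approx(gt.true_parameters.CCrange, rel=0.10)

    def test_stroke_walks_wider_and_flatter_than_healthy(self, subject):
        """Paired seeds: stroke MLrange above healthy, CCrange below."""
        wins_ml = wins_cc = n = 20
        ok_ml = ok_cc = 0
        for seed in range(n):
            out = {}
            for name, prof in (("h", tk.healthy_profile()), ("s", tk.stroke_profile())):
                rec, gt = tk.simulate_test(prof, subject, seed=seed)
                out[name] = tk.compute_all_parameters(rec, gt.events, subject)
            ok_ml += out["s"].MLrange > out["h"].MLrange
            ok_cc += out["s"].CCrange < out["h"].CCrange
        assert ok_ml >= 19 and ok_cc >= 19  # >= 95% of paired seeds

    def test_missing_walk_phase_rejected(self, subject):
        body = _body(n=4700)
        ev = tk.apply_manual_events((30, 31, 31.5, 35, 38, 41, 43, 43, 43.5))
        with pytest.raises(tk.DataError, match="walk"):
            tk.gait_ranges(body, ev)


class TestTransitionPower:
    def test_zero_vertical_excursion_is_zero_power(self, subject):
        body = _body(n=1000)
        body.CC[:] = -G
        assert transition_power(body, (0, 400), subject) == pytest.approx(0.0, abs=1e-6)

    def test_stated_formula_arithmetic(self):
        """m = 70 kg, dh = 0.25 m, duration = 1.75 s -> P = 98.1 W."""
        subj = tk.SubjectProfile(height=1.75, weight=70.0)
        rate, T = 100.0, 1.75
        n = int(T * rate)
        tau = np.arange(n) / rate
        # cycloidal descent of exactly 0.25 m over the segment
        u = tau / T
        acc = -0.25 * (2 * np.pi / T**2) * np.sin(2 * np.pi * u)
        body = _body(cc=acc - G)
        p = transition_power(body, (0, n), subj)
        assert p == pytest.approx(70.0 * G * 0.25 / 1.75, rel=0.02)
        assert 70.0 * G * 0.25 / 1.75 == pytest.approx(98.1, abs=0.1)

    def test_linear_in_mass(self, subject):
        rng = np.random.default_rng(3)
        body = _body(cc=rng.normal(0, 0.5, 600) - G)
        heavy = dataclasses.replace(subject, weight=2 * subject.weight)
        p1 = transition_power(body, (0, 600), subject)
        p2 = transition_power(body, (0, 600), heavy)
        assert p2 == pytest.approx(2 * p1, rel=1e-9)

    def test_time_shift_invariant(self, subject):
        n = 400
        tau = np.arange(n) / RATE
        acc = -0.2 * (2 * np.pi / 4.0**2) * np.sin(2 * np.pi * tau / 4.0)
        cc = np.concatenate([np.zeros(300), acc, np.zeros(300)]) - G
        body = _body(cc=cc)
        p1 = transition_power(body, (300, 300 + n), subject)
        cc2 = np.concatenate([np.zeros(600), acc]) - G
        p2 = transition_power(_body(cc=cc2), (600, 600 + n), subject)
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_too_short_segment_rejected(self, subject):
        body = _body(n=100)
        with pytest.raises(tk.DataError, match="short"):
            transition_power(body, (0, 20), subject)


class TestJerk:
    def test_constant_acceleration_zero_jerk(self):
        body = _body(cc=np.full(500, -G))
        assert jerk_range(body, (0, 500)) == pytest.approx(0.0, abs=1e-9)

    def test_sinusoidal_magnitude_closed_form(self):
        """|acc| = A sin(2 pi f t): jerk range = 2 * 2 pi f A within 2%."""
        f, a = 2.0, 1.0
        t = np.arange(0, 5, 1 / RATE)
        mag = a * np.sin(2 * np.pi * f * t) + 5.0  # keep magnitude positive
        body = _body(cc=-mag)  # magnitude equals |CC|
        r = jerk_range(body, (0, len(t)))
        assert r == pytest.approx(2 * 2 * np.pi * f * a, rel=0.02)

    def test_cubic_polynomial_derivative_oracle(self):
        t = np.arange(0, 4, 1 / RATE)
        mag = 0.5 * t**3 - 2 * t**2 + 3 * t + 10.0
        body = _body(cc=-mag)
        jerk_true = 1.5 * t**2 - 4 * t + 3
        r = jerk_range(body, (0, len(t)))
        expected = jerk_true.max() - jerk_true.min()
        assert r == pytest.approx(expected, rel=0.01)

    def test_too_short_segment_rejected(self):
        with pytest.raises(tk.DataError):
            jerk_range(_body(n=10), (0, 2))


class TestTiming:
    def test_protocol_arithmetic(self):
        ev = tk.apply_manual_events(PROTOCOL_EVENTS)
        total, reaction = timing_parameters(ev)
        assert total == pytest.approx(3 + 3 + 2 + 3)
        assert reaction == pytest.approx(1.0)

    def test_coincident_t6_t7_contributes_zero(self):
        ev = tk.apply_manual_events((30, 31, 34, 35, 38, 41, 43, 44, 47))
        total_pause, _ = timing_parameters(ev)
        ev2 = tk.apply_manual_events(PROTOCOL_EVENTS)
        total_merge, _ = timing_parameters(ev2)
        assert total_pause == total_merge  # walk-back split is 3 s either way


class TestFullPipeline:
    def test_all_parameters_finite_and_nonnegative(self, subject):
        rec, gt = tk.simulate_test(tk.healthy_profile(), subject, seed=7)
        params = tk.compute_all_parameters(rec, gt.events, subject)
        for value in params.as_dict().values():
            assert np.isfinite(value) and value >= 0

    def test_noise_free_ground_truth_recovery(self, quiet_profile, subject):
        """End-to-end: every parameter within 10% (times within 0.2 s)."""
        rec, gt = tk.simulate_test(quiet_profile, subject, seed=5)
        params = tk.compute_all_parameters(rec, gt.events, subject)
        truth = gt.true_parameters
        for key in ("MLDisp", "APDisp", "CCrange", "MLrange",
                    "RangeJerkSit", "RangeJerkStand", "PturnSit", "Pstand"):
            assert getattr(params, key) == pytest.approx(
                getattr(truth, key), rel=0.10
            ), key
        assert params.total_time == pytest.approx(truth.total_time, abs=0.2)
        assert params.reaction_time == pytest.approx(truth.reaction_time, abs=0.2)

    def test_invalid_integration_config_rejected(self):
        with pytest.raises(tk.ParameterError):
            IntegrationConfig(detrend="cubic")
        with pytest.raises(tk.ParameterError):
            IntegrationConfig(jerk_on="rms")
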