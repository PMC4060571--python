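"""Identification pipeline: cycle averaging, harmonic regression, SOPDT fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eaafes import (
    BodePoint,
    HarmonicFit,
    SOPDTModel,
    analytic_response,
    bode_assemble,
    fit_gain_slope,
    fit_sopdt,
    frequency_grid,
    harmonic_fit,
    identify,
    run_protocol,
    steady_cycle_average,
    sweep_sinusoid,
)
from eaafes.plant import ForceTrace
from eaafes.subject import TrialSet, VirtualSubject


def _trialset(cycles: np.ndarray, T: float, n_trials: int = 1, noise_sd=0.0, rng=None):
    """Build a TrialSet whose post-onset record is the given per-cycle matrix."""
    trace = sweep_sinusoid(T, n_cycles=cycles.shape[0])
    f_clean = np.concatenate([np.zeros(trace.onset_index), cycles.ravel()])
    trials = []
    for _ in range(n_trials):
        noise = rng.normal(0, noise_sd, f_clean.size) if noise_sd else 0.0
        trials.append(ForceTrace(trace.t, f_clean + noise, trace.sample_rate))
    return TrialSet(trials=trials, trace=trace, period=T, kind="sweep")


class TestSteadyCycleAverage:
    def test_identical_cycles_average_to_one(self):
        T = 0.2
        one = np.sin(2 * np.pi * np.arange(200) / 200)
        ts = _trialset(np.tile(one, (10, 1)), T)
        np.testing.assert_allclose(steady_cycle_average(ts), one, atol=1e-12)

    def test_window_ignores_transient_and_tail_cycles(self):
        T = 0.2
        one = np.cos(2 * np.pi * np.arange(200) / 200)
        cycles = np.tile(one, (10, 1))
        ref = steady_cycle_average(_trialset(cycles.copy(), T))
        cycles[[0, 1, 8, 9]] += 17.0  # corrupt cycles 1, 2, 9, 10 (1-based)
        assert np.array_equal(steady_cycle_average(_trialset(cycles, T)), ref)

    def test_noise_variance_shrinks_by_trials_times_cycles(self, rng):
        """Averaged-cycle noise variance is sigma^2 / (n_trials * 6)."""
        T, sd, n_trials = 0.2, 1.0, 3
        reps = [
            steady_cycle_average(
                _trialset(np.zeros((10, 200)), T, n_trials=n_trials, noise_sd=sd, rng=rng)
            )
            for _ in range(40)
        ]
        var = float(np.var(np.concatenate(reps)))
        assert var == pytest.approx(sd**2 / (n_trials * 6), rel=0.1)

    def test_too_few_cycles_rejected(self):
        ts = _trialset(np.zeros((4, 200)), 0.2)
        with pytest.raises(ValueError, match="cycles"):
            steady_cycle_average(ts)


class TestHarmonicFit:
    def test_pure_sine_with_offset(self):
        T = 0.25
        t = np.arange(250) / 1000.0
        fit = harmonic_fit(2.0 * np.sin(2 * np.pi * t / T) + 3.0, T)
        assert fit.amplitude_a == pytest.approx(2.0)
        assert fit.phase_phi == pytest.approx(0.0, abs=1e-9)
        assert fit.offset_c == pytest.approx(3.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_quadrature_phase(self):
        T = 0.25
        t = np.arange(250) / 1000.0
        fit = harmonic_fit(np.cos(2 * np.pi * t / T), T)
        assert fit.amplitude_a == pytest.approx(1.0)
        assert fit.phase_phi == pytest.approx(np.pi / 2)
        assert fit.offset_c == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.floats(-5, 5),
        q=st.floats(-5, 5),
        c=st.floats(-10, 10),
    )
    def test_exact_on_single_harmonic(self, p, q, c):
        """Regression is exact (zero residual) on any p*sin + q*cos + c input."""
        T = 0.3
        t = np.arange(300) / 1000.0
        theta = 2 * np.pi * t / T
        fit = harmonic_fit(p * np.sin(theta) + q * np.cos(theta) + c, T)
        recon = fit.amplitude_a * np.sin(theta + fit.phase_phi) + fit.offset_c
        np.testing.assert_allclose(
            recon, p * np.sin(theta) + q * np.cos(theta) + c, atol=1e-9
        )

    def test_phase_convention_reproduces_signal(self):
        """phi = atan2(cos-coef, sin-coef) makes A*sin(theta + phi) + c exact."""
        T = 0.2
        t = np.arange(200) / 1000.0
        theta = 2 * np.pi * t / T
        y = 1.5 * np.sin(theta) - 0.8 * np.cos(theta) + 0.3
        fit = harmonic_fit(y, T)
        np.testing.assert_allclose(
            fit.amplitude_a * np.sin(theta + fit.phase_phi) + fit.offset_c, y, atol=1e-12
        )

    def test_rejects_tiny_cycles(self):
        with pytest.raises(ValueError):
            harmonic_fit(np.ones(4), 0.004)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            HarmonicFit(-1.0, 0.0, 0.0, 0.3, 1.0)


class TestBodeAssemble:
    def test_unity_gain_is_zero_db(self):
        fits = [HarmonicFit(0.5, np.pi, 0.0, T, 1.0) for T in (0.5, 0.25, 0.125)]
        points = bode_assemble(fits)
        assert all(p.gain_db == pytest.approx(0.0) for p in points)

    def test_in_phase_output_gives_zero_phase(self):
        fits = [HarmonicFit(1.0, np.pi, 0.0, T, 1.0) for T in (0.5, 0.25, 0.125)]
        points = bode_assemble(fits)
        assert all(p.phase == pytest.approx(0.0) for p in points)

    def test_points_lie_on_analytic_curve(self, model_b):
        """Noiseless simulation fits land on the closed-form Bode curve."""
        subject = VirtualSubject(plant=model_b, noise_sd=0.0)
        sets = [run_protocol(subject, sweep_sinusoid(T), n_trials=1) for T in frequency_grid()]
        fits = [
            harmonic_fit(steady_cycle_average(ts), ts.period, ts.trials[0].sample_rate)
            for ts in sets
        ]
        for p in bode_assemble(fits):
            gain, phase = analytic_response(model_b, p.omega)
            assert 10 ** (p.gain_db / 20) == pytest.approx(gain, rel=0.01)
            assert p.phase == pytest.approx(phase, abs=0.02)

    def test_phase_unwraps_monotonically(self, model_b):
        omegas = 2 * np.pi / frequency_grid()
        fits = []
        for T in frequency_grid():
            g, ph = analytic_response(model_b, 2 * np.pi / T)
            fits.append(HarmonicFit(0.5 * g, np.angle(np.exp(1j * (ph + np.pi))), 0.0, T, 1.0))
        phases = [p.phase for p in bode_assemble(fits)]
        assert all(b < a for a, b in zip(phases, phases[1:]))
        np.testing.assert_allclose(
            phases, [analytic_response(model_b, w)[1] for w in sorted(omegas)], atol=1e-9
        )

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            bode_assemble([HarmonicFit(0.0, 0.0, 0.0, 0.5, 1.0)])


class TestGainSlope:
    def test_constant_gain_has_zero_slope(self):
        points = [BodePoint(w, 5.0, 0.0) for w in np.geomspace(1, 100, 10)]
        assert fit_gain_slope(points, band=(1, 100)) == pytest.approx(0.0, abs=1e-12)

    def test_second_order_asymptote(self, model_b):
        wn = model_b.omega_n
        band = np.geomspace(10 * wn, 100 * wn, 15)
        gains, _ = analytic_response(model_b, band)
        pts = [BodePoint(w, 20 * np.log10(g), 0.0) for w, g in zip(band, gains)]
        assert fit_gain_slope(pts, band=(band[0], band[-1])) == pytest.approx(-40, abs=0.5)

    def test_grid_band_slope_shallower_than_asymptote(self, model_b):
        """Over the sampled 12.6-62.8 rad/s band the roll-off is partial."""
        omegas = np.sort(2 * np.pi / frequency_grid())
        gains, _ = analytic_response(model_b, omegas)
        pts = [BodePoint(w, 20 * np.log10(g), 0.0) for w, g in zip(omegas, gains)]
        slope = fit_gain_slope(pts)  # default: upper half of the grid
        assert -40 < slope < 0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_gain_slope([BodePoint(1, 0, 0), BodePoint(2, -1, 0)], band=(0, 10))


class TestFitSOPDT:
    def test_self_consistency_on_analytic_points(self, model_b):
        """Analytic Bode of the reference model is recovered to <= 0.5%."""
        pts = []
        for T in frequency_grid():
            w = 2 * np.pi / T
            g, ph = analytic_response(model_b, w)
            pts.append(BodePoint(w, 20 * np.log10(g), ph))
        fit = fit_sopdt(pts)
        assert fit.k == pytest.approx(model_b.k, rel=5e-3)
        assert fit.omega_n == pytest.approx(model_b.omega_n, rel=5e-3)
        assert fit.tau == pytest.approx(model_b.tau, abs=5e-4)

    def test_zero_dead_time_recovered_as_zero(self):
        model = SOPDTModel(k=4.0, omega_n=22.0, tau=0.0)
        pts = []
        for T in frequency_grid():
            w = 2 * np.pi / T
            g, ph = analytic_response(model, w)
            pts.append(BodePoint(w, 20 * np.log10(g), ph))
        assert fit_sopdt(pts).tau <= 1e-3  # one phase-sample equivalent

    def test_gain_scale_equivariance(self, model_b):
        """Scaling all forces by lambda scales K and leaves omega_n, tau."""
        lam = 2.5
        pts, pts_scaled = [], []
        for T in frequency_grid():
            w = 2 * np.pi / T
            g, ph = analytic_response(model_b, w)
            pts.append(BodePoint(w, 20 * np.log10(g), ph))
            pts_scaled.append(BodePoint(w, 20 * np.log10(lam * g), ph))
        a, b = fit_sopdt(pts), fit_sopdt(pts_scaled)
        assert b.k == pytest.approx(lam * a.k, rel=1e-9)
        assert b.omega_n == pytest.approx(a.omega_n, rel=1e-9)
        assert b.tau == pytest.approx(a.tau, abs=1e-12)

    def test_too_few_points_rejected(self):
        pts = [BodePoint(w, 0.0, 0.0) for w in (1, 2, 3, 4)]
        with pytest.raises(ValueError):
            fit_sopdt(pts)


class TestEndToEnd:
    def test_noiseless_recovery(self, model_b):
        """Zero-noise pipeline recovers the plant to <=0.5% and tau to <=1 ms."""
        subject = VirtualSubject(plant=model_b, noise_sd=0.0)
        sets = [run_protocol(subject, sweep_sinusoid(T), n_trials=1) for T in frequency_grid()]
        fit, fits, points = identify(sets)
        assert fit.k == pytest.approx(model_b.k, rel=5e-3)
        assert fit.omega_n == pytest.approx(model_b.omega_n, rel=5e-3)
        assert abs(fit.tau - model_b.tau) <= 1e-3

    def test_offset_diagnostic_sees_vibration_center_shift(self, model_b):
        """Harmonic offsets flag the asymmetry at short periods only."""
        subject = VirtualSubject(plant=model_b, noise_sd=0.0, asymmetry=0.1)
        offsets = {}
        for T in (0.2, 0.5):
            ts = run_protocol(subject, sweep_sinusoid(T), n_trials=1)
            fit = harmonic_fit(steady_cycle_average(ts), T)
            offsets[T] = fit.offset_c - model_b.k * 0.5  # remove the r_E midpoint force
        assert offsets[0.2] > 0.05
        assert offsets[0.5] == pytest.approx(0.0, abs=1e-6)
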