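"""Stimulation protocol generators: sweeps, composites, steps, bursts, AM carrier."""

import numpy as np
import pytest

from eaafes import (
    BurstSpec,
    StepSchedule,
    am_carrier,
    burst_trace,
    composite_sinusoid,
    frequency_grid,
    step_trace,
    sweep_sinusoid,
)


def _at(trace, t):
    return trace.r_e[np.argmin(np.abs(trace.t - t))]


class TestSweep:
    def test_key_phases(self):
        T = 0.3
        tr = sweep_sinusoid(T)
        onset = tr.t[tr.onset_index]
        assert _at(tr, onset) == pytest.approx(0.5)
        assert _at(tr, onset + T / 4) == pytest.approx(0.0, abs=1e-9)
        assert _at(tr, onset + 3 * T / 4) == pytest.approx(1.0, abs=1e-9)

    def test_bounds_and_activity(self):
        tr = sweep_sinusoid(0.125)
        assert np.nanmin(tr.r_e) >= 0 and np.nanmax(tr.r_e) <= 1
        assert np.all(tr.a_e[tr.active] == 1.0)

    def test_active_sample_count_after_onset(self):
        T, rate, n_cycles = 0.25, 1000.0, 10
        tr = sweep_sinusoid(T, n_cycles=n_cycles, sample_rate=rate)
        assert len(tr) - tr.onset_index == round(n_cycles * T * rate)

    def test_off_preconditioning_masks_lead_in(self):
        tr = sweep_sinusoid(0.3, precondition="off")
        assert not tr.active[: tr.onset_index].any()
        assert np.isnan(tr.r_e[0]) and tr.a_e[0] == 0.0

    def test_cycle_preconditioning_is_phase_continuous(self):
        tr = sweep_sinusoid(0.25, precondition="cycle")
        # one full period before onset equals one full period after
        n = 250
        np.testing.assert_allclose(
            tr.r_e[tr.onset_index - n : tr.onset_index],
            tr.r_e[tr.onset_index : tr.onset_index + n],
            atol=1e-12,
        )

    @pytest.mark.parametrize("bad", [0.0, -0.1])
    def test_rejects_nonpositive_period(self, bad):
        with pytest.raises(ValueError):
            sweep_sinusoid(bad)


class TestFrequencyGrid:
    def test_grid_contents(self):
        grid = frequency_grid()
        assert len(grid) == 17
        assert grid[0] == pytest.approx(0.1)
        assert grid[-1] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diff(grid), 0.025)

    def test_angular_frequency_span(self):
        omega = 2 * np.pi / frequency_grid()
        assert omega.max() == pytest.approx(62.83, abs=0.01)
        assert omega.min() == pytest.approx(12.57, abs=0.01)


class TestComposite:
    def test_two_tone_values(self):
        tr = composite_sinusoid((0.6, 0.4), (0.3, 0.6))
        onset = tr.t[tr.onset_index]
        assert _at(tr, onset) == pytest.approx(0.5)
        # at 0.15 s past onset the 0.3 s tone is back at 0.5, the 0.6 s tone at 0
        assert _at(tr, onset + 0.15) == pytest.approx(0.3, abs=1e-9)

    def test_degenerate_reduces_to_sweep(self):
        comp = composite_sinusoid((1.0,), (0.6,), duration=6.0)
        sweep = sweep_sinusoid(0.6, n_cycles=10, precondition="off")
        on = comp.active & sweep.active
        np.testing.assert_allclose(comp.r_e[on], sweep.r_e[on], atol=1e-12)

    def test_stays_in_unit_interval(self):
        tr = composite_sinusoid((0.5, 0.5), (0.2, 0.5))
        assert np.nanmin(tr.r_e) >= 0 and np.nanmax(tr.r_e) <= 1

    def test_rejects_escaping_weights(self):
        with pytest.raises(ValueError):
            composite_sinusoid((1.0, 1.0), (0.3, 0.6))


class TestStep:
    def test_default_staircase_levels(self):
        tr = step_trace()
        assert _at(tr, 1.0) == pytest.approx(0.0)
        assert _at(tr, 4.0) == pytest.approx(0.2)
        assert _at(tr, 16.0) == pytest.approx(1.0)
        # descending limb mirrors the ascent
        assert _at(tr, 19.0) == pytest.approx(0.8)

    def test_changes_only_at_dwell_boundaries(self):
        tr = step_trace(StepSchedule(dwell=2.0))
        switch = np.flatnonzero(np.diff(tr.r_e))
        assert np.all((switch + 1) % int(2.0 * tr.sample_rate) == 0)

    def test_direction_variants(self):
        up = step_trace(StepSchedule(direction="up"))
        assert up.r_e[-1] == pytest.approx(1.0)
        down = step_trace(StepSchedule(direction="down"))
        assert down.r_e[0] == pytest.approx(1.0) and down.r_e[-1] == pytest.approx(0.0)


class TestBurst:
    def test_burst_waveform_and_gaps(self):
        tr = burst_trace()
        assert _at(tr, 1.0) == pytest.approx(0.5)  # onset of first burst
        assert _at(tr, 1.125) == pytest.approx(0.0, abs=1e-9)  # sin peak
        i3 = np.argmin(np.abs(tr.t - 3.0))
        assert not tr.active[i3] and tr.a_e[i3] == 0.0  # between bursts: OFF

    def test_each_burst_spans_two_cycles(self):
        spec = BurstSpec()
        tr = burst_trace(spec)
        n_active = int(tr.active.sum())
        assert n_active == len(spec.burst_starts) * round(
            spec.n_cycles * spec.period * tr.sample_rate
        )

    def test_overlapping_bursts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BurstSpec(burst_starts=(1.0, 1.5))


class TestAmCarrier:
    def test_constant_envelope_is_pure_tone(self):
        t_env = np.arange(0, 1.0, 1e-3)
        t, w = am_carrier(t_env, np.full(t_env.size, 8.0))
        np.testing.assert_allclose(w, 8.0 * np.sin(2 * np.pi * 60 * t), atol=1e-9)

    def test_zero_envelope(self):
        t_env = np.arange(0, 0.5, 1e-3)
        _, w = am_carrier(t_env, np.zeros(t_env.size))
        assert np.all(w == 0)

    def test_cycle_peaks_track_sinusoidal_envelope(self):
        """Per-carrier-cycle peak series reproduces the commanded envelope."""
        T = 0.5
        t_env = np.arange(0, 2 * T, 1e-3)
        env = -3.0 * np.sin(2 * np.pi * t_env / T) + 8.0
        t, w = am_carrier(t_env, env, out_rate=60000.0)
        n_per_cycle = int(60000 / 60)
        n_cycles = w.size // n_per_cycle
        peaks = np.abs(w[: n_cycles * n_per_cycle]).reshape(n_cycles, -1).max(axis=1)
        centers = (np.arange(n_cycles) + 0.5) / 60.0
        expected = np.interp(centers, t_env, env)
        # within each 16.7 ms carrier cycle the envelope itself drifts by up
        # to ~0.3 mA, so the peak tracks it only to a few percent
        np.testing.assert_allclose(peaks, expected, rtol=0.05)

    def test_rejects_negative_envelope_and_coarse_rate(self):
        t_env = np.arange(0, 0.1, 1e-3)
        with pytest.raises(ValueError):
            am_carrier(t_env, np.full(t_env.size, -1.0))
        with pytest.raises(ValueError):
            am_carrier(t_env, np.ones(t_env.size), out_rate=300.0)
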