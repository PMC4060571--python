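"""Frequency-response identification of the elbow-joint SOPDT model.

Pipeline, per input period T of the sweep protocol:

1. average the replicate trials, cut the post-onset record into 10 input
   cycles, and average cycles 3-8 (1-based; the steady-state window);
2. fit one cycle by harmonic regression
   f(t) ~ p*sin(2*pi*t/T) + q*cos(2*pi*t/T) + c, giving amplitude
   A = sqrt(p**2 + q**2), phase phi = atan2(q, p) and offset c;
3. assemble Bode points: gain in dB of A over the input amplitude (0.5,
   the r_E sinusoid's amplitude) and phase relative to the input's -sin
   convention, unwrapped across the grid;
4. fit the SOPDT model with zeta = 1: (K, omega_n) by least squares on the
   gain curve, then the dead time tau by regressing the residual phase
   [measured phase + 2*atan(omega/omega_n)] on -tau*omega through the
   origin.

The offset c is excluded from the transfer-function fit and reported
separately: it is the vibration-center-shift diagnostic (a positive c at
short periods indicates extensor/flexor response-speed imbalance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from eaafes.plant import SOPDTModel
from eaafes.subject import TrialSet

INPUT_AMPLITUDE = 0.5  # amplitude of the r_E identification sinusoid
INPUT_PHASE = np.pi  # -0.5*sin(wt) + 0.5 == 0.5*sin(wt + pi) + 0.5

STEADY_CYCLES = (3, 8)  # 1-based inclusive window of steady-state cycles

OMEGA_N_SEARCH = (5.0, 100.0)  # rad/s, log-grid initialization range


@dataclass(frozen=True)
class HarmonicFit:
    """Single-harmonic sinusoid fit of one averaged output cycle."""

    amplitude_a: float
    phase_phi: float
    offset_c: float
    period_t: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.amplitude_a < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class BodePoint:
    """One frequency-response sample (phase unwrapped across the grid)."""

    omega: float
    gain_db: float
    phase: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be > 0")


def steady_cycle_average(
    trials: TrialSet,
    T: float | None = None,
    cycles: tuple[int, int] = STEADY_CYCLES,
) -> np.ndarray:
    """Average the replicate trials, then the steady-state cycles.

    Returns one cycle of ``round(T * sample_rate)`` force samples starting
    at a cycle boundary of the input.  Cycle numbering is 1-based;
    the default window (3, 8) averages six cycles and is unaffected by the
    transients in cycles 1-2 and any end effects in 9-10.
    """
    if T is None:
        T = trials.period
    if T is None:
        raise ValueError("input period T is required")
    rate = trials.trials[0].sample_rate
    n_cycle = int(round(T * rate))
    onset = trials.trace.onset_index
    mean_f = trials.mean_force().f[onset:]
    first, last = cycles
    n_need = last * n_cycle
    if mean_f.size < n_need:
        raise ValueError(
            f"need {last} whole cycles ({n_need} samples) after onset, got {mean_f.size}"
        )
    stacked = mean_f[(first - 1) * n_cycle : last * n_cycle].reshape(-1, n_cycle)
    return stacked.mean(axis=0)


def harmonic_fit(cycle: np.ndarray, T: float, sample_rate: float = 1000.0) -> HarmonicFit:
    """Least-squares single-harmonic regression of one output cycle.

    Fits f ~ p*sin + q*cos + c on the cycle's own time base t_i = i/rate,
    and reports A = sqrt(p**2 + q**2), phi = atan2(q, p) (so that
    f = A*sin(2*pi*t/T + phi) + c identically) and the offset c.  Exact on
    any noiseless single-harmonic input.
    """
    cycle = np.asarray(cycle, dtype=float)
    if cycle.size < 8:
        raise ValueError("need at least 8 samples per cycle")
    t = np.arange(cycle.size) / sample_rate
    theta = 2 * np.pi * t / T
    design = np.column_stack([np.sin(theta), np.cos(theta), np.ones_like(theta)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design (constant regressors)")
    (p, q, c), *_ = np.linalg.lstsq(design, cycle, rcond=None)
    resid = cycle - design @ np.array([p, q, c])
    ss_tot = float(np.sum((cycle - cycle.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return HarmonicFit(
        amplitude_a=float(np.hypot(p, q)),
        phase_phi=float(np.arctan2(q, p)),
        offset_c=float(c),
        period_t=T,
        r_squared=r2,
    )


def _wrap(phase: float) -> float:
    """Wrap to (-pi, pi]."""
    return float(-((-phase + np.pi) % (2 * np.pi) - np.pi))


def bode_assemble(
    fits: Iterable[HarmonicFit],
    input_amplitude: float = INPUT_AMPLITUDE,
) -> list[BodePoint]:
    """Turn per-period harmonic fits into an unwrapped Bode table.

    Gain is the output amplitude per unit input amplitude, in dB; phase is
    the fitted phase minus the input sinusoid's phase (the input follows the
    -sin convention), wrapped to (-pi, pi] at the lowest frequency and
    unwrapped monotonically towards higher frequencies.
    """
    fits = sorted(fits, key=lambda ft: ft.period_t, reverse=True)  # ascending omega
    if not fits:
        raise ValueError("no harmonic fits supplied")
    omegas, gains, raw = [], [], []
    for ft in fits:
        if ft.amplitude_a <= 0:
            raise ValueError(f"zero amplitude fit at T={ft.period_t}")
        omegas.append(2 * np.pi / ft.period_t)
        gains.append(20 * np.log10(ft.amplitude_a / input_amplitude))
        raw.append(_wrap(ft.phase_phi - INPUT_PHASE))
    phases = np.unwrap(raw)
    return [
        BodePoint(omega=w, gain_db=g, phase=float(ph))
        for w, g, ph in zip(omegas, gains, phases)
    ]


def fit_gain_slope(points: Sequence[BodePoint], band: tuple[float, float] | None = None):
    """OLS slope of gain_db against log10(omega), in dB/decade.

    ``band`` restricts to omega in [lo, hi]; the default takes the upper
    half of the sampled grid (the high-frequency region).
    """
    pts = sorted(points, key=lambda p: p.omega)
    if band is None:
        pts = pts[len(pts) // 2 :]
    else:
        pts = [p for p in pts if band[0] <= p.omega <= band[1]]
    if len(pts) < 3:
        raise ValueError("need at least 3 points in the band")
    x = np.log10([p.omega for p in pts])
    y = [p.gain_db for p in pts]
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def _gain_db_model(k: float, omega_n: float, omega: np.ndarray) -> np.ndarray:
    return 20 * np.log10(k * omega_n**2 / (omega_n**2 + omega**2))


def fit_sopdt(points: Sequence[BodePoint]) -> SOPDTModel:
    """Fit the critically damped SOPDT model to a Bode table.

    (K, omega_n) minimize the squared dB error of the zeta = 1 gain curve;
    initialization is a deterministic log-grid search over omega_n with the
    per-omega_n optimal K in closed form.  tau then comes from the residual
    phase (measured + 2*atan(omega/omega_n)) regressed on -tau*omega through
    the origin, clamped at tau >= 0.
    """
    if len(points) < 5:
        raise ValueError("need at least 5 Bode points")
    omega = np.array([p.omega for p in points])
    gain_db = np.array([p.gain_db for p in points])
    phase = np.array([p.phase for p in points])

    # deterministic initialization: closed-form K for each candidate omega_n
    best = None
    for wn in np.geomspace(*OMEGA_N_SEARCH, 61):
        shape = 20 * np.log10(wn**2 / (wn**2 + omega**2))
        k_db = float(np.mean(gain_db - shape))
        sse = float(np.sum((gain_db - shape - k_db) ** 2))
        if best is None or sse < best[0]:
            best = (sse, 10 ** (k_db / 20), wn)
    _, k0, wn0 = best

    res = least_squares(
        lambda x: _gain_db_model(x[0], x[1], omega) - gain_db,
        x0=[k0, wn0],
        bounds=([1e-6, 1e-3], [np.inf, np.inf]),
    )
    if not res.success:
        raise RuntimeError(f"SOPDT gain fit did not converge: {res.message}")
    k_fit, wn_fit = float(res.x[0]), float(res.x[1])
    if not (omega.min() <= wn_fit <= omega.max()):
        import warnings

        warnings.warn(
            f"fitted corner frequency {wn_fit:.3g} rad/s lies outside the "
            f"sampled band [{omega.min():.3g}, {omega.max():.3g}]",
            stacklevel=2,
        )

    resid_phase = phase + 2 * np.arctan(omega / wn_fit)
    tau = max(0.0, float(-np.sum(resid_phase * omega) / np.sum(omega**2)))
    return SOPDTModel(k=k_fit, omega_n=wn_fit, zeta=1.0, tau=tau)


def identify(
    trial_sets: Iterable[TrialSet],
    input_amplitude: float = INPUT_AMPLITUDE,
):
    """Full pipeline from sweep trial sets to an identified SOPDT model.

    Returns ``(model, fits, points)``: the fitted model, the per-period
    harmonic fits (whose offsets are the vibration-center diagnostics), and
    the assembled Bode table.
    """
    fits = []
    for ts in trial_sets:
        cycle = steady_cycle_average(ts)
        rate = ts.trials[0].sample_rate
        fits.append(harmonic_fit(cycle, ts.period, sample_rate=rate))
    points = bode_assemble(fits, input_amplitude=input_amplitude)
    return fit_sopdt(points), fits, points
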