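"""Stimulation input protocols expressed as EAA-ratio traces.

All protocols modulate the EAA ratio r_E(t) at a fixed activity a_E
(default 1.0).  The identification sweep is

    r_E(t) = -0.5 * sin(2*pi*t/T) + 0.5

so r_E starts at 0.5 (balanced co-contraction), dips towards 0 (pure
flexion) in the first quarter-cycle, and peaks at 1 (pure extension).
Samples are on a uniform 1 kHz grid (matching the force acquisition rate)
with half-open cycle windows [kT, (k+1)T) anchored at input onset.

The physical stimulator output is a 60 Hz sinusoidal carrier whose amplitude
follows the commanded current envelope (amplitude modulation);
:func:`am_carrier` synthesizes that waveform for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_SAMPLE_RATE = 1000.0  # Hz, matches force acquisition
DEFAULT_ACTIVITY = 1.0


@dataclass
class EAATrace:
    """Uniformly sampled (r_E, a_E) command trace.

    ``active`` marks samples where stimulation is on; outside it both
    channels are OFF (not held at r_E = 0) and ``r_e`` is NaN.
    ``period`` records the dominant input period for protocols that have one.
    """

    t: np.ndarray
    r_e: np.ndarray
    a_e: np.ndarray
    sample_rate: float
    active: np.ndarray = field(default=None)  # type: ignore[assignment]
    kind: str = ""
    period: float | None = None
    onset: int | None = None  # sample index of pattern onset, if it differs
    # from the first active sample (e.g. a conditioning hold precedes it)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r_e = np.asarray(self.r_e, dtype=float)
        self.a_e = np.asarray(self.a_e, dtype=float)
        if self.active is None:
            self.active = np.ones(self.t.shape, dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool)
        if self.t.ndim != 1 or np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be 1-D and strictly increasing")
        on = self.active & (self.a_e > 0)
        r = self.r_e[on]
        if r.size and (np.nanmin(r) < 0 or np.nanmax(r) > 1):
            raise ValueError("r_e must lie in [0, 1] on active samples")

    def __len__(self) -> int:
        return self.t.size

    @property
    def onset_index(self) -> int:
        """Sample index where the pattern proper begins.

        Defaults to the first active sample; a conditioning hold before the
        pattern sets ``onset`` explicitly.
        """
        if self.onset is not None:
            return self.onset
        idx = np.flatnonzero(self.active)
        return int(idx[0]) if idx.size else 0


@dataclass(frozen=True)
class StepSchedule:
    """Staircase schedule for the EAA ratio.

    Default replicates the step task: start at 0, change by 0.2 every 3 s,
    up to 1 and back down.
    """

    start_level: float = 0.0
    increment: float = 0.2
    dwell: float = 3.0
    direction: str = "up-down"  # "up", "down", or "up-down"

    def levels(self) -> list[float]:
        n = int(round(1.0 / self.increment))
        up = [self.start_level + k * self.increment for k in range(n + 1)]
        down = up[-2::-1]
        if self.direction == "up":
            seq = up
        elif self.direction == "down":
            seq = [1.0 - u for u in up]
        elif self.direction == "up-down":
            seq = up + down
        else:
            raise ValueError(f"unknown direction {self.direction!r}")
        if any(not (-1e-12 <= x <= 1 + 1e-12) for x in seq):
            raise ValueError("step schedule escapes [0, 1]")
        return [min(1.0, max(0.0, x)) for x in seq]


@dataclass(frozen=True)
class BurstSpec:
    """Short sinusoidal bursts separated by stimulation-off gaps.

    Default: two 0.5 s cycles per burst (1 s on) starting at t = 1, 4, 7 s;
    channels are OFF between bursts.
    """

    period: float = 0.5
    n_cycles: int = 2
    burst_starts: Sequence[float] = (1.0, 4.0, 7.0)

    def __post_init__(self) -> None:
        starts = sorted(self.burst_starts)
        width = self.period * self.n_cycles
        for a, b in zip(starts, starts[1:]):
            if a + width > b:
                raise ValueError(f"bursts at t={a} and t={b} overlap")


def _time_grid(duration: float, sample_rate: float) -> np.ndarray:
    n = int(round(duration * sample_rate))
    return np.arange(n) / sample_rate


def sweep_sinusoid(
    T: float,
    n_cycles: int = 10,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    start_delay: float = 0.5,
    activity: float = DEFAULT_ACTIVITY,
    precondition: str = "cycle",
) -> EAATrace:
    """Identification sweep: n_cycles of the r_E sinusoid at period T.

    The analyzed input begins ``start_delay`` after measurement start, at
    r_E = 0.5, range [0, 1], with a_E constant while active.  The
    ``precondition`` mode sets what the pre-input interval carries:

    * ``"cycle"`` (default) — the sinusoid itself, extended backwards
      phase-continuously: the joint oscillates in periodic steady state
      before the analyzed cycles begin, so the steady-state analysis window
      (cycles 3-8) is exactly steady;
    * ``"hold"`` — balanced co-contraction (r_E = 0.5), the sinusoid's
      operating point;
    * ``"off"`` — no stimulation; the analyzed record then contains the
      switch-on transient, which at short periods has not decayed by
      cycle 3.
    """
    if T <= 0 or sample_rate <= 0:
        raise ValueError("period and sample rate must be positive")
    if precondition not in ("cycle", "hold", "off"):
        raise ValueError(f"unknown precondition mode {precondition!r}")
    t = _time_grid(start_delay + n_cycles * T, sample_rate)
    onset = int(round(start_delay * sample_rate))
    after = t >= start_delay - 0.5 / sample_rate
    active = after if precondition == "off" else np.ones(t.shape, dtype=bool)
    tp = t - start_delay
    sinus = -0.5 * np.sin(2 * np.pi * tp / T) + 0.5
    if precondition == "cycle":
        r_e = sinus
    elif precondition == "hold":
        r_e = np.where(after, sinus, 0.5)
    else:
        r_e = np.where(after, sinus, np.nan)
    a_e = np.where(active, activity, 0.0)
    return EAATrace(
        t, r_e, a_e, sample_rate, active, kind="sweep", period=T, onset=onset
    )


def frequency_grid() -> np.ndarray:
    """Sweep periods for identification: 0.100 to 0.500 s in 0.025 s steps."""
    return np.round(np.arange(0.100, 0.500 + 1e-9, 0.025), 3)


def composite_sinusoid(
    weights: Sequence[float],
    periods: Sequence[float],
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    duration: float | None = None,
    start_delay: float = 0.5,
    activity: float = DEFAULT_ACTIVITY,
) -> EAATrace:
    """Convex combination of r_E sinusoids of different periods.

    r_E(t) = sum_i w_i * (-0.5*sin(2*pi*t/T_i) + 0.5).  With weights summing
    to 1 the trace stays in [0, 1].  Default duration is 10 cycles of the
    longest period.
    """
    weights = np.asarray(weights, dtype=float)
    periods = np.asarray(periods, dtype=float)
    if weights.shape != periods.shape:
        raise ValueError("weights and periods must have equal length")
    if np.any(weights < 0) or np.any(periods <= 0):
        raise ValueError("weights must be >= 0 and periods > 0")
    if duration is None:
        duration = 10 * float(periods.max())
    t = _time_grid(start_delay + duration, sample_rate)
    active = t >= start_delay - 0.5 / sample_rate
    tp = t - start_delay
    comp = sum(
        w * (-0.5 * np.sin(2 * np.pi * tp / T) + 0.5) for w, T in zip(weights, periods)
    )
    r_e = np.where(active, comp, np.nan)
    if np.any((r_e[active] < -1e-12) | (r_e[active] > 1 + 1e-12)):
        raise ValueError("composite trace leaves [0, 1]")
    r_e = np.clip(r_e, 0.0, 1.0, out=r_e, where=active)
    a_e = np.where(active, activity, 0.0)
    return EAATrace(
        t, r_e, a_e, sample_rate, active, kind="composite", period=float(periods.max())
    )


def step_trace(
    schedule: StepSchedule = StepSchedule(),
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    activity: float = DEFAULT_ACTIVITY,
) -> EAATrace:
    """Piecewise-constant r_E staircase; level changes at dwell boundaries."""
    levels = schedule.levels()
    t = _time_grid(len(levels) * schedule.dwell, sample_rate)
    idx = np.minimum((t / schedule.dwell).astype(int), len(levels) - 1)
    r_e = np.asarray(levels, dtype=float)[idx]
    a_e = np.full_like(t, activity)
    return EAATrace(
        t, r_e, a_e, sample_rate, np.ones(t.shape, bool), kind="step", period=None
    )


def burst_trace(
    spec: BurstSpec = BurstSpec(),
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    duration: float | None = None,
    activity: float = DEFAULT_ACTIVITY,
) -> EAATrace:
    """Sinusoidal bursts with OFF gaps.

    Inside each burst starting at ``a``,
    r_E = -0.5*sin(2*pi*(t-a)/period) + 0.5; outside, stimulation is off.
    """
    width = spec.period * spec.n_cycles
    if duration is None:
        duration = max(spec.burst_starts) + width + 1.0
    t = _time_grid(duration, sample_rate)
    r_e = np.full_like(t, np.nan)
    active = np.zeros(t.shape, dtype=bool)
    for a in spec.burst_starts:
        win = (t >= a - 0.5 / sample_rate) & (t < a + width - 0.5 / sample_rate)
        active |= win
        r_e[win] = -0.5 * np.sin(2 * np.pi * (t[win] - a) / spec.period) + 0.5
    a_e = np.where(active, activity, 0.0)
    return EAATrace(t, r_e, a_e, sample_rate, active, kind="burst", period=spec.period)


def am_carrier(
    t_env: np.ndarray,
    envelope_ma: np.ndarray,
    carrier_hz: float = 60.0,
    out_rate: float = 6000.0,
):
    """Synthesize the amplitude-modulated stimulator waveform.

    The stimulator emits a fixed-frequency (60 Hz) sine whose amplitude
    tracks the commanded current envelope.  The envelope is linearly
    resampled onto the output grid, which must be at least 10x the carrier.

    Returns ``(t, waveform)`` with ``waveform = envelope(t) * sin(2*pi*f*t)``.
    """
    envelope_ma = np.asarray(envelope_ma, dtype=float)
    if np.any(envelope_ma < 0):
        raise ValueError("envelope must be non-negative")
    if out_rate < 10 * carrier_hz:
        raise ValueError("output rate must be >= 10x the carrier frequency")
    t_env = np.asarray(t_env, dtype=float)
    t = np.arange(t_env[0], t_env[-1], 1.0 / out_rate)
    env = np.interp(t, t_env, envelope_ma)
    return t, env * np.sin(2 * np.pi * carrier_hz * t)
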