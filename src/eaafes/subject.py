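"""Virtual subject: a synthetic generator of "measured" 1 kHz force traces.

A :class:`VirtualSubject` wraps a ground-truth SOPDT plant and reproduces the
statistical structure the identification and validation stages assume:

* additive Gaussian measurement noise on the force channel;
* an optional extensor/flexor response-speed asymmetry that shifts the
  vibration center of the oscillating output to the positive (extension)
  side at short input periods (T <= 0.4 s) and vanishes above;
* an optional voluntary baseline force (central movement command) that adds
  linearly to the stimulation response;
* an optional monotone dependence of the natural frequency on the EAA
  activity a_E (stiffness grows with total drive).

The subject drives its plant with the extensor normalized intensity
u = a_E * r_E, which reduces exactly to r_E at the identification activity
a_E = 1 and makes step-force displacement scale with activity.

The asymmetry is a deliberately synthetic stand-in: the physiological cause
(unequal flexor/extensor response speeds) is not modelled; only its
phenomenology — a positive cycle-mean offset c(T) = asymmetry * K *
max(0, 0.4 - T)/0.4 — is injected, so the offset-diagnostic path of the
pipeline has something to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from eaafes.calibration import SubjectCalibration, command_trace_to_currents
from eaafes.data import reference_calibrations
from eaafes.patterns import EAATrace, StepSchedule, step_trace
from eaafes.plant import DEFAULT_DT, ForceTrace, SOPDTModel, simulate

# Parameter ranges spanned by the six reference subjects
OMEGA_N_RANGE = (14.0, 31.4)  # rad/s
K_RANGE = (1.04, 11.22)  # N per unit r_E
TAU_RANGE = (0.045, 0.100)  # s

# Activity -> natural-frequency anchors measured for reference subject A
DEFAULT_OMEGA_N_ANCHORS = ((0.5, 14.3), (0.8, 19.0), (1.0, 20.5))

DEFAULT_NOISE_SD = 0.5  # N, at the 1 kHz sample level

ASYMMETRY_KNEE_S = 0.4  # input period below which the vibration center shifts


@dataclass
class VirtualSubject:
    """Synthetic subject with a ground-truth plant and nonidealities."""

    plant: SOPDTModel
    noise_sd: float = DEFAULT_NOISE_SD
    asymmetry: float = 0.0
    baseline_force: float = 0.0
    omega_n_by_activity: tuple[tuple[float, float], ...] | None = None
    calibration: SubjectCalibration | None = None
    seed: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.asymmetry < 0:
            raise ValueError("asymmetry must be >= 0")
        if self.omega_n_by_activity is not None:
            pts = sorted(self.omega_n_by_activity)
            wn = [w for _, w in pts]
            if any(b < a for a, b in zip(wn, wn[1:])):
                raise ValueError("omega_n_by_activity must be monotone nondecreasing")
            self.omega_n_by_activity = tuple(pts)
        if self.calibration is None:
            self.calibration = reference_calibrations()["B"]

    def omega_n_at(self, a_e: float) -> float:
        """Natural frequency at activity a_e (piecewise-linear, clamped)."""
        if self.omega_n_by_activity is None:
            return self.plant.omega_n
        a = np.array([p[0] for p in self.omega_n_by_activity])
        w = np.array([p[1] for p in self.omega_n_by_activity])
        return float(np.interp(a_e, a, w))

    def plant_at(self, a_e: float) -> SOPDTModel:
        if self.omega_n_by_activity is None or a_e == 1.0:
            return self.plant
        return SOPDTModel(
            k=self.plant.k,
            omega_n=self.omega_n_at(a_e),
            zeta=self.plant.zeta,
            tau=self.plant.tau,
        )


@dataclass
class TrialSet:
    """Replicate force traces for one protocol, sharing a time base."""

    trials: list[ForceTrace]
    trace: EAATrace
    period: float | None = None
    kind: str = ""
    ground_truth: SOPDTModel | None = None
    seeds: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        lengths = {len(tr) for tr in self.trials}
        if len(lengths) > 1:
            raise ValueError("replicate trials must share a time base")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def mean_force(self) -> ForceTrace:
        """Trial-averaged force trace."""
        f = np.mean([tr.f for tr in self.trials], axis=0)
        first = self.trials[0]
        return ForceTrace(first.t, f, first.sample_rate)


def sample_subject(
    rng_seed: int,
    noise_sd: float = DEFAULT_NOISE_SD,
    asymmetry: float = 0.0,
    baseline_force: float = 0.0,
    with_activity_map: bool = False,
) -> VirtualSubject:
    """Draw a reproducible virtual subject.

    Plant parameters are sampled independently and uniformly within the
    ranges spanned by the six reference subjects (omega_n 14.0-31.4 rad/s,
    K 1.04-11.22 N, tau 0.045-0.100 s), with zeta = 1; the calibration is
    one of the six reference calibrations.
    """
    rng = np.random.default_rng(rng_seed)
    plant = SOPDTModel(
        k=float(rng.uniform(*K_RANGE)),
        omega_n=float(rng.uniform(*OMEGA_N_RANGE)),
        zeta=1.0,
        tau=float(rng.uniform(*TAU_RANGE)),
    )
    cals = reference_calibrations()
    sid = sorted(cals)[rng.integers(len(cals))]
    return VirtualSubject(
        plant=plant,
        noise_sd=noise_sd,
        asymmetry=asymmetry,
        baseline_force=baseline_force,
        omega_n_by_activity=DEFAULT_OMEGA_N_ANCHORS if with_activity_map else None,
        calibration=cals[sid],
        seed=rng_seed,
        subject_id=f"synthetic-{rng_seed}",
    )


def _noiseless_response(subject: VirtualSubject, trace: EAATrace, dt: float) -> np.ndarray:
    """Plant response + baseline + asymmetry offset, no measurement noise."""
    a_active = trace.a_e[trace.active]
    a_const = float(a_active[0]) if a_active.size else 1.0
    plant = subject.plant_at(a_const) if np.all(a_active == a_const) else subject.plant

    u = np.where(trace.active & (trace.a_e > 0), trace.a_e * trace.r_e, 0.0)
    f = simulate(plant, u, dt=dt, t=trace.t).f + subject.baseline_force

    if subject.asymmetry > 0 and trace.period is not None:
        c = (
            subject.asymmetry
            * plant.k
            * max(0.0, ASYMMETRY_KNEE_S - trace.period)
            / ASYMMETRY_KNEE_S
        )
        if c > 0:
            f = f + np.where(np.arange(f.size) >= trace.onset_index, c, 0.0)
    return f


def run_protocol(
    subject: VirtualSubject,
    trace: EAATrace,
    n_trials: int = 3,
    dt: float = DEFAULT_DT,
    trial_seed: int | None = None,
) -> TrialSet:
    """Measure the subject's force response to a stimulation protocol.

    Each trial is the same noiseless response (plant + baseline + asymmetry
    offset) plus an independent Gaussian noise draw; replicates differ only
    in noise.  The trace must be realizable under the subject's calibration
    (checked by decoding it to physical currents).

    Randomness derives from ``(subject.seed, trial_seed)`` so trial sets are
    reproducible independently of subject sampling.
    """
    command_trace_to_currents(trace, subject.calibration)  # realizability check
    clean = _noiseless_response(subject, trace, dt)
    base = subject.seed if trial_seed is None else trial_seed
    ss = np.random.SeedSequence(entropy=base, spawn_key=(7,))  # trial-noise substream
    seeds = tuple(int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_trials))
    trials = []
    for s in seeds:
        rng = np.random.default_rng(s)
        noise = rng.normal(0.0, subject.noise_sd, clean.size) if subject.noise_sd else 0.0
        trials.append(ForceTrace(trace.t, clean + noise, trace.sample_rate))
    return TrialSet(
        trials=trials,
        trace=trace,
        period=trace.period,
        kind=trace.kind,
        ground_truth=subject.plant,
        seeds=seeds,
    )


def activity_sweep(
    subject: VirtualSubject,
    a_levels=(0.1, 0.3, 0.5, 0.7, 0.9, 1.0),
    schedule: StepSchedule = StepSchedule(),
    n_trials: int = 3,
    dt: float = DEFAULT_DT,
) -> dict[float, TrialSet]:
    """Step-response families at several activity levels.

    Replays the r_E staircase at each a_E; force displacement grows with
    a_E and the effective natural frequency follows the subject's
    omega_n(a_E) map.
    """
    out: dict[float, TrialSet] = {}
    for a in a_levels:
        if not (0.0 < a <= 1.0):
            raise ValueError(f"activity level {a} outside (0, 1]")
        trace = step_trace(schedule, sample_rate=1.0 / dt, activity=a)
        out[a] = run_protocol(subject, trace, n_trials=n_trials, dt=dt)
    return out
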