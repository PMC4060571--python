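"""Second-order-plus-dead-time (SOPDT) model of the isometric elbow joint.

The EAA-ratio-to-hand-force dynamics are modelled as

    G(s) = K * omega_n**2 / (s**2 + 2*zeta*omega_n*s + omega_n**2) * exp(-tau*s)

with the damping ratio fixed at zeta = 1 (critically damped) during
identification.  K is the steady-state gain in N per unit r_E, omega_n the
natural angular frequency in rad/s, and tau the stimulation-to-force dead
time in s.

Time-domain simulation uses the exact zero-order-hold discretization of the
second-order state-space core (the matrix exponential of the companion
matrix per step), so piecewise-constant inputs are integrated without
truncation error; the dead time is an integer-sample shift at the default
1 ms step (tau values of interest are multiples of 5 ms).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

MODEL_SCHEMA_VERSION = 1

DEFAULT_DT = 1e-3  # s


@dataclass(frozen=True)
class SOPDTModel:
    """SOPDT parameters (K [N/unit r_E], omega_n [rad/s], zeta [-], tau [s])."""

    k: float
    omega_n: float
    zeta: float = 1.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.omega_n <= 0:
            raise ValueError(f"omega_n must be > 0, got {self.omega_n}")
        if self.zeta <= 0:
            raise ValueError(f"zeta must be > 0, got {self.zeta}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")

    @property
    def denominator(self) -> tuple[float, float, float]:
        """Monic denominator coefficients (1, 2*zeta*omega_n, omega_n**2)."""
        return (1.0, 2.0 * self.zeta * self.omega_n, self.omega_n**2)

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "k": self.k,
            "omega_n": self.omega_n,
            "zeta": self.zeta,
            "tau": self.tau,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SOPDTModel":
        version = d.get("schema_version", MODEL_SCHEMA_VERSION)
        if version != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unknown model schema version {version!r}")
        return cls(k=d["k"], omega_n=d["omega_n"], zeta=d.get("zeta", 1.0), tau=d.get("tau", 0.0))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SOPDTModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ForceTrace:
    """Uniformly sampled hand force in N (flexion negative)."""

    t: np.ndarray
    f: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.shape != self.f.shape:
            raise ValueError("time and force arrays must have equal shape")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("force trace contains non-finite values")

    def __len__(self) -> int:
        return self.t.size


def analytic_response(model: SOPDTModel, omega) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form frequency response (gain magnitude, phase in rad).

    gain  = K*wn**2 / sqrt((wn**2 - w**2)**2 + (2*zeta*wn*w)**2)
    phase = -atan2(2*zeta*wn*w, wn**2 - w**2) - tau*w

    For zeta = 1 the gain simplifies to K*wn**2 / (wn**2 + w**2).
    """
    omega = np.asarray(omega, dtype=float)
    wn2 = model.omega_n**2
    re = wn2 - omega**2
    im = 2.0 * model.zeta * model.omega_n * omega
    gain = model.k * wn2 / np.sqrt(re**2 + im**2)
    phase = -np.arctan2(im, re) - model.tau * omega
    return gain, phase


def _discrete_core(model: SOPDTModel, dt: float):
    """Discrete state-space of the second-order core (no delay).

    First-order-hold discretization built from the matrix exponential of the
    companion form: exact for piecewise-linear inputs, so smooth commands
    sampled at 1 kHz are integrated without the half-sample phase lag a
    zero-order hold would introduce, and the DC gain is preserved exactly.
    """
    wn2 = model.omega_n**2
    a = np.array([[0.0, 1.0], [-wn2, -2.0 * model.zeta * model.omega_n]])
    b = np.array([[0.0], [model.k * wn2]])
    c = np.array([[1.0, 0.0]])
    d = np.array([[0.0]])
    ad, bd, cd, dd, _ = signal.cont2discrete((a, b, c, d), dt, method="foh")
    return ad, bd, cd, dd


def simulate(model: SOPDTModel, u, dt: float = DEFAULT_DT, t=None) -> ForceTrace:
    """Simulate the force response to a sampled input series.

    Parameters
    ----------
    model : SOPDTModel
    u : array-like or EAATrace
        Input series sampled at 1/dt.  An EAATrace is accepted directly; its
        r_E is the input where active and the input is 0 where stimulation
        is off.
    dt : float
        Sample interval, s; must be <= 1 ms and fine relative to the plant
        (a warning is raised above omega_n*dt > 0.2).
    t : array-like, optional
        Time base; defaults to arange(n)*dt.

    The input is held constant over each step (ZOH), matching the discrete
    transition, so the settled response to a constant u is exactly K*u.
    The dead time shifts the output by round(tau/dt) samples.
    """
    if dt > 1e-3 + 1e-12:
        raise ValueError("dt must be <= 1 ms")
    if model.omega_n * dt > 0.2:
        warnings.warn(
            f"dt={dt} is coarse for omega_n={model.omega_n} (omega_n*dt > 0.2)",
            stacklevel=2,
        )
    if hasattr(u, "r_e"):  # EAATrace
        if t is None:
            t = u.t
        u = np.where(u.active & (u.a_e > 0), u.r_e, 0.0)
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("input contains non-finite values")
    if t is None:
        t = np.arange(u.size) * dt

    ad, bd, cd, dd = _discrete_core(model, dt)
    # run the ZOH-exact recursion as a difference equation (zero initial state)
    num, den = signal.ss2tf(ad, bd, cd, dd)
    y = signal.lfilter(num[0], den, u)
    delay = int(round(model.tau / dt))
    if delay > 0:
        y = np.concatenate([np.zeros(delay), y[:-delay] if delay < y.size else y[:0]])
        y = y[: u.size]
    return ForceTrace(np.asarray(t, dtype=float), y, 1.0 / dt)


def simulate_with_voluntary(
    model: SOPDTModel,
    trace,
    baseline_force: float = 0.0,
    dt: float = DEFAULT_DT,
) -> ForceTrace:
    """Superpose the stimulation response on a voluntary baseline force.

    The central movement command and the FES command add linearly
    (r = r_h + r_E), so the measured force is the plant response to r_E plus
    the force the subject holds voluntarily.  With stimulation off
    everywhere the output equals the baseline.
    """
    out = simulate(model, trace, dt=dt)
    return ForceTrace(out.t, out.f + baseline_force, out.sample_rate)
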