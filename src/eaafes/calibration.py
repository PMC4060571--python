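"""EAA command coding and per-subject stimulation-current calibration.

Two stimulation channels (flexor = biceps, extensor = triceps) are commanded
through two scalars:

* EAA ratio  ``r_E = I_e / (I_f + I_e)`` — the extensor share of the total
  normalized intensity; it sets the joint equilibrium point.
* EAA activity ``a_E = I_f + I_e`` — the total normalized intensity; it sets
  the joint stiffness.

Normalized intensities map affinely onto physical currents between each
muscle's contraction threshold ``I'_min`` and pain-free maximum ``I'_max``:
``I = (I' - I'_min) / (I'_max - I'_min)``.

Sign convention throughout the package: hand force is negative in flexion,
positive in extension.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

# intensities this far outside [0, 1] are treated as floating-point noise
CLAMP_TOL = 1e-9

CALIBRATION_SCHEMA_VERSION = 1


class UnrealizableCommandError(ValueError):
    """An EAA command maps to a normalized intensity outside [0, 1]."""


@dataclass(frozen=True)
class MuscleCalibration:
    """Stimulation current limits for one muscle.

    Parameters
    ----------
    i_max : float
        Maximum pain-free stimulation current I'_max, mA.
    i_min : float
        Minimum current at which contraction commences I'_min, mA.
    """

    i_max: float
    i_min: float

    def __post_init__(self) -> None:
        if not (self.i_max > self.i_min >= 0):
            raise ValueError(
                f"require i_max > i_min >= 0, got i_max={self.i_max}, i_min={self.i_min}"
            )

    @property
    def span(self) -> float:
        return self.i_max - self.i_min


@dataclass(frozen=True)
class SubjectCalibration:
    """Per-subject current limits for the flexor (biceps) and extensor (triceps)."""

    flexor: MuscleCalibration
    extensor: MuscleCalibration
    subject_id: str = ""

    def to_dict(self) -> dict:
        return {
            "schema_version": CALIBRATION_SCHEMA_VERSION,
            "subject_id": self.subject_id,
            "flexor": {"i_max_ma": self.flexor.i_max, "i_min_ma": self.flexor.i_min},
            "extensor": {"i_max_ma": self.extensor.i_max, "i_min_ma": self.extensor.i_min},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectCalibration":
        version = d.get("schema_version", CALIBRATION_SCHEMA_VERSION)
        if version != CALIBRATION_SCHEMA_VERSION:
            raise ValueError(f"unknown calibration schema version {version!r}")
        return cls(
            flexor=MuscleCalibration(d["flexor"]["i_max_ma"], d["flexor"]["i_min_ma"]),
            extensor=MuscleCalibration(d["extensor"]["i_max_ma"], d["extensor"]["i_min_ma"]),
            subject_id=d.get("subject_id", ""),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SubjectCalibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class EAACommand:
    """One (r_E, a_E) command sample.

    ``r_e`` is the extensor share in [0, 1]; ``a_e`` is the total normalized
    activity, non-negative.  The command is physically realizable only when
    both derived intensities ``I_f = (1 - r_e) * a_e`` and ``I_e = r_e * a_e``
    lie in [0, 1].
    """

    r_e: float
    a_e: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_e <= 1.0):
            raise ValueError(f"r_e must be in [0, 1], got {self.r_e}")
        if self.a_e < 0:
            raise ValueError(f"a_e must be >= 0, got {self.a_e}")


@dataclass(frozen=True)
class NormalizedStimPair:
    """Normalized intensities (dimensionless) for flexor and extensor."""

    i_f: float
    i_e: float


@dataclass(frozen=True)
class PhysicalStimPair:
    """Physical stimulation currents in mA; 0 means the channel is off."""

    i_f_ma: float
    i_e_ma: float


def _clamp_unit(x: float, muscle: str) -> float:
    if x < -CLAMP_TOL or x > 1.0 + CLAMP_TOL:
        raise UnrealizableCommandError(
            f"{muscle} normalized intensity {x:.6g} outside [0, 1]"
        )
    return min(1.0, max(0.0, x))


def eaa_to_normalized(cmd: EAACommand) -> NormalizedStimPair:
    """Decode an EAA command into normalized muscle intensities.

    ``I_e = r_e * a_e`` and ``I_f = (1 - r_e) * a_e``, so that the pair
    conserves ``I_f + I_e = a_e`` and reproduces ``r_e`` as the extensor
    share.  Raises :class:`UnrealizableCommandError` when either intensity
    leaves [0, 1] by more than floating-point noise.
    """
    i_e = _clamp_unit(cmd.r_e * cmd.a_e, "extensor")
    i_f = _clamp_unit((1.0 - cmd.r_e) * cmd.a_e, "flexor")
    return NormalizedStimPair(i_f=i_f, i_e=i_e)


def normalized_to_eaa(pair: NormalizedStimPair, rest_r_e: float = math.nan) -> EAACommand:
    """Encode normalized intensities back into an EAA command.

    When both channels are off (``i_f = i_e = 0``) the ratio is undefined;
    ``rest_r_e`` (NaN by default) is recorded instead.
    """
    if pair.i_f < 0 or pair.i_e < 0:
        raise ValueError("normalized intensities must be >= 0")
    a_e = pair.i_f + pair.i_e
    if a_e == 0.0:
        cmd = object.__new__(EAACommand)
        object.__setattr__(cmd, "r_e", rest_r_e)
        object.__setattr__(cmd, "a_e", 0.0)
        return cmd
    return EAACommand(r_e=pair.i_e / a_e, a_e=a_e)


def denormalize(i: float, cal: MuscleCalibration) -> float:
    """Map a normalized intensity in [0, 1] to a physical current in mA.

    ``I' = i * (I'_max - I'_min) + I'_min``; affine and monotone.
    """
    if not (0.0 <= i <= 1.0):
        raise ValueError(f"normalized intensity {i} outside [0, 1]")
    return i * cal.span + cal.i_min


def normalize(i_ma: float, cal: MuscleCalibration) -> float:
    """Map a physical current in [i_min, i_max] mA to a normalized intensity."""
    if not (cal.i_min <= i_ma <= cal.i_max):
        raise ValueError(
            f"current {i_ma} mA outside calibration range [{cal.i_min}, {cal.i_max}]"
        )
    return (i_ma - cal.i_min) / cal.span


def command_to_currents(cmd: EAACommand, cal: SubjectCalibration) -> PhysicalStimPair:
    """Decode one EAA command to physical currents for both muscles.

    At rest (``a_e = 0``) both channels are OFF (0 mA): ``i_min`` is the
    contraction threshold, not zero output, so the affine map does not apply.
    """
    if cmd.a_e == 0.0:
        return PhysicalStimPair(0.0, 0.0)
    pair = eaa_to_normalized(cmd)
    return PhysicalStimPair(
        i_f_ma=denormalize(pair.i_f, cal.flexor),
        i_e_ma=denormalize(pair.i_e, cal.extensor),
    )


def command_trace_to_currents(trace, cal: SubjectCalibration):
    """Vectorized decoding of an EAA trace into physical current series.

    Parameters
    ----------
    trace : EAATrace
        Sampled (r_e, a_e) commands with an active-sample mask.
    cal : SubjectCalibration

    Returns
    -------
    (i_f_ma, i_e_ma) : tuple of ndarray
        Physical currents per sample, mA; 0 where the channel is off.

    Raises
    ------
    UnrealizableCommandError
        Naming the first offending sample index.
    """
    r_e = np.asarray(trace.r_e, dtype=float)
    a_e = np.asarray(trace.a_e, dtype=float)
    active = trace.active & (a_e > 0)

    i_e = np.where(active, r_e * a_e, 0.0)
    i_f = np.where(active, (1.0 - r_e) * a_e, 0.0)
    for name, arr in (("extensor", i_e), ("flexor", i_f)):
        bad = np.flatnonzero((arr < -CLAMP_TOL) | (arr > 1.0 + CLAMP_TOL))
        if bad.size:
            raise UnrealizableCommandError(
                f"{name} intensity {arr[bad[0]]:.6g} outside [0, 1] at sample {bad[0]}"
            )
    i_e = np.clip(i_e, 0.0, 1.0)
    i_f = np.clip(i_f, 0.0, 1.0)

    i_f_ma = np.where(active, i_f * cal.flexor.span + cal.flexor.i_min, 0.0)
    i_e_ma = np.where(active, i_e * cal.extensor.span + cal.extensor.i_min, 0.0)
    return i_f_ma, i_e_ma
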