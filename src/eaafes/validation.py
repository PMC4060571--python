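"""Forward-prediction validation of an identified SOPDT model.

Three verification experiments mirror the force-control tasks:

* ``continuous`` — a two-tone composite EAA-ratio input (periods 0.3 and
  0.6 s, weights 0.6/0.4); scored on one steady-state cycle of the 0.6 s
  composite period.
* ``stepwise``  — the 0.2-per-3-s ratio staircase; scored on the settled
  final second of each dwell.
* ``voluntary`` — three 1 s sinusoidal bursts (period 0.5 s) superposed on a
  voluntarily held baseline force of about +/-10 N; scored on the full
  record.

Each experiment simulates both the model prediction and the virtual
subject's "measured" response and reports the coefficient of determination
R^2 = 1 - SS_res/SS_tot (SS_tot about the measured mean) plus the maximum
absolute error.  R^2 over the full trace is always reported alongside the
experiment's segment score.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from eaafes.patterns import BurstSpec, StepSchedule, burst_trace, composite_sinusoid, step_trace
from eaafes.plant import DEFAULT_DT, ForceTrace, SOPDTModel, simulate_with_voluntary
from eaafes.subject import VirtualSubject, run_protocol

EXPERIMENTS = ("continuous", "stepwise", "voluntary")

CONTINUOUS_WEIGHTS = (0.6, 0.4)
CONTINUOUS_PERIODS = (0.3, 0.6)
VOLUNTARY_BASELINE_N = 10.0
SETTLED_WINDOW_S = 1.0  # scored portion at the end of each step dwell


@dataclass(frozen=True)
class ValidationReport:
    """Scores for one verification experiment."""

    r_squared: float
    r_squared_full: float
    max_abs_error: float
    protocol: str
    model_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.r_squared > 1 or self.r_squared_full > 1:
            raise ValueError("R^2 cannot exceed 1")

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "r_squared": self.r_squared,
            "r_squared_full": self.r_squared_full,
            "max_abs_error_n": self.max_abs_error,
            "model_id": self.model_id,
            "subject_id": self.subject_id,
        }


def r_squared(estimated: ForceTrace | np.ndarray, measured: ForceTrace | np.ndarray) -> float:
    """Coefficient of determination of the prediction against the measurement.

    1 - SS_res/SS_tot with SS_tot about the measured mean; the traces must be
    aligned and of equal length.  Raises on a constant measured trace.
    """
    est = estimated.f if isinstance(estimated, ForceTrace) else np.asarray(estimated, float)
    mea = measured.f if isinstance(measured, ForceTrace) else np.asarray(measured, float)
    if est.shape != mea.shape:
        raise ValueError("traces must be aligned and of equal length")
    ss_tot = float(np.sum((mea - mea.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("measured trace is constant; R^2 undefined")
    return 1.0 - float(np.sum((mea - est) ** 2)) / ss_tot


def _experiment_input(experiment: str, dt: float):
    rate = 1.0 / dt
    if experiment == "continuous":
        return composite_sinusoid(CONTINUOUS_WEIGHTS, CONTINUOUS_PERIODS, sample_rate=rate)
    if experiment == "stepwise":
        return step_trace(StepSchedule(), sample_rate=rate)
    if experiment == "voluntary":
        return burst_trace(BurstSpec(), sample_rate=rate)
    raise ValueError(f"unknown experiment {experiment!r}; choose from {EXPERIMENTS}")


def _score_mask(experiment: str, trace, dt: float) -> np.ndarray:
    """Samples entering the experiment's segment score."""
    n = len(trace)
    if experiment == "continuous":
        # one steady-state cycle of the long (0.6 s) composite period
        n_cycle = int(round(max(CONTINUOUS_PERIODS) / dt))
        onset = trace.onset_index
        start = onset + 8 * n_cycle
        mask = np.zeros(n, dtype=bool)
        mask[start : start + n_cycle] = True
        return mask
    if experiment == "stepwise":
        dwell = int(round(StepSchedule().dwell / dt))
        settled = int(round(SETTLED_WINDOW_S / dt))
        mask = np.zeros(n, dtype=bool)
        for start in range(0, n, dwell):
            mask[min(n, start + dwell - settled) : start + dwell] = True
        return mask
    return np.ones(n, dtype=bool)


def run_verification(
    subject: VirtualSubject,
    model: SOPDTModel,
    experiment: str,
    baseline_force: float | None = None,
    n_trials: int = 3,
    dt: float = DEFAULT_DT,
    trial_seed: int | None = None,
    model_id: str = "",
) -> ValidationReport:
    """Run one verification experiment and score the model's prediction.

    The subject's "measured" response is the trial average of
    ``run_protocol``; the prediction is the model's simulated response plus
    the (known) voluntary baseline.  With the ground-truth model, zero noise
    and zero asymmetry, R^2 = 1 and the maximum error is numerically zero.
    """
    trace = _experiment_input(experiment, dt)
    if baseline_force is None:
        baseline_force = VOLUNTARY_BASELINE_N if experiment == "voluntary" else 0.0
    subj = replace(subject, baseline_force=baseline_force)
    measured = run_protocol(subj, trace, n_trials=n_trials, dt=dt, trial_seed=trial_seed)
    mean_measured = measured.mean_force()
    predicted = simulate_with_voluntary(model, trace, baseline_force=baseline_force, dt=dt)

    mask = _score_mask(experiment, trace, dt)
    r2_seg = r_squared(predicted.f[mask], mean_measured.f[mask])
    r2_full = r_squared(predicted, mean_measured)
    max_err = float(np.max(np.abs(predicted.f[mask] - mean_measured.f[mask])))
    return ValidationReport(
        r_squared=r2_seg,
        r_squared_full=r2_full,
        max_abs_error=max_err,
        protocol=experiment,
        model_id=model_id,
        subject_id=subject.subject_id,
    )
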