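"""CSV/JSON formats, run configuration and the end-to-end pipeline.

All on-disk artifacts are plain text: CSV for sampled traces (force,
commands, currents, Bode tables) and JSON for calibrations, models and run
manifests.  Schemas are versioned; unknown versions are rejected rather
than silently coerced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from eaafes import __version__
from eaafes.patterns import EAATrace, frequency_grid, sweep_sinusoid
from eaafes.plant import ForceTrace, SOPDTModel
from eaafes.subject import VirtualSubject, run_protocol, sample_subject
from eaafes.sysid import identify
from eaafes.validation import EXPERIMENTS, run_verification

logger = logging.getLogger("eaafes")

MANIFEST_SCHEMA_VERSION = 1
_TIME_TOL = 1e-6  # s, allowed jitter of the uniform time grid


def write_force_csv(trace: ForceTrace, path: str | Path) -> None:
    # %.17g keeps the roundtrip bit-exact
    pd.DataFrame({"time_s": trace.t, "force_n": trace.f}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_force_csv(path: str | Path) -> ForceTrace:
    """Read a force trace; rejects malformed headers and non-uniform time."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "force_n"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(float)
    dts = np.diff(t)
    bad = np.flatnonzero(dts <= 0)
    if bad.size:
        # +3: 1-based lines, header row, and the offending sample is diff index + 1
        raise ValueError(f"{path}: time not strictly increasing at line {bad[0] + 3}")
    if dts.size and np.max(np.abs(dts - dts.mean())) > _TIME_TOL:
        raise ValueError(f"{path}: non-uniform sampling beyond {_TIME_TOL} s tolerance")
    rate = 1.0 / dts.mean() if dts.size else 0.0
    return ForceTrace(t, df["force_n"].to_numpy(float), rate)


def write_trace_csv(trace: EAATrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.t, "r_e": trace.r_e, "a_e": trace.a_e, "active": trace.active.astype(int)}
    ).to_csv(path, index=False, float_format="%.17g")


def read_trace_csv(path: str | Path) -> EAATrace:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "r_e", "a_e"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time not strictly increasing")
    active = (
        df["active"].to_numpy(bool)
        if "active" in df.columns
        else np.ones(t.shape, dtype=bool)
    )
    rate = 1.0 / float(np.mean(np.diff(t))) if t.size > 1 else 0.0
    return EAATrace(t, df["r_e"].to_numpy(float), df["a_e"].to_numpy(float), rate, active)


def write_bode_csv(points, path: str | Path) -> None:
    pd.DataFrame(
        {
            "omega_rad_s": [p.omega for p in points],
            "gain_db": [p.gain_db for p in points],
            "phase_rad": [p.phase for p in points],
        }
    ).to_csv(path, index=False)


def write_harmonic_csv(fits, path: str | Path) -> None:
    pd.DataFrame(
        {
            "period_s": [f.period_t for f in fits],
            "amplitude_n": [f.amplitude_a for f in fits],
            "phase_rad": [f.phase_phi for f in fits],
            "offset_n": [f.offset_c for f in fits],
            "r_squared": [f.r_squared for f in fits],
        }
    ).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of one end-to-end identification + validation run.

    All randomness flows from ``seed`` through named substreams (subject
    parameters, trial noise).  The config is validated up front and echoed
    into every output manifest.
    """

    seed: int = 0
    sample_rate: float = 1000.0
    n_trials: int = 3
    n_cycles: int = 10
    noise_sd: float = 0.5
    asymmetry: float = 0.0
    baseline_force: float = 0.0
    periods: tuple[float, ...] = field(default_factory=lambda: tuple(frequency_grid()))
    experiments: tuple[str, ...] = EXPERIMENTS

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.n_trials < 1 or self.n_cycles < 8:
            raise ValueError("invalid config: need rate > 0, trials >= 1, cycles >= 8")
        if any(T <= 0 for T in self.periods):
            raise ValueError("periods must be positive")
        unknown = set(self.experiments) - set(EXPERIMENTS)
        if unknown:
            raise ValueError(f"unknown experiments: {sorted(unknown)}")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def to_dict(self) -> dict:
        d = asdict(self)
        d["periods"] = list(self.periods)
        d["experiments"] = list(self.experiments)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def derive_seeds(seed: int) -> dict[str, int]:
    """Named substream seeds derived from the top-level seed."""
    ss = np.random.SeedSequence(seed)
    subject_ss, trial_ss = ss.spawn(2)
    return {
        "subject": int(subject_ss.generate_state(1)[0] % 2**31),
        "trials": int(trial_ss.generate_state(1)[0] % 2**31),
    }


def pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full study on one synthetic subject.

    Stages: sample a virtual subject, run the sinusoidal sweep protocol over
    the period grid, identify the SOPDT model, and score the three
    verification experiments.  Deterministic given ``config.seed``.

    Returns a dict with the subject, identified model, Bode table, harmonic
    fits, validation reports and a manifest; optionally writes all artifacts
    under ``out_dir``.
    """
    t0 = time.perf_counter()
    seeds = derive_seeds(config.seed)
    subject = sample_subject(
        seeds["subject"],
        noise_sd=config.noise_sd,
        asymmetry=config.asymmetry,
        baseline_force=config.baseline_force,
    )
    logger.info("stage subject: id=%s plant=%s", subject.subject_id, subject.plant)

    trial_sets = []
    for i, T in enumerate(config.periods):
        trace = sweep_sinusoid(T, n_cycles=config.n_cycles, sample_rate=config.sample_rate)
        trial_sets.append(
            run_protocol(
                subject,
                trace,
                n_trials=config.n_trials,
                dt=config.dt,
                trial_seed=seeds["trials"] + i,
            )
        )
    logger.info("stage protocol: %d periods x %d trials", len(trial_sets), config.n_trials)

    model, fits, points = identify(trial_sets)
    logger.info("stage identify: %s", model)

    reports = [
        run_verification(
            subject,
            model,
            exp,
            n_trials=config.n_trials,
            dt=config.dt,
            trial_seed=seeds["trials"] + 1000,
            model_id="identified",
        )
        for exp in config.experiments
    ]
    logger.info("stage validate: %s", {r.protocol: round(r.r_squared, 4) for r in reports})

    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "package_version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "derived_seeds": seeds,
        "ground_truth": subject.plant.to_dict(),
        "wall_time_s": round(time.perf_counter() - t0, 3),
    }
    result = {
        "subject": subject,
        "model": model,
        "fits": fits,
        "bode": points,
        "reports": reports,
        "manifest": manifest,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.save(out / "model.json")
        subject.calibration.save(out / "calibration.json")
        write_bode_csv(points, out / "bode.csv")
        write_harmonic_csv(fits, out / "harmonic_fits.csv")
        (out / "validation.json").write_text(
            json.dumps([r.to_dict() for r in reports], indent=2) + "\n"
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result
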