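"""Packaged reference data for the six study subjects (A-F).

``calibrations.json`` holds the per-muscle stimulation-current limits,
``models.json`` the identified SOPDT parameters (plus the worked-example
model ``eq12``, stored verbatim), and ``activity_anchors.json`` the
activity-to-natural-frequency anchor points measured for subject A.
"""

from __future__ import annotations

import json
from importlib import resources

from eaafes.calibration import SubjectCalibration
from eaafes.plant import SOPDTModel


def _read(name: str) -> dict:
    return json.loads(resources.files(__package__).joinpath(name).read_text())


def reference_calibrations() -> dict[str, SubjectCalibration]:
    """Stimulation-current calibrations for subjects A-F, keyed by id."""
    raw = _read("calibrations.json")
    return {sid: SubjectCalibration.from_dict(d) for sid, d in raw["subjects"].items()}


def reference_models() -> dict[str, SOPDTModel]:
    """Identified SOPDT models for subjects A-F plus the ``eq12`` example."""
    raw = _read("models.json")
    return {sid: SOPDTModel.from_dict(d) for sid, d in raw["subjects"].items()}


def activity_anchors() -> tuple[tuple[float, float], ...]:
    """(a_E, omega_n) anchor pairs for the activity-to-stiffness map."""
    raw = _read("activity_anchors.json")
    return tuple((p["a_e"], p["omega_n"]) for p in raw["anchors"])
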