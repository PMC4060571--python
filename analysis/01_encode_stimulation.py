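"""Encode the sinusoidal EAA-ratio protocol into per-muscle stimulation currents.

For reference subject B, drives the two-muscle calibration with the
identification sweep (r_E = -0.5*sin(2*pi*t/T) + 0.5, a_E = 1) and recovers
the amplitude and offset of each muscle's physical current trace by harmonic
regression.  The triceps (extensor) current should be -3.0*sin + 8.0 mA and
the biceps (flexor) current 4.5*sin + 7.0 mA, exactly, because the affine
calibration map preserves the sinusoid.

Writes results/stimulation_encoding.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from eaafes import command_trace_to_currents, harmonic_fit, sweep_sinusoid
from eaafes.data import reference_calibrations

RESULTS = Path(__file__).resolve().parents[1] / "results"

T = 0.3  # s; any grid period gives the same coefficients


def sine_coefficients(series: np.ndarray, t: np.ndarray, period: float):
    """Signed sine coefficient and constant offset of a sampled sinusoid."""
    fit = harmonic_fit(series, period, sample_rate=1.0 / (t[1] - t[0]))
    # signed coefficient of sin: A*cos(phi); cos term A*sin(phi) should vanish
    return fit.amplitude_a * np.cos(fit.phase_phi), fit.offset_c


def main() -> None:
    cal = reference_calibrations()["B"]
    trace = sweep_sinusoid(T, n_cycles=10)
    i_f_ma, i_e_ma = command_trace_to_currents(trace, cal)

    onset = trace.onset_index
    n = int(round(T * trace.sample_rate))
    rows = []
    for muscle, series in (("triceps (extensor)", i_e_ma), ("biceps (flexor)", i_f_ma)):
        cycle = series[onset : onset + n]
        coeff, offset = sine_coefficients(cycle, trace.t[onset : onset + n], T)
        rows.append({"muscle": muscle, "sine_coeff_ma": coeff, "offset_ma": offset})
        print(f"{muscle}: I'(t) = {coeff:+.10f} * sin(2*pi*t/T) + {offset:.10f} mA")

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "stimulation_encoding.csv", index=False)
    print(f"wrote {RESULTS / 'stimulation_encoding.csv'}")


if __name__ == "__main__":
    main()
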