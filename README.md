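# eaafes — equilibrium-point FES control of the elbow joint

`eaafes` models and identifies the input–output behaviour of a human elbow
joint driven by multichannel functional electrical stimulation (FES) of an
agonist–antagonist muscle pair (biceps/triceps) under isometric conditions.
It is written for researchers in neuroprosthetics and motor control who want
a tested, fully synthetic re-implementation of the equilibrium-point
stimulation-coding and system-identification chain: no stimulator hardware or
human data is required to run, test, or extend any stage.

## The model

Following the equilibrium-point hypothesis, the two stimulation channels are
coded by two scalars instead of two raw currents:

- **EAA ratio** `r_E = I_e / (I_f + I_e)` — the extensor's share of the total
  normalized intensity; it sets the joint's equilibrium point.
- **EAA activity** `a_E = I_f + I_e` — the total normalized intensity; it sets
  joint stiffness.

Normalized intensities map affinely onto physical currents between each
muscle's contraction threshold `I'_min` and pain-free maximum `I'_max`.
With `a_E` fixed at 1, the ratio-to-hand-force dynamics are identified as a
critically damped second-order system with dead time (SOPDT),

```
G(s) = K · ωn² / (s² + 2ζωn s + ωn²) · e^(−τs),   ζ = 1
```

with gain `K` (N per unit `r_E`), natural frequency `ωn` (rad/s), and
stimulation-to-force latency `τ` (s). Identification drives the joint with
sinusoidal ratio sweeps `r_E(t) = −0.5·sin(2πt/T) + 0.5` over 17 periods
`T = 0.100 … 0.500 s`, extracts one steady-state cycle per period (trial mean,
then mean of cycles 3–8), fits a single harmonic
`f(t) ≈ A·sin(2πt/T + φ) + c` by least squares, assembles the Bode table, and
fits `(K, ωn)` on the gain curve and `τ` on the residual phase. A virtual
subject (SOPDT ground truth + measurement noise + optional extensor/flexor
asymmetry, voluntary baseline force, and activity-dependent stiffness) stands
in for the human, so the whole chain is testable end to end.

## Worked example

```python
import numpy as np
from eaafes import command_trace_to_currents, simulate, sweep_sinusoid
from eaafes.data import reference_calibrations, reference_models

# two-muscle current coding for reference subject B
trace = sweep_sinusoid(T=0.3)                  # r_E sinusoid, a_E = 1
i_f, i_e = command_trace_to_currents(trace, reference_calibrations()["B"])
on = trace.onset_index
print(i_e[on], i_f[on])                        # 8.0 7.0  (mA, at r_E = 0.5)
print(i_e[on + 75], i_f[on + 75])              # 5.0 11.5 (mA, at r_E = 0)

# force predicted by the reference plant for a unit ratio step
model = reference_models()["eq12"]             # K=11.22, ωn=20.5, ζ=1, τ=0.05
out = simulate(model, np.ones(2000))
print(round(out.f[-1], 2))                     # 11.22  (N, settled at K)
```

At the balanced ratio `r_E = 0.5` both muscles sit halfway between their
calibration limits (triceps 8.0 mA, biceps 7.0 mA); a quarter period later the
command is pure flexion (triceps at threshold 5.0 mA, biceps at maximum
11.5 mA). The step response settles at the model's DC gain, 11.22 N.

The full study is scripted under `analysis/`:
`01_encode_stimulation.py` (current coding), `02_plant_response.py`
(time/frequency-domain plant checks), `03_identify.py` (parameter recovery,
noiseless and Monte-Carlo), `04_validate.py` (force-prediction scoring).
Each writes its tables under `results/`.

## Layout

- `src/eaafes/` — library: `calibration` (EAA coding), `patterns` (protocols),
  `plant` (SOPDT model), `subject` (virtual subject), `sysid` (identification),
  `validation` (prediction scoring), `io` (formats + pipeline), `data/`
  (reference calibrations and models for subjects A–F).
- `analysis/` — numbered study drivers.
- `docs/methods.md` — modelling assumptions, parameter choices, limitations.
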