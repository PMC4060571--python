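# Methods

## Scope and model

The package treats one elbow joint in an isometric rig: stimulation of the
biceps (flexor) and triceps (extensor) produces a hand force sampled at
1000 Hz, negative in flexion. Stimulation is commanded through the EAA ratio
`r_E` (extensor share of the total normalized intensity, the equilibrium
point) and EAA activity `a_E` (total normalized intensity, the stiffness).
The ratio-to-force dynamics are a critically damped second-order transfer
function with dead time,

    G(s) = K ωn² / (s² + 2ζωn s + ωn²) e^(−τs),  ζ = 1 fixed,

which captures the two features the frequency response shows: a second-order
gain roll-off (−40 dB/dec asymptote) and a phase lag in excess of any
rational second-order system, attributed to the stimulation-to-force latency
τ. Linearity is assumed throughout; co-contraction nonlinearity, fatigue,
recruitment saturation and joint motion are out of scope.

## Parameters

| parameter | units | default / range | meaning |
|---|---|---|---|
| `K` | N per unit r_E | 1.04–11.22 (reference range) | steady-state force per unit ratio |
| `ωn` | rad/s | 14.0–31.4 (reference range) | natural frequency; grows with a_E |
| `ζ` | – | 1 (fixed) | damping; critically damped by assumption |
| `τ` | s | 0.045–0.100 (reference range) | stimulation-to-force dead time |
| `I'_min`, `I'_max` | mA | per subject/muscle | contraction threshold / pain-free maximum |
| sample rate | Hz | 1000 | force acquisition and command rate |
| noise_sd | N | 0.5 | additive Gaussian measurement noise (see below) |

The reference ranges and the six per-subject calibration and model fixtures
in `eaafes/data/` are the published values for six adult subjects (A–F); the
`eq12` model (K = 11.22, ωn = 20.5, ζ = 1, τ = 0.05) is the worked-example
plant used by the analysis scripts and tests.

## Identification pipeline

Per period T of the 17-period grid (0.100–0.500 s in 0.025 s steps): three
trials of 10 input cycles are averaged, the post-onset record is cut at the
input-cycle boundaries (half-open windows [kT, (k+1)T), 1-based numbering),
and cycles 3–8 are averaged into one steady-state cycle. A single harmonic
`p·sin + q·cos + c` is fitted by ordinary least squares; `A = √(p²+q²)`,
`φ = atan2(q, p)`, so `A·sin(θ+φ) + c` reproduces the fit identically (the
convention is pinned by a test). Gain is `A / 0.5` (0.5 is the input
sinusoid's amplitude); phase is measured against the input's −sin convention
and unwrapped from the lowest frequency upward. `(K, ωn)` minimize the
squared dB error of the ζ = 1 gain curve, initialized deterministically from
a log-grid over ωn ∈ [5, 100] rad/s with the per-ωn optimal K in closed form
(no random restarts); τ is the through-origin regression slope of the
residual phase `φ_meas + 2·atan(ω/ωn)` on −ω, clamped at τ ≥ 0. The offset
`c` is excluded from the transfer-function fit and reported per period as
the vibration-center-shift diagnostic.

## Numerical choices

- **Simulation.** The second-order core is discretized by first-order hold
  (matrix exponential of the companion form), exact for piecewise-linear
  inputs. This preserves the DC gain exactly and, unlike a zero-order hold,
  adds no half-sample input lag — a 0.5 ms artifact that would otherwise
  exceed the phase agreement budget at the top of the frequency grid and
  bias fitted dead times. Dead time is an integer-sample shift at dt = 1 ms
  (the reference τ values are multiples of 5 ms); outputs before
  onset + τ are exactly zero.
- **Pre-input conditioning.** The analyzed input starts 0.5 s after
  measurement start. By default the conditioning interval carries the
  sinusoid phase-continuously (mode `"cycle"`), so the joint is in periodic
  steady state when the analyzed cycles begin and the cycles 3–8 window is
  exactly steady. With stimulation OFF before onset (mode `"off"`), the
  switch-on transient has not decayed by cycle 3 at short periods — a 1.8%
  gain bias at T = 0.1 s for ωn = 20.5 rad/s, growing for slower plants —
  which contaminates recovered parameters by up to tens of percent for the
  slowest reference dynamics. Real experiments necessarily start from rest
  and carry (a milder version of) this bias; the synthetic study removes it
  so that identification accuracy, not protocol transients, is what the
  tests measure. Modes `"hold"` (balanced co-contraction) and `"off"` remain
  available.
- **Degenerate inputs.** Zero activity means both channels physically OFF
  (0 mA) — `I'_min` is a contraction threshold, not zero output — and the
  ratio is recorded as undefined (NaN). Computed intensities within 1e−9 of
  [0, 1] are clamped; larger excursions raise an error naming the muscle
  and sample.

## The virtual subject

The generator produces "measured" 1 kHz force traces with the statistical
structure the analysis assumes:

- **Plant input.** The subject drives its plant with `u = a_E · r_E` (the
  extensor normalized intensity). At the identification activity `a_E = 1`
  this is exactly `r_E`, so the plant contract is unchanged; at lower
  activity the force displacement scales down, reproducing the
  stiffness-like effect of total drive. The activity map `ωn(a_E)` is a
  piecewise-linear interpolation through anchor points (default: the
  subject-A triple 0.5 → 14.3, 0.8 → 19.0, 1.0 → 20.5 rad/s), clamped at the
  ends.
- **Noise.** Gaussian white noise at the sample level, default sd 0.5 N — a
  level at which single-trial sweeps are visibly noisy but three-trial,
  six-cycle averaging yields clean cycles; the level is configurable and
  recorded in every manifest.
- **Asymmetry.** The extensor/flexor response-speed imbalance is represented
  only by its phenomenology: a positive offset
  `c(T) = asymmetry · K · max(0, 0.4 − T)/0.4` added to the oscillating
  output at input periods T ≤ 0.4 s and vanishing above. This is an
  explicitly synthetic stand-in — no muscle-dynamics mechanism is modelled —
  and exists so the offset diagnostic has something to detect.
- **Voluntary baseline.** A held central-command force adds linearly to the
  stimulation response (superposition of movement commands).
- **Sampling.** Random subjects draw (K, ωn, τ) independently and uniformly
  within the reference ranges; no physiological covariance is claimed. All
  randomness flows from named, spawned seed streams, so subjects, trials and
  pipelines are exactly reproducible.

Because the subject is linear with additive stationary noise, passing tests
demonstrate the correctness and noise robustness of the pipeline — not its
behaviour under fatigue, recruitment nonlinearity, day-to-day calibration
drift, or non-stationary voluntary drive, none of which are emulated.

## Validation experiments

Three forward-prediction tasks score an identified model against the
subject's measured response by `R² = 1 − SS_res/SS_tot` (SS_tot about the
measured mean) and the maximum absolute error:

- **continuous** — two-tone ratio input (periods 0.3/0.6 s, weights
  0.6/0.4); scored on one steady-state cycle of the 0.6 s composite period
  (the ninth), since steady-state waveform agreement is what the task
  probes;
- **stepwise** — ±0.2 ratio staircase every 3 s, 0 → 1 → 0; scored on the
  final second of each dwell (settled plateaus);
- **voluntary** — three 1 s bursts (two 0.5 s cycles each) at t = 1, 4, 7 s
  over a held baseline of ±10 N, stimulation OFF between bursts; scored on
  the full record.

Full-trace R² is always reported alongside the segment score, since which
portion enters the statistic is a reporting choice, not a property of the
model.

## Problem sizes and known limitations

The test suite and analysis scripts run the full 17-period grid with 3
trials × 10 cycles per period (the study's own protocol) and 20-seed
Monte-Carlo batches for noisy-recovery statistics; these sizes keep every
check well characterized while running in seconds. Known limitations: ζ is
never estimated (fixed at 1), the fitted τ inherits a ≤ 1-sample
quantization from the 1 kHz grid, identification assumes the fundamental
harmonic dominates (no distortion analysis), and the asymmetry and noise
models are synthetic conveniences, not physiology. The high-frequency slope
measured on real data over an unspecified band is steeper than the ζ = 1
asymptote; the package asserts only the −40 dB/dec second-order property.
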