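# Methods

Conventions, models, parameter sources, numerical choices, and limitations
of the `trackloop` identification pipeline.

## Signal and phasor conventions

A sum-of-sines component is `M · sin(2πft + φ)`, represented by the complex
phasor `c = M · e^{jφ}`. The single-frequency DFT that inverts this
convention over a record `x(t)` sampled at `f_s` is

```
c = j · (2/N) · Σ_n x(t_n) · e^{-j2πf t_n}
```

This is exact (no leakage) whenever the analysis window contains an integer
number of cycles of every component present, which the design guarantees:
all frequencies are multiples of the 0.04 Hz base, trials last 75 s with the
first 25 s discarded, and the remaining 50 s window is two full base
periods. The highest stimulated frequency (2.84 Hz) is far below the 40 Hz
Nyquist limit at the 80 Hz sample rate.

Transfer functions are evaluated at `s = j2πf`. A pure delay τ contributes
`e^{-sτ}` and enters the complex residual directly, so fitting never
involves phase unwrapping.

## Stimulus design

- **Grid**: the first 20 prime multiples of 0.04 Hz — 0.08 to 2.84 Hz.
  Prime multipliers make every stimulated frequency harmonically independent
  of the others: no frequency is an integer multiple, sum, or difference of
  any two others, so nonlinear intermodulation products of the subject never
  land on a stimulated line.
- **Amplitude profile**: `min(c_v / f, cap)` with `(c_v, cap)` = (1.3, 2.3)
  cm for the reference and (0.7, 1.5) cm for the disturbance. This caps
  both component displacement (2.3 / 1.5 cm) and component velocity
  (2π·1.3 ≈ 2.6π and 2π·0.7 = 1.4π cm/s). The profile is stated as a
  minimum because only the minimum satisfies both bounds simultaneously.
- **Session**: the grid is split round-robin into four reference groups
  (r1–r4) and four disturbance groups (d1–d4) of five frequencies each.
  A four-row rotation assigns groups to the four stimulus roles
  (x-reference, x-disturbance, y-reference, y-disturbance) such that the
  reference and disturbance sets on each axis are always disjoint; the
  rotation crossed with two preview conditions (0 and 500 ms) and two
  repetitions gives 16 trials, presented in a seeded pseudo-random order.
  Pooled over a rotation, every frequency appears in every role.

## Closed-loop model and simulation

Feedforward pathway `PF` acts on the (possibly preview-filtered) reference,
feedback pathway `PB` on the visual error:

```
Y = (PF + PB)·M·R / (1 + PB)  +  D / (1 + PB)
H_YR = (PF + PB)M / (1 + PB),    H_YD = 1 / (1 + PB)
```

with preview filter `M = 1` in the no-preview condition. Synthetic trials
are simulated in steady state by frequency-domain superposition: each
stimulus component is propagated through the exact closed-loop response at
its own frequency and re-synthesised in time. This is exact for the linear
models used (no ODE integration, no transient error); the 25 s discard is
retained anyway so the analysis path matches the experimental protocol.
Optional remnant noise is white Gaussian on the cursor output. A simulated
subject is rejected if `|1 + PB|` comes within 1e-6 of zero on the grid.

## Pathway models

| name | transfer function | parameters |
|---|---|---|
| `gain_delay` | `k·e^{-sτ}` | k, τ |
| `leaky_integrator_delay` | `k·e^{-sτ}/(s + a)` | k, τ, a |
| `first_order_delay` | `k·e^{-sτ}/(1 + s/a)` | k, τ, a |
| `second_order_delay` | `k·e^{-sτ}/((s+a)(s+b))` | k, τ, a, b |

`first_order_delay` is a reparameterisation of the leaky integrator
(`k/(1+s/a) = ka/(s+a)`); the selection tie-break below keeps the declared
McRuer-style form when both fit equally.

### Generating parameters for synthetic groups

The synthetic cohorts in `GROUP_PARAMS` use the published group-level
best-fit values: feedforward delay 185 ms (control) / 245 ms (ataxia);
feedback gain 1.3 / 1.0, delay 123 ms / 144 ms. Two quantities are **not**
reported at group level and are package defaults: the feedforward gain
(0.6) and the feedback integrator pole (a = 0.5 rad/s). The counterfactual
conclusions are checked over a pole sweep (0.1–2.0 rad/s) precisely because
`a` is a convention, not a measurement. The demo preview filters
(time advance cascaded with a first-order low-pass) are likewise
illustrative choices that reproduce the qualitative preview benefit, not
fitted quantities.

## Estimation, isolation, fitting

- **FRF estimation**: per trial and axis, `H = DFT(y)/DFT(input)` at each
  stimulated frequency of the relevant role; estimates are pooled across
  trials by complex mean. Missing frequency coverage or a vanishing input
  line raises a `CoverageError` rather than producing silent NaNs.
- **Isolation** is exact algebra: `PB = 1/H_YD − 1`,
  `PF = H_YR/H_YD − 1/H_YD + 1`, with a `NearSingularError` naming the
  offending frequencies when `|H_YD|` is within 1e-8 of zero.
- **Fitting** minimises `FD_error = Σ_f |model(f) − data(f)|²` with
  Nelder–Mead from 100 uniform random starts inside the bounds
  k ∈ (1e-6, 5], τ ∈ [0, 0.6] s, poles ∈ (1e-3, 20]; out-of-bounds points
  are penalised. Tight simplex tolerances (`xatol` 1e-10, `fatol` 1e-14)
  let zero-residual problems converge to ~1e-8 parameter accuracy.
- **Selection** uses leave-one-subject-out cross-validation: fit to the
  complex mean of the remaining subjects, score on the held-out subject;
  CVE = mean validation error. Among structures within 5% of the best CVE
  the fewest-parameter structure wins; FD-error ties (again within 5%, with
  an absolute 1e-12 floor so exact fits tie) fall through to the declared
  candidate order.

## Preview filter

The two-channel reference-controller form `PH_R = H_YR/H_YD = M(PF + PB)`
and `PH_B = PB` gives the preview filter as the cross-condition ratio
`M = PH_R(preview)/PH_R(no preview)`. The feedback channel must be
condition-invariant; the estimator reports the ratio
`PH_B(preview)/PH_B(no preview)` and warns when it departs from 1 by more
than 20%, since a changed feedback channel invalidates the division.

## Stability margins and counterfactual

The open loop of the disturbance-rejection loop is `PB` itself. Margins are
read from 1000 log-spaced samples over 0.08–2.84 Hz by linear interpolation
of log-magnitude and unwrapped phase against log-frequency: the phase
margin is `180° + ∠L` at the first unit-magnitude crossing, the gain margin
`1/|L|` at the first −180° crossing; crossovers outside the band yield
`inf` (gain margin) or `NaN` sentinels. Nonparametric margins from
estimated FRFs use the same path after optional magnitude/phase smoothing
(default 3-point window, endpoints untouched). The interpolation path is
validated against closed forms (`e^{-0.3s}/s`: PM ≈ 72.81°, GM = π/0.6) and
dense root-finding to 0.1° / 0.01.

Tracking error is the mean squared cursor-target distance over the analysis
window, summed over both axes. The gain-swap counterfactual replaces only
the feedback gain of a subject, re-simulates the identical session, and
compares tracking error and margins.

## Limitations

- The simulator is linear and time-invariant; it produces no nonlinear
  distortion, crossover remnant, or learning effects, so recovery of the
  generating parameters is exact rather than merely unbiased. Remnant
  noise is modelled as additive white Gaussian output noise only.
- The feedforward gain and feedback integrator pole of the synthetic
  groups are conventions (see above); quantities that depend on them
  (absolute margin values, absolute MSE) are illustrative, while delay and
  gain contrasts between groups are the fitted published values.
- Margins are band-limited to the stimulated range; crossovers outside
  0.08–2.84 Hz are reported as sentinels, not extrapolated.
- Group-level inferential statistics (t-tests, ANOVA, correlations with
  clinical scores) are deliberately out of scope; `summarize` produces the
  per-subject tables such analyses consume.
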