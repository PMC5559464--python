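# Methods

## The function curve

The baroreflex stimulus–response relation is modelled as the
four-parameter logistic `Y = A1/(1 + exp[A2(X − A3)]) + A4` mapping mean
arterial pressure (mmHg) to sympathetic nerve activity (arbitrary units).
The convention is `A1, A2 > 0` with the decreasing branch implied by the
functional form, and `A4 ≥ 0` since nerve activity is non-negative. All
derived descriptors are closed forms: threshold `A3 − ln(19)/A2`,
saturation `A3 + ln(19)/A2` (the exact solutions of the 5%-of-range
conditions), operating range `2·ln(19)/A2`, and maximum gain `A1·A2/4` at
`A3`. The test suite cross-checks the closed forms against an independent
bracketed root-finder on the curve itself (agreement to 1e−9 mmHg) and the
analytic gain against central finite differences.

For `|A2(X − A3)| > 700` evaluation returns the exact plateau value; the
exponential would otherwise overflow while the curve is already flat to
machine precision.

## Fitting

`fit_logistic` is bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) with a
data-driven start: `a4 ← min(SNA)`, `a1 ← range(SNA)`, `a3 ←` the pressure
whose SNA is nearest mid-range, and `a2 ← 4·|local slope|/a1` from a
linear fit in a ±10 mmHg window around `a3`. Four additional starts are
jittered with a seeded generator, so a fit is a deterministic function of
(series, options). Bounds: `a1, a2 > 0`, `a4 ≥ 0`.

Identifiability guards: at least 8 points, a pressure span of at least
20 mmHg, and a non-flat response are required; violations raise
`UnidentifiableDataError` rather than returning garbage parameters.
Optimizer failure on identifiable data returns `converged=False`.

One consequence of the `a4 ≥ 0` bound is worth knowing: when the true
curve is pinned at exactly zero over a long saturated segment (as the
rectified circuit's rest curve is), the unconstrained optimum for `a4` is
slightly negative and the bound is active; a constant offset added to such
data then shifts the fitted `a4` by slightly less than the offset (~0.6
a.u. for the default circuit). Between two strictly interior offsets the
shift is exact.

Under the reference recovery conditions (n = 200 samples over
60–180 mmHg, Gaussian noise sd = 2 a.u. ≈ 2% of the response range), the
mean bias of every recovered parameter over 100 replicates is below 0.2%,
well inside the 2% design requirement.

## The circuit model

The central arc is a static composition — the model is an input–output
map, not a dynamical system:

```
afferent  a = σ(k_a (P − p_a))           baroreceptor afferent, [0, 1]
NTS       n = σ(k_n (a − θ_n − m1))      second-order relay, [0, 1]
CVLM      c = (1 + m2) n                 inhibitory interneurons
RVLM      r = max(0, d0 + m3 − w c)      premotor neurons, tonic drive d0
SNA       y = max(0, s0 r + m4)          spinal output
```

with σ the logistic sigmoid. The anatomy fixes only the wiring (an
excitatory relay, an inhibitory interneuron stage, a tonically driven
premotor stage, and a spinal output); the transfer functions above are the
simplest composition that realises all four mechanism contracts — a
sigmoid afferent and relay, a linear CVLM with multiplicative
facilitation, a rectified-linear RVLM subtraction, and an additive
baroreflex-independent output drive. The contracts, not these particular
equations, are the normative surface: each modulation swept alone must
reshape the fitted curve in its own characteristic way (m1 right-shift,
m2 gain, m3 upper plateau, m4 both plateaus) with the pinned descriptors
moving by less than 2% of the response range, and the test suite checks
exactly that.

Default constants: `k_a = 0.06 /mmHg`, `p_a = 115 mmHg`, `k_n = 10`,
`θ_n = 0.5`, `w = 1.5`, `d0 = 1`, `s0 = 100 a.u.` They put the rest curve
at plateaus ≈ 97/0 a.u. with an operating range of ≈ 55 mmHg and a
midpoint near 110 mmHg — a realistic resting sympathetic function curve
for a conscious animal. The admissibility condition `w ≥ d0 + max(m3)`
(default `max_m3 = 0.5`) guarantees that full CVLM activation silences the
RVLM, which is what pins the lower plateau at exactly `m4`; `m3` above
`max_m3` is rejected. Rectification at zero for RVLM activity and SNA
encodes the non-negativity of firing rates.

Because of the rectification, the simulated curve is logistic-like but
not exactly logistic (a hard kink where RVLM activity reaches zero);
logistic fits to it achieve r² ≥ 0.996 on the default grid, and residual
effects of the kink are what make the 2% cross-effect tolerances
necessary rather than zero.

Modulations are signed: the model's prose motivation concerns increases
(exercise, stress), and the down-and-left displacement seen in sleep is
encoded as negative `m1` and `m3`, keeping one mechanism vocabulary for
all states.

### Behavioral presets

Preset magnitudes are package defaults (overridable per run; no
quantitative consensus values exist for them):

| state | m1 | m2 | m3 | m4 | rationale |
|---|---|---|---|---|---|
| rest | 0 | 0 | 0 | 0 | no modulatory inputs active; only the tonic RVLM drive |
| exercise | 0.15 | 0.5 | 0.3 | 10 | all four mechanisms engaged: up-and-right shift with higher gain |
| stress | 0.20 | 0.4 | 0 | 0 | right shift with higher gain, plateaus unchanged |
| sleep | −0.10 | 0 | −0.30 | 0 | down-and-left shift |

Stress is modelled with mechanisms 1 and 2 only: the observed stress
phenotype is a shift to higher pressures with increased gain, and there
is no comparable evidence for plateau changes, so `m3 = m4 = 0` is the
conservative encoding. The stress `m1` is set to 0.20 (larger than the
exercise component) because CVLM facilitation on its own drags the
fitted midpoint left by a few mmHg; the chosen pair yields a net
rightward shift of ≈ 10 mmHg, comparable to the exercise preset, so the
state expresses an unambiguous lateral resetting alongside the gain
increase.

### Resetting types

State-vs-rest comparisons are summarised by four deltas (midpoint, max
gain, upper plateau, lower plateau) computed from the fitted curve
metrics. A type is "present" when its delta exceeds a tolerance in
magnitude; defaults are 5 mmHg for the midpoint and 5% of the rest
curve's corresponding descriptor for the others, since no standard
definition of "significant" resetting exists. Types are numbered to match
the mechanism that produces each effect: 1 lateral shift, 2 gain,
3 upper plateau, 4 lower plateau.

## Mechanism inference

`infer_mechanisms` estimates `(m1, m2, m3, m4)` by least squares between
the forward model and a state series, optimizing in
`(m1, log(1 + m2), m3, m4)` so the CVLM gain stays positive, with bounds
keeping `m3` within the circuit's admissible range and `m4 ≥ 0`;
multi-start (5 starts, seeded) guards against local minima. The rest
series is used only as a check that the shared circuit is the right
baseline: if the unmodulated circuit explains the rest data with
r² < 0.9, inference refuses to proceed (`BaselineMismatchError`) rather
than attributing circuit miscalibration to behavioral mechanisms.

The four mechanisms leave nearly orthogonal fingerprints (m4 pins the
lower plateau, m3 the upper, m1 the midpoint, m2 the slope), so the
inverse problem is well posed: noiseless round-trips recover every preset
to machine-level accuracy, and with 2 a.u. noise on ~190-sample ramps the
mean estimate over 10 replicates is within 15% of truth for every active
mechanism. Single noisy replicates can trade `m2` against `m4` by more
than that; the replicate mean is the meaningful accuracy statement. The
`m4 ≥ 0` bound gives zero-truth `m4` a small positive half-normal bias
(< 1 a.u.) in noisy data.

## Synthetic data

The generator emulates a modified-Oxford run: a piecewise-linear pressure
trajectory (start → nadir → peak at a constant rate, default
100 → 60 → 180 mmHg at 1 mmHg/s sampled at 1 Hz) through the forward
circuit, plus additive Gaussian noise on SNA only, rectified at zero.
Pressure is treated as measured exactly. Everything is a pure function of
its arguments including seeds; per-state seeds in a bundle are derived
from the base seed and the state index via a seed sequence.

What the generator deliberately does not emulate: beat-to-beat cardiac
and respiratory modulation, baroreceptor adaptation, and hysteresis
between the falling and rising limbs of the ramp. Passing tests on this
data therefore demonstrate correctness of the estimation machinery under
the stated noise model, not robustness to those physiological
complications in real recordings.

## Numerical and scale choices

- Analysis grid: 40–200 mmHg at 1 mmHg (`default_pressure_grid`), wide
  enough that both plateaus of the default circuit are pinned by data
  rather than extrapolation.
- Recovery and inference studies use 100 fit replicates and 10 inference
  replicates per state; at these sizes the full suite runs in seconds.
- Admissible sweep ranges for the mechanism contracts: m1 ∈ [0, 0.2],
  m2 ∈ [0, 1], m3 ∈ [0, 0.4], m4 ∈ [0, 20]. Beyond m1 ≈ 0.25 the
  operating point moves so far into the afferent sigmoid's tail that the
  fitted upper plateau drifts by more than 2%, which is a property of
  this realization, not of the mechanism idea.
- Series CSVs round-trip losslessly (`float_precision="round_trip"` on
  read); parameter files are JSON with unknown-key and missing-key
  rejection.

## Known limitations

- The circuit is one admissible realization of the wiring diagram; other
  transfer-function choices satisfying the same contracts would give
  different absolute modulation magnitudes. Inferred `m` values are
  therefore comparable within this model, not across models.
- The model is static: resetting in reality is a continuous process, and
  protocols that sweep pressure faster than the reflex settles would
  violate the static assumption.
- Only the sympathetic vasomotor limb is modelled; the cardiac (vagal)
  limb of the reflex is out of scope.
- Classification tolerances are analysis conventions, not statistical
  tests; no subject-level variability model is provided.
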