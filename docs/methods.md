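# Methods

## The result contract

Every model returns an `NDResult`: a labeled float array over
`(mode, time, x[, y, z])` — mode and time mandatory, up to three spatial
axes, five axes total — with explicit coordinate tables (ms for time,
degrees for space), mode role tags (≥ 2 unisensory, exactly 1
multisensory), an optional causal readout `causes ∈ [0, 1]`, and a metadata
record (model name, resolved parameters, seed). Axis order is fixed as
`(mode, time, x, y, z)` with absent spatial axes dropped from the right;
one canonical layout keeps every downstream tool free of transposition
logic. `causes` is a scalar for the closed-form observer (one posterior per
trial) and a time series for the three-layer network (the readout evolves
with the dynamics); the trial-level value of a series is its **peak** over
time, because transient multisensory responses under temporal disparity
would be invisible at trial end. Validation is strict and constructive:
nothing invalid is ever stored, shapes are never silently coerced.

On disk, results are NetCDF (classic format via xarray's scipy engine,
which round-trips float64 bit-exactly); tables are CSV with a header row
and an optional JSON provenance comment line.

## Stimuli and the model contract

A `Stimulus` is one modality's physical description: position (deg), onset
and duration (ms), dimensionless intensity ≥ 0, and a noise SD ≥ 0.
Intensity is treated as dimensionless throughout; per-modality physical
units (dB, cd/m²) are out of scope. A `ModelContract` declares the
modality slots, spatial dimensionality, a bounded parameter schema, and a
runner; parameter names are modality-adaptive (template slots such as
`{mod1}_sigma` instantiate to `auditory_sigma` or `tactile_sigma` with the
core logic untouched). Noise semantics differ by level of description:
for the closed-form models a nonzero stimulus `noise` switches the
measurements from the true values to draws from `N(value, σ_modality)`;
for the networks, `noise_frac` perturbs each neuron's input amplitude
multiplicatively, drawn once per trial. All randomness in a run flows
through one generator seeded by the run seed; sweeps pre-assign child
seeds as `sha256(base_seed, value_index, repeat) mod 2³¹`, so sequential
and parallel execution are bit-identical. The noiseless regime used by the
task protocols is stimulus `noise = 0` and `noise_frac = 0`.

## Bimodal integrator

Weights `w_A = σ_V²/(σ_A²+σ_V²)`, fused estimate `w_A ŝ_A + w_V ŝ_V`,
fused variance `σ_A²σ_V²/(σ_A²+σ_V²)`. Defaults `σ_A = 4`, `σ_V = 3` deg
place audition below vision in spatial reliability, the regime in which
spatial ventriloquism is observed. Mode activities are normal densities on
the model grid renormalized to sum to 1 per mode, which makes activity
comparable across models. The integrator defines no causal readout; its
unity value is NaN unless a threshold rule (unity iff the unisensory
discrepancy is below a configured threshold) is explicitly enabled. This
gap is intrinsic: reliability weighting has no representation of cause.

## Bayesian causal inference

Exact Gaussian marginalizations of the two-hypothesis generative model
(formulas in the README). Conditional estimates are precision-weighted
means; the default readout is model averaging
`ŝ_A = π ŝ_{A|C=1} + (1−π) ŝ_{A|C=2}` — selection and probability matching
are provided because the readout strategy is a modeling choice, not a
consequence of the generative model. The unisensory modes carry each
modality's full posterior marginal (a fused/segregated mixture whose mean
is exactly the model-averaged estimate); the multisensory mode carries the
fused posterior.

Spatial defaults: `σ_A = 4`, `σ_V = 3`, `σ_p = 15` deg, `μ_p = 45` deg
(the implicit task's anchor), `p_common = 0.5`. Temporal defaults:
`σ_A = σ_V = 50` ms, `σ_p = 150` ms, `μ_p = 160` ms (the visual onset) —
the same equations applied to onsets. With a single noiseless presentation
per condition, the unity-report proportion is the posterior itself.

## Rate networks

Both networks use rings of `n` neurons (default 180 at 1 deg/neuron,
period 180 deg) with circular distances, a sigmoid
`F(q) = 1/(1+exp(−s(q−θ)))`, and forward Euler at `dt = 0.1` ms with the
stability guard `dt ≤ min(τ)/10`; rates provably stay in `[0, 1)`.
Defaults — lateral Mexican hat `L_ex = 5, σ_ex = 3`, `L_in = 4,
σ_in = 24` deg; sigmoid `s = 0.6, θ = 20`; `τ = 15` ms; inputs
`E⁰_A = 28, σ_A = 15` deg (broad) and `E⁰_V = 27, σ_V = 4` deg (narrow);
cross-modal `W⁰ = 3.5, σ_c = 10` deg — were chosen once to put the model
in its intended operating regime: a winner-take-all bump attractor with a
resting state at effectively zero (`F(0) ≈ 6·10⁻⁶`, which keeps the
arithmetic barycenter uncontaminated by baseline activity), suprathreshold
unisensory drive, and a cross-modal interaction window of roughly the task's
disparity range. The barycenter is arithmetic, not circular: task stimuli
sit mid-grid (45–90 deg), far from the wrap point, and the near-zero
baseline keeps wrap-around tails negligible. Readout is taken at the final
step after ≥ 5τ of settling. The two-layer model has no multisensory
layer; its `multi` mode is the mean of the layer activities, a documented
surrogate kept only to satisfy the result contract — consequently its
unity surrogate (peak of that mean map) reflects bump overlap, and the
decoupling-flattens-unity property belongs to the three-layer model.

The three-layer network adds a multisensory layer (`L⁰ᶜ_ex = 3,
L⁰ᶜ_in = 2.6`, same widths as unisensory; `τ_c = 15` ms) driven by
feedforward Gaussian synapses from both unisensory layers
(`W⁰_mc = 2.2, σ = 3` deg) and feeding back (`W⁰_cm = 4, σ = 3` deg).
In this model the direct cross-modal weights default to `W⁰ = 1.5` —
weaker than in the two-layer model — because part of the interaction is
deliberately routed through the feedback loop; this is what gives the
multisensory lateral excitation and the feedback pathway measurable
influence on the implicit bias. The feedforward gain is set so a single
modality's drive is subthreshold (~13 < θ) while two coincident drives are
suprathreshold (~26 > θ): this coincidence-detector regime produces
superadditivity and carries the temporal principle. Pathway latencies
(cross-modal 5 ms, feedforward/feedback 10 ms) are ring buffers of past
rates at `dt` resolution (non-multiples round to nearest step); temporal
filters are first-order low-passes per population (`τ_filt = 20` ms
auditory/visual, 10 ms multisensory; 0 disables), chosen first-order as the
simplest filter with the required time-constant semantics. The causal
readout divides the maximal multisensory rate by `causes_norm` (default
1.0, the sigmoid ceiling, making the readout the raw maximal rate) and
clips to `[0, 1]`; the normalization is exposed as a parameter. With
feedforward, feedback and filters off and zero cross-modal latency, the
unisensory update reduces operation-for-operation to the two-layer model:
the equality of trajectories at 1e-12 is a standing regression test
between the two independent implementations.

## Task protocols

Spatial tasks anchor the auditory stimulus at 45 deg with visual
disparities ±3, ±6, ±12, ±24 deg; the temporal task anchors the visual
onset at 160 ms with auditory onset disparities 0, ±20, ±80, ±150, +250 ms
(8 conditions, the protocol's printed set). Each condition is presented
once, noiseless. Spatial stimuli last the whole 500 ms trial; temporal
stimuli are 50 ms flashes/beeps co-located at 90 deg (mid-grid) — the
protocol specifies onsets only, so duration and position are package
choices in line with the brief-stimulus conventions of such experiments.
Auditory bias is `(ŝ_A − s_A)/(s_V − s_A)` with the sign convention
`Δ = s_V − s_A`, so positive bias always means attraction toward vision;
bias is undefined at zero disparity.

Unity curves are summarized by least-squares Gaussian fits
`P(Δ) = A exp(−(Δ−μ)²/2w²)` with bounds `A ∈ [0,1]`, `μ` within the
disparity span, `w ∈ (0, 2·span]`, started from 5 deterministic
initializations; a constant curve is returned flagged degenerate (width
unidentifiable) rather than fitted. Parameter sweeps report the bias at
the −6 deg point for implicit tasks and the Gaussian (amplitude, mean,
width) for explicit tasks; swept parameters vary one at a time with all
others held at their defaults. Model-to-data fitting minimizes the sum of
squared errors with SciPy's differential evolution (seeded, population 15,
iteration cap derived from the evaluation budget, no polish step so the
budget is respected).

## What the synthetic protocols do and do not show

All inputs are synthetic and noiseless by default: the tests and the
acceptance script characterize the models' deterministic predictions —
closed forms against brute-force numerical integration, analytic limits,
monotonicity and reduction properties, and self-recovery of generative
parameters from the models' own curves. Passing them shows the machinery
is correct and internally consistent; it does not show that any model fits
human data, which requires observed response tables (supported via the
CSV fitting interface but outside the test suite). Trial-to-trial
variability, lapses, response biases and motor noise present in real data
are not emulated.

## Numerical choices and degenerate inputs

- Brute-force oracles integrate on finite windows (±12 max σ around all
  Gaussian centers) with breakpoints at the centers and pure relative
  tolerance 1e-11; an unbounded quadrature misses narrow mass.
- `posterior_common` raises on double likelihood underflow rather than
  returning 0/0.
- All-zero activity has no barycenter and raises; a uniform ring is read
  out as the grid midpoint by the same formula (degenerate but defined).
- Mexican-hat parameterizations with dominant inhibition warn (no bump can
  form) but are not rejected.
- Network unit tests run 90-neuron rings for speed; properties that depend
  on absolute synaptic drive (the coincidence-detector threshold of the
  multisensory layer) are tested at the full 180-neuron scale, where the
  acceptance checks also run (dt 0.1 ms, 500 ms trials).

## Known limitations

- Networks are 1-D in space (the result container supports 3-D).
- The two-layer model's unity surrogate conflates bump overlap with
  integration; use the three-layer model for explicit tasks.
- The temporal application of the Bayesian observer reuses the spatial
  machinery with ms units; there is no asymmetry between auditory-leading
  and visual-leading asynchronies, which real observers show.
- Model comparison metrics (information criteria) are not included.
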