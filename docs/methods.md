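# Methods

## Model

All dynamics are discrete-time with a unit step; frequencies are in
cycles/step on [0, 0.5]. A leaky integrator with membrane time constant
`τ_m` discounts its past by `e^{−1/τ_m}` per step; `τ_m = 0` is treated as
the memoryless limit `v_t = g_s · input_t`.

The input ensemble is an exponentially correlated signal `s_t` — a
stationary AR(1) process, `s_t = β s_{t−1} + √(1−β²) ξ_t`,
`β = e^{−1/τ_s}`, with `s_0` drawn from the stationary distribution so the
process is stationary from the first sample — mixed with white noise
`ε_t` at power SNR `σ`:

    f_t = √(σ/(1+σ)) s_t + √(1/(1+σ)) ε_t .

The square-root weights make the *power* ratio of the two components
exactly `σ` and the total input power 1; any other convention breaks the
power-SNR semantics. Innovations are Gaussian. The theory constrains only
second-order statistics, so the Gaussian choice is one of convenience.

### Optimal linear filter

Restricting the prediction-error filter to the geometric family realized
by the feedback circuit, `H(z) = (1−βz⁻¹)/(1−ηz⁻¹)` with `η = β(1−Λ)`,
the expected network gain against the ensemble spectrum is

    G(η) = [σ(1−β²) + (β−η)²] / [(1+σ)(1−η²)] + 1/(1+σ) ,

whose minimizer solves `βη² − [1+β²+σ(1−β²)]η + β = 0`. The root inside
the unit circle is evaluated in the cancellation-free form
`η = 2β/(b + √(b²−4β²))`, `b = 1+β²+σ(1−β²)`, stable to `σ = 10¹⁰` and
beyond. `Λ* = 1−η/β` satisfies `Λ*(β,0) = 0`, `Λ*(β,∞) = 1`, and is
monotone in `σ`. The same optimum is recovered, to well under 1%, by two
independent numerical routes used in the tests: normal-equations (Wiener)
solves on the analytic and on simulated autocovariances, and generic
quasi-Newton minimization of the spectral gain integral over an
unconstrained 12-tap weight vector — evidence that the geometric family
restriction is not binding at these ensemble parameters.

Weight sequences are truncated when the dropped geometric tail's l1 mass
falls below 1e−12 (recorded in `OptimalSolution`).

### Circuits

Both linear circuits carry a one-step synaptic delay into the interneuron
only; the principal cell updates without delay (adding one there would
just shift the whole output). Circuits start quiescent (`n_0 = 0`); the
onset transient is part of every simulated series, and stationary
quantities in tests discard a burn-in of order `10·max(τ_s, τ_m)` samples.
The principal pathway has unit gain so the leading `f_t` coefficient of
the prediction-error filter is exactly 1; `g_s` appears only in the
standalone leaky-integrator utility.

Decoding inverts the encoder exactly: for the feedback form the prediction
depends only on past transmitted values, so the decoder is unconditionally
stable; for the feedforward form the decoder pole is `α̂(1+Γ̂)`, which the
optimal mapping pins to `β < 1` but which exceeds 1 for some arbitrary
parameter pairs — there the code is still lossless in exact arithmetic but
round-off grows exponentially.

### Nonlinear circuit

The dead zone `R_δ` (zero on [−δ, δ], unit slope outside) applies to the
interneuron's output as seen by the principal cell: `p_t = f_t − R_δ(n_t)`
with the interneuron integrating its raw state,
`n_t = α(n_{t−1} + Γ p_{t−1})`. The biological ON/OFF half-wave pair
described for implementing the symmetric rectifier is mathematically the
single odd function used here. An alternative in which the rectified
output also re-enters the interneuron's self-integration was implemented
and rejected: it degrades the signal-segment prediction and performs worse
on every mixture tested.

The extended circuit for comparison with measured temporal filters chains
an upstream low-pass (`τ_u`), the principal cell (`τ_p`), and the
interneuron (`τ_i > τ_p`), each stage normalized to unit DC gain so
amplitude sweeps are comparable across time constants (synaptic
conductances are otherwise unconstrained). Defaults are `τ_u = 5`,
`τ_p = 3`, `τ_i = 12`, `Γ = 0.9`, `δ = 0.5` (in units of the reference
input standard deviation 1). These are illustrative: no canonical values
exist, but the rising-to-a-peak kernel shape requires
`e^{−1/τ_u} + e^{−1/τ_p} > 1` in discrete time, which rules out
single-step stages.

## Describing-function analysis

For sinusoidal drive at amplitude A the rectifier is replaced by its
first-harmonic equivalent gain `k = N(A_n, δ)` (computed by quadrature
with the integrand split at the threshold crossings; closed-form checked
in tests), and the loop gain is solved self-consistently:
`k = N(|H_n(ω; k)|·A, δ)`, by damped fixed-point iteration (damping 0.5,
relative tolerance 1e−8, 10³ iterations) with a bracketing root-finder
fallback — the residual is continuous and changes sign on k ∈ [0, 1], so
a fixed point always exists; frequencies where neither route converges are
flagged per-frequency. The reported network gain is `|H_p(ω; k)|²`.

Two structural facts the analysis exposes:

* the curve always lies inside the *envelope* of the linear feedback
  family over loop gains [0, 1] (it coincides pointwise with the member at
  `Γ_eff = kΓ`), approaching the full-feedback member at low frequencies
  under strong drive and the open-loop member near Nyquist when the
  interneuron response is subthreshold;
* it is *not* bounded by the two endpoint curves alone: at mid frequencies
  (`cos ω ∈ (0, α)`) intermediate effective gains resonate above both
  endpoints, by up to ≈0.14 in gain for `α = e^{−1/4}`. Time-domain
  simulation shows the same excess, so this is a property of the system,
  not of the approximation.

Time-domain cross-checks project input and output onto the drive frequency
over an integer number of periods after burn-in (the analog of the
describing function's first-harmonic restriction); agreement is within
10% wherever the fixed point converges, the expected accuracy of harmonic
balance.

## Mixture comparison protocol

Non-stationary inputs are 1:1 two-segment mixtures: 1000 samples of pure
correlated signal (amplitude 1, `τ_s = 10`) followed by 1000 samples of a
pure unpredictable component (Nyquist alternation or Gaussian white noise)
whose amplitude is swept over [0.5, 2]. `τ_s = 10` — a correlation time
one decade above the simulation step — is the package's fixed study
condition. Per condition, 20 seeded trials (40 in the acceptance script)
are drawn; per-trial network gains include the onset transient, matching
the power-sum definition of the gain from t = 0. Sensitivity check:
discarding a 100-sample burn-in from the power sums shifts the type-1 and
nonlinear mean gains by about 0.4 trial standard deviations each and the
percentage improvement by less than 0.2 points.

Three networks are optimized on each mixture, all with `α` fixed to the
signal's `β`:

* type-1 linear: one `Γ` over the whole mixture;
* type-2 linear: `Γ` per segment (each segment's gain minimized
  separately, then pooled) — the best any linear coder can do given time
  to adapt;
* nonlinear: `(Γ, δ)` jointly over the whole mixture.

Grids are `Γ ∈ [0,1]` step 0.02 and `δ ∈ [0, 3·rms]` step `0.05·rms`,
followed by one refinement pass at a fifth of each step around the coarse
optimum; resolutions sit well below the reported effect sizes. All
candidates and all three networks share the same trials (common random
numbers), so the linear search space is literally the `δ = 0` slice of the
nonlinear one and the orderings `gain_nl ≤ gain_type1` and
`gain_type2 ≤ gain_type1` hold by construction on shared seeds.

Percentage improvement is `100·(G_type1 − G_nl)/G_type1`; error bars are
one standard deviation across trials.

**Results at these conditions.** Nyquist mixtures: peak improvement ≈30%
(stable at 30.1–30.3 for 40 trials across seeds), with the nonlinear gain
within one standard deviation of the type-2 benchmark and more than one
standard deviation below type-1 at every swept amplitude. White-noise
mixtures: peak improvement ≈5–6%. The separation mechanism differs
between the two: the interneuron cancels Nyquist input by frequency
(closed- or open-loop response amplitude `αΓa/(1+α) ≈ 0.24a`, far below
the signal-segment state std ≈ β), but white noise drives the open-loop
interneuron in a random walk to std `αΓa/√(1−α²) ≈ 1.06a` — comparable to
the signal-segment state — because closed-loop predictive coding whitens
the transmitted error in both regimes. A fixed amplitude threshold
therefore cannot separate signal from white noise here, and the ≈20%
white-noise improvement sometimes quoted for this protocol is not
attained by this implementation at any `τ_s` in [2, 30] (the exhaustive
2-D grid search bounds what the circuit can do). The corresponding
acceptance test is left failing rather than weakened.

## Reverse-correlation (STA) filter estimation

Linearized filters are estimated from 2000 trials of 1000-sample Gaussian
white noise per amplitude (amplitude = sampling std; the same seed, hence
the same normalized noise, at every amplitude). The readout is the final
sample of each trial — a single readout per trial keeps samples
independent and the circuit state stationary — and
`kernel[l] = mean(p_{t*} · f_{t*−l}) / amplitude²`, so a linear circuit's
kernel equals its impulse response, amplitude-invariantly (verified at
r > 0.99 against the analytic impulse response at 4000 trials).

Metrics: positive/negative mass ratio (∞ sentinel for single-signed
kernels), best mean frequency (peak of the zero-padded FFT magnitude,
DC excluded), extremum lag (argmax |kernel|, ties to the smaller lag).
Across a 0.5–8 amplitude sweep of the extended circuit the ratio falls
monotonically (≈11 → ≈5) and the BMF rises — the fast-adaptation
signature. The extremum lag never increases but typically stays constant:
the discrete-time peak shift between the open-loop and full-feedback
kernels is a single step and the kernel top is flat, so the argmax is
noise-limited at realistic trial counts.

## Numerical choices and degenerate inputs

* Seeding: every public generator takes an integer seed; mixtures derive
  per-segment streams by hashing (seed, segment index), with segment 0
  inheriting the master seed so a single-segment mixture reproduces the
  bare generator call bit for bit. The evaluation protocol hashes
  (seed, trial) the same way. All outputs are bitwise reproducible.
* `σ = 0` and `σ = ∞` are handled exactly (pure-noise / pure-signal
  limits), as is `τ_m = 0`.
* Gain integrals use a 4096-point trapezoid rule on [0, 0.5]; the
  closed-form gain agrees to 1e−6 relative.
* Zero kernels, zero input power, empty mixtures, non-positive time
  constants, and divergent feedback parameterizations raise `ValueError`
  rather than propagating NaNs.

## What the synthetic conditions do and do not show

The stimuli are exactly the idealized ensembles of the theory: a single
exponential correlation time, stationary Gaussian innovations, instant
switches between pure components. Real sensory streams have multiple
correlation times, heavy-tailed statistics, and graded transitions; the
gain comparisons here quantify the circuit mechanism under its design
assumptions, not performance on natural stimuli. Mutual inhibition across
parallel circuits tuned to different time constants, spiking dynamics, and
spatial predictive coding are out of scope.
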