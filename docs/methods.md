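# Methods

## Model

Channel gating is a continuous-time Markov chain on labelled states, with
per-transition rates `a·exp(z·φ)`, `φ = V·F/(R·T)` dimensionless for V in
volts. The packaged IKs scheme has six states (C1, C2, C3, O1, O2, C2s with
O1/O2 conducting) and the rate laws listed in the README; only `γ` and `ρ`
are voltage-independent. Occupancy evolves by the master equation
`dp/dt = p·Q`, with `Q[i,j]` the i→j rate and diagonal entries the negative
row sums, so every row of Q sums to zero and probability is conserved.

Assumptions inherited from this model class: macroscopic (law-of-mass-action)
kinetics with no channel-count fluctuations; memoryless transitions;
instantaneous voltage steps (piecewise-constant protocols, no ramps); ohmic
instantaneous conduction `I = G·P_open·(V − E_rev)` with outward current
positive. Single-channel stochastic simulation, Q₁₀ temperature scaling and
multi-subunit combinatorial expansions are out of scope.

### Drug action

The gating modifier is modelled two ways:

* **Configuration switch** (`DrugConfig`): the fully bound channel is the
  same scheme with the C2s→C2 exit `ρ` replaced, 10 → 0.1 s⁻¹. The simulated
  "drug" condition in the activation-family pipeline is this fully bound
  configuration; fractional occupancy is deliberately not mixed in, because
  the two parameter sets define exactly two configurations.
* **Explicit binding expansion** (`BindingSpec` + `augment_with_binding`):
  2N states (unbound copy + bound copy carrying the bound configuration),
  association `k_on·C` from each binding-competent state to its bound twin,
  dissociation `k_off` back, no other cross-copy edges. The competent set for
  the IKs preset is the four closed states (C1, C2, C3, C2s), reflecting
  closed-state access of the compound.

Binding defaults: the paper-style dissociation constant is taken as the
wild-type half-inhibition concentration, Kd = 78.4 nM, with
k_on = 1e4 M⁻¹s⁻¹ (a typical small-molecule association rate that puts
wash-in time constants at ~90 s for 1 µM, the minutes scale seen in such
experiments) and k_off = k_on·Kd ≈ 7.8e-4 s⁻¹. Both are plain parameters;
nothing downstream depends on these exact values beyond the wash-in time
scale.

### Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| T | K | 293.15 | room-temperature oocyte recording; φ at 19–23 °C differs by <2% |
| E_rev | mV | −90 | typical K⁺ reversal at ~4 mM external K⁺ |
| G_max | µS | 1 | normalized outputs are independent of it |
| dt (sampling) | s | 1e-3 | resolves the fastest IKs relaxations (~30 s⁻¹) by >30× |
| k_on, Kd | M⁻¹s⁻¹, M | 1e4, 78.4e-9 | see above |

## Numerical choices

* **Propagation** is by matrix exponential per constant-voltage segment:
  eigendecomposition of Qᵀ, occupancies evaluated vectorized on the output
  grid. This is exact (to round-off) for piecewise-constant protocols, unlike
  time-stepping integrators. The decomposition is accepted only if it
  reconstructs Qᵀ to a relative residual <1e-9 with eigenvector condition
  number <1e10; otherwise the propagator falls back to per-step
  `expm(Q·dt)` stepping, which remains exact at the grid times even for a
  defective spectrum. (A stiff ODE integrator would reintroduce controlled
  but nonzero discretization error, so it is not used.)
* **Probability guards**: entries in (−1e-12, 0) — eigen round-off — are
  clipped to zero and rows renormalized; larger violations raise instead of
  being hidden. Output rows must sum to 1 within 1e-7 before renormalization.
* **Steady states** come from the SVD null space of Qᵀ; a null-space
  dimension other than 1 (disconnected chain, no unique stationary law)
  raises rather than returning an arbitrary vector. The stationary residual
  ‖p·Q‖∞ is at machine precision (~1e-15) for the packaged scheme.
* **Initial conditions**: each sweep starts from the steady state at the
  protocol's holding potential, matching experimental practice, except in
  repetitive/conditioning/rest protocols where occupancy deliberately carries
  over between sweeps (that carry-over is the phenomenon of interest), and in
  wash-in simulations, which start from the *drug-free* equilibrium embedded
  in the unbound copy (drug applied at t = 0).
* **Segment durations** must sit on the sampling grid (checked to 1e-9
  relative); all packaged protocols do.

An independent explicit-Euler integration (step 1e-5 s) of the drug-free
scheme over a 5 s step to +40 mV differs from the matrix-exponential solution
by 2.1e-6 at most (1.0e-7 for the bound configuration). That difference is
the Euler scheme's own first-order discretization error — it shrinks tenfold
when the Euler step does — and is the expected agreement level for such a
cross-check, not a defect of the propagator.

## Protocol engine

Protocols are tuples of sweeps of (duration, voltage) segments with a
sampling interval, holding potential, carry-over flag, and indices naming the
test and tail segments. The six presets cover: repetitive 7 s +40 mV pulses
every 30 s; the 10 s activation current–voltage family (−100…+60 mV, tails
−120 mV); deactivation tail families (−140…−40 mV after a −20 mV prepulse);
a 4.5 min closed-state rest; subthreshold conditioning trains (300 ms to
−40 mV at 0.2 or 2 Hz); and the six-sweep 5 s activation family
(−40…+60 mV, tail −120 mV) used for the model pipeline. Preset overrides are
explicit keyword arguments — an unknown keyword raises — so nothing changes
silently. Sweeps of the activation families re-equilibrate at the holding
potential between sweeps (the experimental 30 s inter-pulse interval); this
is configurable via the carry-over flag.

## Fitting

All nonlinear fits use least squares (lmfit) with analytic starting values
and up to three jittered restarts before a result is flagged non-converged
(flagged, not raised — a flat trace returns `converged=False`).

* **Hill**: IC₅₀ fitted in log₁₀ space; default search window 10 pM–1 mM,
  widened automatically when the data's concentration scale lies outside it
  (this keeps the fit invariant under unit changes). H free in [0.2, 5] by
  default, optionally fixed — the printed equation includes H but reports no
  fitted values, so both modes are exposed.
* **Boltzmann**: V½ initialized by interpolating the half-amplitude
  crossing; k > 0 enforced.
* **Exponential**: τ initialized from the 1/e crossing; time is shifted to
  the window start. Activation fits exclude the first 200 ms of the test
  pulse — IKs activates sigmoidally, so a single exponential is a late-time
  description; deactivation fits exclude the first 10 ms of the tail.
* **Tail amplitudes** are read at the first sample ≥5 ms after the tail step
  ("settle" method, letting the instantaneous ohmic jump pass), configurable
  to peak-within-50 ms; amplitudes are normalized to the largest magnitude
  across sweeps (tail normalization, not conductance division), so the
  activation-curve maximum is exactly 1.
* **End-pulse inhibition** is `100·(1 − I_drug/I_control)` over the last
  50 ms of the designated pulse; it is invariant under common rescaling and
  undefined (raises) when the control current is ~0.
* **Wash-in slope**: ordinary least squares of log₁₀(τ) on log₁₀(C).

## Synthetic data

Generators are pure functions of (parameters, seed). `synth_recording` adds
to the noiseless model current: ohmic leak `g_leak·(V − E_leak)`, additive
Gaussian current noise (σ in µA), and an optional slow contaminant — a
first-order current (τ = 2 s, default off) switched on above +40 mV,
emulating endogenous oocyte currents elicited by long pulses at high
potentials, solely to test analysis robustness. Replicate scatter in
concentration–response tables is multiplicative (σ_rel = 0.03 by default,
clipped to [0, 1.1]) — an approximation to the visible scatter of published
dose–response data, not an estimate of it; no noise magnitudes are reported
for the recordings these emulate, so all noise parameters are synthetic-
fixture choices.

Wash-in simulations pulse the binding-augmented scheme repetitively (7 s to
+40 mV every 30 s) from drug application onset and record end-pulse
amplitudes normalized to the first pulse. Recording length adapts to the
expected pseudo-first-order time constant 1/(k_on·C + k_off) — about five
time constants, clamped between 300 and 1800 s — as an experimenter records
until inhibition approaches steady state; this also guarantees the
exponential fit its minimum of ten points. Wash-in uses a 10 ms sampling
interval; the kinetics of interest are tens of seconds.

What passing tests show, and what they do not: parameter-recovery tests
demonstrate that the analysis chain is self-consistent under the generators'
noise model (Gaussian, independent, multiplicative for replicates). Real
oocyte recordings add capacitance transients, series-resistance error,
correlated drift and batch variability, none of which are modelled; recovery
tolerances measured here do not transfer to such data.

## Design choices where the ground was open

* **Edge-to-rate mapping**: the published listing order is followed —
  α/β pairs along C1⇌C2⇌C3⇌O1, ε/δ on O1⇌O2, γ/ρ on C2⇌C2s — with ε taken
  as the forward (O1→O2) rate, consistent with its positive effective charge
  (depolarization-favoured). The mapping lives in the packaged scheme JSON,
  not in code, so the alternative wiring (ε/δ on C3⇌O1) is a data edit.
* **The "drug" condition** of the simulated pipeline is the fully bound
  configuration; graded occupancy is available only through the explicit
  binding expansion.
* **Activation-slowing property range**: the `reproduce-fig9` property suite
  asserts τ_activation(bound) > τ_activation(control) at test voltages
  ≥ +20 mV. At −20 and 0 mV the bound configuration's open probability is
  vanishingly small (≲0.7% of control) and equilibrates *faster* than
  control — a genuine property of this parameter set, computed by the
  pipeline itself; experimentally, activation kinetics in drug are only
  measurable at the higher voltages, which is the regime the slowing claim
  describes.

## Problem sizes

The shipped analysis and test suite use: 1 ms sampling for the activation
family (6 sweeps × 7.5 s ≈ 45k samples per configuration), a 500k-step
Euler cross-check, 108 round-trip fits over the four families' parameter
grids, 200 seeded noisy dose–response datasets (9 concentrations × 5
replicates), and wash-in simulations at five concentrations (0.1–10 µM,
10 ms sampling, 300–1800 s each). These sizes resolve every quantity the
package reports while keeping a full run in the low minutes on one core.

## Known limitations

* Rate constants are asserted, not fitted; there is no machinery for fitting
  Markov-scheme rates to recordings.
* The binding expansion assumes a single binding site, state-independent
  k_on/k_off within the competent set, and no conduction change upon binding
  beyond the gating switch.
* Leak subtraction, capacitance artefacts and ramp/sine protocols are not
  modelled.
* Boltzmann fits of strongly right-shifted activation curves (bound
  configuration) extrapolate beyond the sampled voltage range; the fitted
  V½ is then protocol-dependent, as it is for the experimental analysis this
  mirrors.
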