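# Methods

## The gating model

I_K,L is modelled as a homogeneous population of channels, each a
continuous-time Markov chain on ten states: a voltage-dependent activation
chain of five closed states C0…C4 (four identical voltage sensors, hence
statistical factors 4α,3α,2α,α forward and β,2β,3β,4β backward), a parallel
chain of five open states O0…O4, voltage-independent vertical transitions
between matching rungs, and a final voltage-independent opening step
C4 ⇄ O4 with rates a (forward) and b (backward) that is kinetically
unrelated to the rest of the scheme. Horizontal rates are single
exponentials of voltage,

    α(V) = α₀ exp(V / k_α),      β(V) = β₀ exp(−V / k_β),

so each e-fold change takes k mV. All ten states conduct nothing except
O0…O4; the macroscopic current is I = g·P_open·(V − V_rev) in arbitrary
units with V_rev = −76 mV.

Default kinetic constants (ms⁻¹ unless noted): α₀ = 0.99, β₀ = 1.57·10⁻⁶,
k_α = k_β = 12.67 mV, C_on = 4.5·10⁻⁴, C_off = 0.8, a = 4.25, b = 0.38.

### Placement of a and b — the two scheme variants

The roles of the constants a and b admit two readings, both implemented:

* **final-rung** — a and b act only as the C4 ⇄ O4 rates; the verticals
  C_i ⇄ O_i are the bare C_on/C_off. Early open states then carry an
  equilibrium occupancy of only C_on/C_off ≈ 6·10⁻⁴ of their closed
  partners and are effectively invisible.
* **allosteric** (default) — a and b additionally act as allosteric
  factors: vertical rates are C_on·aⁱ (up) and C_off·bⁱ (down) on rungs
  i = 0…3, and the open-chain horizontal rates are the closed-chain ones
  scaled ×a forward and ×b backward, with an O3 ⇄ O4 edge. Opening from
  intermediate closed states is then substantial at weak depolarization,
  producing the slow onset component, visibly occupied early open states,
  and transient early-open occupancy during deactivation; the fast initial
  deactivation phase comes from O4 → C4 at rate b.

`run_calibrate` scores both variants (× the statistical-factor flag)
against a reference table of onset-fit parameters of the simulated current
at −94…−54 mV and selects the allosteric variant with multiplicity on; that
combination is the shipped default. Within the allosteric ladder (rungs
0…3) every four-state cycle satisfies microscopic reversibility by
construction (the ×a/×b open-chain scaling exactly balances the aⁱ/bⁱ
verticals); the two cycles touching the final rung are not
balance-constrained, because that step is deliberately outside the
allosteric ladder. Physically this means the final concerted opening step
is treated as an independent conformational change rather than another
sensor movement.

At −64 mV the model's steady state puts ≈90% of channels in O4 with the
remainder mostly in C4 (the O4:C4 ratio is a:b ≈ 11.2), and its
steady-state activation curve is steep (Boltzmann slope ≈ 3.7 mV).

## Numerics

* **Integration.** Occupancies follow dp/dt = pQ(V) by forward Euler with
  dt = 0.1 ms and per-step renormalization (optional; drift without it is
  < 10⁻¹³ per second here). The Euler end-state agrees with the matrix
  exponential to < 10⁻⁶ per state over 1-s simulations, and halving dt
  halves the error. If dt·(max exit rate) exceeds 0.5 — which happens only
  for commands above ≈ 0 mV, outside the study's protocol range — the step
  is split into equal Euler sub-steps composed into a single per-sample
  matrix, preserving the output grid.
* **Steady states** are computed from the null space of Qᵀ (SVD), not by
  long integration; propagation from a steady state stays within 10⁻⁸.
* **Protocols** are piecewise-constant with half-open segments: the first
  sample of a step is already at the new voltage, and "instantaneous" tail
  amplitudes are read at that sample (for noisy traces, the median of the
  first millisecond is available instead). Segment durations must be
  integer multiples of dt; anything else is an error rather than a silent
  truncation.
* **Initial condition** is the steady state at the first (holding) segment
  level unless an explicit distribution is given, matching protocols that
  hold until the current is fully (de)activated.

## Fitting

The onset of activation is fitted with

    I(t) = A[(1−Ā₂)(1−e^(−t/τ_f))ⁿ + Ā₂(1−e^(−t/τ_s))(1−e^(−t/τ_f))ⁿ] + C,

by unweighted least squares (trust-region reflective). Ā₂ ∈ [0,1] is the
relative amplitude of the slow component (Ā₁ = 1−Ā₂ by construction);
τ_f < τ_s is enforced by parameterizing τ_s = τ_f + δ, δ > 0; n ∈ [0.5, 6].
Initialization: τ_f from the 10–90% rise time, τ_s = 10·τ_f, n = 2,
Ā₂ = 0.6, A and C from the trace ends. Any parameter can be fixed (it then
gets no SD); SDs come from the linearized covariance at the optimum.
Windows longer than 4000 samples are uniformly decimated before optimizing
— a pure cost measure that leaves the unweighted estimate on a uniform grid
unchanged for noiseless traces.

**Identifiability.** On simulated I_K,L traces the four shape parameters
are strongly correlated: the residual surface is nearly flat over wide
ranges of Ā₂ (with τ_f, n, τ_s compensating), particularly when τ_s is
within a factor of ~2 of τ_f. Fits of the activation family therefore use
two deterministic starts per voltage — the standard guess and a
continuation from the previous (more depolarized) potential — keeping the
lower-rss solution. Parameter-recovery guarantees hold where the problem is
well-posed: with separated time constants (τ_s/τ_f ≈ 10) and 2% noise, all
free parameters are recovered with median error well below 10%; with
τ_s/τ_f ≈ 1.5 the slow/fast decomposition is not identifiable from noisy
data and only A, τ_f and n are stable. Consequently the exponential power n
(and the O4 occupancy, which needs no fitting) are the robust readouts of
the simulated kinetics, while Ā₂ and τ_f at weakly depolarized potentials
depend on the optimizer path for any fitting procedure.

Steady-state activation uses the Boltzmann function
I(V) = I_max + (I_min − I_max)/(1 + e^((V−V_half)/S)) on instantaneous
tail amplitudes (normalized min/max over the family); with 8-s conditioning
the normalized tail curve matches the steady-state open probability to
< 10⁻³. Deactivation uses a sum of one or two decaying exponentials plus
offset, multi-started over several τ splits (a single start lands in a
degenerate cancelling-pair solution on model traces); fitted slow time
constants agree with the slowest relaxation eigenvalue of the generator to
within ~20%. Series-resistance correction subtracts I·R_s from the command
voltage and flags drops above 6 mV, the conventional discard threshold.

## Synthetic fixtures

The fixture generators emulate whole-cell voltage-clamp recordings from
type I hair cells; all are deterministic given their settings and seed.

* **Noise**: additive i.i.d. Gaussian, default σ = 0.05 a.u. White noise
  only — no 1/f, line pickup, or filtering artifacts of real rigs.
* **Series resistance**: the membrane voltage solves the ohmic balance
  V_m = V_cmd − I·R_s·s per sample (closed form, since I is linear in V_m),
  and gating is integrated at V_m; defaults R_s = 3 MΩ, s = 0.05 nA/a.u.
  The maximum voltage drop is reported against the 6-mV discard rule.
* **Residual-calyx cleft**: a single well-mixed compartment whose K⁺
  concentration obeys d[K]/dt = I·s/(F·vol) − ([K] − K_bath)/τ_clear, with
  the reversal potential shifted by the Nernstian displacement of [K] from
  the bath (5.8 mM out / 131 mM in, 24 °C, ≈ −80 mV). Defaults
  (vol = 11 fL, τ_clear = 5 ms, s = 0.1 nA/a.u.) are illustrative, chosen
  once so that a 1-s step to +16 mV shifts V_rev by ≈ +40 mV; they
  reproduce, qualitatively, the outward-current relaxation during
  depolarizing steps, the inward-then-outward instantaneous tail after
  strong conditioning, and the non-monotonic tail-vs-conditioning curve.
  This is deliberately a minimal phenomenological stand-in — real cleft
  geometry, septate-junction diffusion barriers and calyx conductances are
  out of scope — so tests passing on these fixtures show the analysis code
  behaves correctly under calyx-like distortion, not that the cleft model
  is quantitatively right.

## Problem sizes and determinism

The activation-family simulations use test steps of 10/6/3/2/1 s at
−94/−84/−74/−64/−54 mV — at least five expected slow time constants each,
so the slow component is resolved — at dt = 0.1 ms. Recovery properties use
25 seeded replicates (onset) and 200 (Boltzmann). Everything outside the
seeded noise generators is deterministic; repeated runs are bit-identical.

## Known limitations

* The printed kinetic constants under any ladder topology we examined give
  activation roughly half as fast as the reference onset-fit table for the
  simulated current; the exponential power n, τ_s at most potentials, the
  90% O4 occupancy, steepness of activation, Cole–Moore shift and
  multi-exponential deactivation are reproduced, but τ_f runs ~1.5–2×
  high and Ā₂ is only reproduced where it is identifiable (−64/−54 mV).
* Single-channel (stochastic) gating, temperature dependence, leak and
  capacitative currents, the I_K,v and I_h conductances, and fitting the
  rate constants themselves to data are out of scope.
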