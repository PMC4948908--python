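# Methods

## The models

`vnboost` implements a family of models of medial vestibular nucleus (MVN)
neurons whose firing is shaped by a high-voltage-activated calcium current
and a calcium-activated potassium (KCa) current.

**Conductance-based model.** The full model has four state variables
(V, n, x, C) in units of mV / ms / mS·cm⁻² / µA·cm⁻²:

    Cm dV/dt = mu − I_Na − I_K − I_leak − I_Ca − I_KCa
    dn/dt = [n∞(V) − n]/τn        (spike generator recovery)
    dx/dt = [x∞(V) − x]/τx        (Ca-channel activation, τx = 10 ms)
    dC/dt = [C∞(V,x) − C]/τC      (calcium concentration, τC = 20 ms)

with I_Na = gNa m∞³(V)(1−n)(V−VNa), I_K = gK n⁴(V−VK), I_leak = gL(V−VL),
I_Ca = gCa x²(V−VCa), I_KCa = gKCa·C/(C+Kd)·(V−VK), sigmoidal steady states
z∞(V) = 1/[1+exp(−2a_z(V−V½,z))], and calcium equilibrium C∞ = −KR·I_Ca
(no saturation term).  Because VK < V < VCa over the operating range, the
calcium current is always depolarizing and the KCa current always
hyperpolarizing; together they form the adaptation current W = I_Ca + I_KCa.

**QIF reduction.** Replacing the spike generator (n, I_Na, I_K, I_leak)
with the quadratic drive ψ(V) = g2 (V−V2)² plus a threshold Vth / reset
Vreset boundary condition gives a three-variable adaptive quadratic
integrate-and-fire model that preserves the subthreshold fixed-point
structure.  During the refractory period τr the voltage follows a
piecewise-linear artificial action potential (Vth → Vmax in t1 ms, then
down to Vreset by τr); its high voltages are what activate x.  Three reset
rules for (x, C) at a spike are supported: integrating the gating
equations through the waveform (state-dependent), adding fixed increments
(Δx, ΔC), or resetting to fixed values (x_reset, C_reset).  Fixed values
make every interspike trajectory identical, so bursting is impossible;
the other two rules permit it.

## Parameter provenance and calibration

The published account of this model prints only a subset of its constants
(τn ≈ 1.5, τx = 10, τC = 20 ms; g2 = 0.1, V2 = −50 mV; Vmax = 30 mV,
t1 = 0.4 ms, τr = 3 ms; ε = 0.5; x_reset = 0.1; the gCa values of the
sweeps) and defers the rest to earlier conductance-based MVN models that
are not distributed with it.  The packaged default set therefore keeps
every printed value verbatim and fixes the remaining constants by a
one-time calibration against the reported behavior, in this order of
priority:

1. saddle-node spiking onset near mu = 0 for gCa = 0, with no subthreshold
   fixed points left at mu = 5;
2. two subthreshold fixed points at mu = 5 for gCa = 0.6, Hopf
   destabilization of the resting point, and annihilation of the unstable
   pair at higher bias;
3. a second-order expansion of the reduced flow about its minimum landing
   near the adopted (g2, V2) = (0.1, −50);
4. the period-adding burst ladder (1-spk → 2-spk → 3-spk → … → 1-spk) for
   gCa = 0.6 positioned so the 2-spike window covers mu = 19, with tonic
   firing at mu = 18 and 22.5;
5. the bidirectional afterhyperpolarization (AHP) present in the low-gain
   region and absent in the high-gain region;
6. a fixed-reset QIF whose simulated gain peaks at the analytic tangency
   bias mu* for gCa ∈ {0.05, 0.1, 0.15, 0.2}, with a genuine low-gain
   branch below it;
7. spike-waveform QIF bursting at gCa = 0.2.

Every field of `vnboost.params.PROVENANCE` is tagged `printed` or
`reference (calibrated)` so the sensitivity of any result to the
calibrated values is auditable.  Requirements (2) and (6) pull in opposite
directions — (2) wants strong steady-state KCa activation below threshold,
(6) wants the reset-pinned adaptation line to dominate the steady-state
one — and are reconciled by a calcium activation curve with a small
subthreshold tail (x∞(−50) ≈ 0.06) and a KCa half-activation Kd of order
the spike-driven calcium level.  Two known compromises remain with the
packaged set:

* the 3-spike window sits at mu ≈ 20.25–20.4 rather than the reported 22
  (the ladder's order and its 1-spk boundaries at 18 and 22.5 are
  reproduced);
* the annihilation of the unstable subthreshold pair (mu ≈ 10.3) lies
  below the burst ladder (mu ≈ 19–21.8) rather than inside it: with a
  high-threshold calcium gate, the calcium driven in by full action
  potentials substantially exceeds its subthreshold steady state, which
  offsets the spiking structures upward in bias relative to the
  fixed-point structures.

## Numerics

Production integration is fixed-step RK4 (default dt = 0.01 ms) in
compiled kernels, chosen so that traces, interspike intervals and burst
classifications are bit-reproducible; `scipy.integrate.solve_ivp` (RK45,
rtol 1e-8) is wired behind the same interface as an independent
cross-check, and the two agree on ISIs to better than 0.1%.  Spike times
are upward crossings of a detection voltage (default 0 mV) linearly
interpolated inside the step, with a 2 ms guard against double counting.
QIF threshold crossings are likewise located by in-step interpolation;
gating integration through the spike waveform uses RK4 substeps of
≤ 0.01 ms.

Burst classification discards the first 20 ISIs and finds the smallest
period N ≤ 6 under a relative tolerance of 1e-3; sequences near window
edges that have not converged within the retained sample classify as
aperiodic rather than being forced into a period.

Fixed points are sign-change brackets on a 0.01 mV grid refined by Brent's
method to residuals below 1e-9, deduplicated within 1e-6 mV.  Stability
uses the analytic Jacobian (4×4 or 3×3 with the structural zeros of the
gating cascade), cross-checked against central differences; a 1e-9 band
around zero real part is flagged marginal.  Onset classification bisects
in mu on the event "lowest fixed point stable"; the Hopf case additionally
locates the annihilation of the remaining subthreshold pair.

## The analytic rate theory

For the fixed-reset QIF the slow-gating approximation pins (x, C) at their
reset values, giving the 1D flow F(V) = mu + ψ(V) − W̄(V) with the linear
adaptation line W̄(V) = W0 + Wm·V.  Completing the square gives
F = μ̄ + g2 (V−V̄2)² with V̄2 = V2 + Wm/(2g2) and

    μ̄ = mu − W0 − Wm·V2 − Wm²/(4 g2) = mu − mu* + ε,

where mu* is the tangency bias at which min_V F = ε (ε = 0.5 is a floor
that keeps 1/F integrable).  The printed form of μ̄ in the source
publication is inconsistent with its own tangency condition; the package
uses the algebraically consistent expression above, which the quadrature
oracles confirm to 1e-8.

Above mu* the interspike interval is the closed-form arctan integral I0;
below it the trajectory stalls at V* (where F = ε) and the interval
decomposes into I1 (reset → V*, arctan/log closed form), I* (adaptation
decay at pinned voltage, first order in time: I* = (mu−ε−A)/B) and I2
(V2 → threshold under the decayed line, anchored so W̄*(V2) = mu−ε).  The
calcium decay inside I2 defaults to the forward-Euler refinement that
tracks the moving target C∞(V*, x*(t)) — it captures the transient rise
of calcium that the fixed-target exponential misses — with the analytic
variant selectable.  When the decayed slope Wm* exceeds √(4 g2 ε) the
anchored closed form for I2 is undefined (μ̄* = ε − Wm*²/(4g2) ≤ 0 follows
identically from the anchoring); the interval is then integrated
numerically with the flow floored at ε, the same regularization the
theory applies at the stall.  Rates are reported in spk/s, with and
without the refractory contribution.

The gain G = ∂R/∂mu is computed by central differences of the analytic
rate; the closed-form approximations are G− ≈ |B|/(mu−mu*)² below the
tangency (using the printed constants I1 ≈ 0, I2 ≈ 2π ms, kept as printed
with the computed-interval variant available) and G+ = √g2/(2π√μ̄) above
it.  G+ rests on the arctan span approaching π, so it is quantitatively
accurate just above mu* and tracks the finite-difference gain up to a
slowly varying factor further out; both approximations diverge at mu*,
which is why the gain peaks there.  One printed qualitative claim does not
survive the algebra: mu* does not generally increase with x_reset — the
x pathway is depolarizing (VCa far above threshold), so
∂mu*/∂x_reset = 2 gCa x_r (V2 + Wm/(2g2) − VCa) < 0; mu* does increase
with C_reset.

## The iterative algorithm

For spike-generated resets the reset values are unknown.  Each iteration
computes mu*(x_r, C_r) and branches: above it (Case 1) the stationary
voltage density p0 ∝ 1/F on [Vreset, Vth] (normalization constant exactly
I0) is mixed with the time-occupancy density of the spike waveform,
weighted I0 : τr, and the next resets are the density-weighted means
⟨x⟩ = ∫x∞(V)p(V)dV, ⟨C⟩ = ∫C∞(V, x∞(V))p(V)dV taken over the full
combined support (the subthreshold-only variant was tested and agrees
distinctly worse with direct simulation, so the combined support is the
default and only mode).  Below it (Case 2) the interval decomposition runs
with the gating decay, and the decayed end-of-stall values are pushed
through the spike waveform to produce the next resets.  Twenty transient
iterations are discarded; the retained twenty are classified with the same
periodicity machinery as the simulator.  The algorithm is deterministic.

With the packaged set the iteration reproduces the structure reported for
this scheme: stable one-spike fixed points at low and high bias (agreeing
with direct simulation to ~1.5% far above the bursting region, the error
growing toward the bursting edge where the slow-gating approximation
weakens), an unstable middle region alternating short and long intervals
(1-spk/2-spk burst character), and no reproduction of the simulated
period-adding ladder.  The repeating windows inside the unstable region
have periods 2 and 4 for gCa = 0.2 (period-3 windows appear at
gCa ≈ 0.25); the exact cycle length of these windows is sensitive to the
calibrated conductances.

## Problem sizes used by the shipped sweeps

Simulated f-I points use 2.5–5 s of model time at dt = 0.01 ms with the
first 20 ISIs discarded; burst-ladder scans use 5 s per bias at 0.25-bias
resolution; density grids use 2000 subthreshold and 500 waveform points
(refinement-stability tested); the closed-form oracles draw 100 random
admissible parameter sets.  These sizes make every result reproducible on
a single CPU in minutes.

## Limitations

* No stochastic (noise-driven) variants: all simulations are
  deterministic.
* The packaged parameter set is a calibrated emulation, not a transcription
  of the original unprinted constants; quantities tied to absolute bias
  positions (window locations, onset biases) carry that uncertainty, while
  structural results (fixed-point counts, ladder order, scaling laws,
  tangency-peak property, closed-form/oracle identities) are robust to it.
* The reduced theory's Case-2 construction assumes a single stall per
  interval; the ε-floored extension covers the strongly adapted regime but
  remains an approximation.
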