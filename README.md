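# vnboost

Modeling tools for a class of medial vestibular nucleus (MVN) neurons
whose input–output function shows a **boosting nonlinearity**: a shallow
(low-gain) segment of the firing-rate-vs-bias-current (f-I) curve at low
input, followed by a steeper (high-gain) segment at high input, with a
window of period-adding bursting in between.  The mechanism is an
adaptation current built from a high-voltage-activated calcium current
and a calcium-activated potassium current.

The package is aimed at computational neuroscientists studying adaptation
currents, bursting and f-I gain control.  It provides, as one consistent
stack:

* a 4-variable conductance-based (Hodgkin–Huxley-type) simulator
  (`vnboost.hh`) with spike detection, ISI/burst classification,
  bidirectional-AHP detection, f-I sweeps and ISI return maps;
* its 3-variable adaptive quadratic integrate-and-fire (QIF) reduction
  (`vnboost.qif`), Cm·V̇ = μ + g₂(V−V₂)² − I_Ca − I_KCa with an artificial
  spike waveform and three reset rules for the gating variables
  (waveform-integrated, fixed increments, fixed values);
* fixed-point and bifurcation analysis for both models
  (`vnboost.fixed_points`): dense-scan root finding of the reduced
  steady-state functions, analytic Jacobians, saddle-node vs Hopf onset
  classification;
* the analytic slow-gating firing-rate theory (`vnboost.theory`): the
  adaptation line W̄(V) = W₀ + W_m V, the tangency bias

      μ* = (2g₂V₂ + W_m)²/(4g₂) − g₂V₂² + W₀ + ε,

  closed-form interspike intervals I₀ (μ > μ*) and I₁ + I* + I₂ (μ < μ*),
  the rate R(μ) = 1/(ΣI + τ_r), and the gain G(μ) = ∂R/∂μ with its
  divergent approximations G₋ ∝ (μ*−μ)⁻² and G₊ ∝ μ̄⁻¹ᐟ²;
* the self-consistent iterative prediction of spike-generated reset
  values (`vnboost.iterative`), alternating the stationary voltage
  density p(V) ∝ 1/F(V) (mixed with the spike-waveform occupancy) with
  the gating means ⟨x⟩, ⟨C⟩;
* reproducible sweep experiments and fixture generation
  (`vnboost.experiments`) plus a thin `vnboost` command-line front end.

The packaged default parameter set keeps every published constant
verbatim and documents the provenance of the rest
(`vnboost.params.PROVENANCE`); see `docs/methods.md` for the calibration
and the model definitions.

## Worked example

```sh
python examples/burst_ladder.py
```

```
bias mu | rate (spk/s) | pattern   | distinct ISIs (ms)
  18.00 |         29.7 | tonic_1spk | 33.7
  19.00 |         38.4 | burst_2   | 12.8, 39.3
  20.25 |         49.0 | burst_3   | 8.4, 9.0, 44.0
  22.50 |        180.6 | tonic_1spk | 5.5, 5.5
```

Reading: at bias 18 the conductance-based model fires tonically
(one ISI ≈ 33.7 ms); at 19 it alternates a short and a long interval
(2-spike bursts); at 20.25 a third interval appears (3-spike bursts) —
the period-adding route; by 22.5 it is back to fast tonic firing.  The
rate jump from ~30 to ~180 spk/s across the burst window is the boosting
nonlinearity.  The other examples show the matching pieces: the
subthreshold fixed-point structure behind it
(`bifurcation_structure.py`), why fixed gating resets abolish bursting
but not boosting (`reset_rules.py`), the analytic rate/gain theory whose
gain peaks at μ* (`rate_theory_gain.py`), and the iterative
self-consistent predictions (`iterative_predictions.py`).

The same sweeps are scriptable from the shell, e.g.

```sh
vnboost fi --model hh --gca 0.6 --mu-min 8 --mu-max 26 --mu-step 0.5 --out out/
vnboost fixtures --tier fast --out fixtures/
```

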