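"""Self-consistent iterative predictions for spike-generated resets.

For the QIF with the artificial spike waveform, the reset values of the
gating variables are unknown: they are whatever the previous interspike
trajectory plus the waveform produce.  The iterative algorithm alternates:

* Case 1 (mu > mu*(x_r, C_r)) — the slow-gating flow F(V) stays positive,
  so the interval is I0 and the stationary voltage density is
  p0(V) ~ 1/F(V) on [Vreset, Vth] (normalization constant = I0).  The full
  density mixes p0 with the time-occupancy density of the spike waveform,
  weighted I0 : tau_r, and the next reset values are the self-consistent
  means <x> = int x_inf(V) p(V) dV and <C> = int C_inf(V, x_inf(V)) p(V) dV.
* Case 2 (mu < mu*) — the slow-gating approximation fails at V*; the
  interval decomposes into I1 + I* + I2 with the gating variables decaying
  during the stall, and the next reset values come from pushing the decayed
  end-of-trajectory gating values through the spike waveform.

The produced ISI sequence may settle to a fixed point (tonic), a repeating
cycle (bursting-like), or wander aperiodically; it is classified on the
retained iterations via the same periodicity machinery as the simulator.
The algorithm is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import calcium_steady_state, x_inf
from .hh import classify_firing_pattern
from .params import ModelParameters
from .qif import SpikeWaveform, integrate_gating_through_spike
from .theory import (
    adaptation_line,
    flow,
    gating_decay,
    interval_I0,
    interval_I1,
    interval_I2,
    interval_Istar,
    mu_star,
    v_star,
)

__all__ = [
    "VoltageDensity",
    "subthreshold_density",
    "spike_density",
    "combined_density",
    "self_consistent_means",
    "IterationRecord",
    "IterationSummary",
    "iterate",
    "segment_density_case2",
]

N_GRID_SUB = 2000
N_GRID_SPK = 500


@dataclass
class VoltageDensity:
    """Probability density over a voltage grid (trapezoid-normalized)."""

    support: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    def norm(self) -> float:
        return float(np.trapezoid(self.density, self.support))

    def expect(self, fn) -> float:
        return float(np.trapezoid(fn(self.support) * self.density, self.support))


def subthreshold_density(
    mu: float, x_r: float, C_r: float, p: ModelParameters, n_grid: int = N_GRID_SUB
) -> tuple[VoltageDensity, float]:
    """Stationary subthreshold voltage density p0(V) ~ 1/F(V) (Case 1).

    Valid only when F > 0 on the whole reset-to-threshold window; the
    normalization constant is exactly the interval I0.  Returns (p0, I0).
    """
    line = adaptation_line(x_r, C_r, p)
    grid = np.linspace(p.Vreset, p.Vth, n_grid)
    F = flow(grid, mu, line, p)
    if np.any(F <= 0):
        raise ValueError("subthreshold_density requires F(V) > 0 on [Vreset, Vth]")
    raw = p.Cm / F
    I0 = interval_I0(mu, line, p)
    return VoltageDensity(grid, raw / I0), I0


def spike_density(w: SpikeWaveform, n_grid: int = N_GRID_SPK) -> VoltageDensity:
    """Time-occupancy density of the artificial action potential.

    The waveform is piecewise linear, so occupancy is piecewise constant:
    1/|slope| per branch, normalized by the refractory period.  The rising
    branch covers [Vth, Vmax], the falling branch [Vreset, Vmax].
    """
    lo, hi = min(w.Vreset, w.Vth), w.Vmax
    grid = np.linspace(lo, hi, n_grid)
    rise_rate = (w.Vmax - w.Vth) / w.t1
    fall_rate = (w.Vmax - w.Vreset) / (w.tau_r - w.t1)
    dens = np.zeros_like(grid)
    on_rise = (grid >= w.Vth) & (grid <= w.Vmax)
    dens[on_rise] += 1.0 / rise_rate
    dens += 1.0 / fall_rate  # falling branch spans the whole support
    dens /= w.tau_r
    # trapezoid renormalization absorbs the discontinuity at Vth on the grid
    d = VoltageDensity(grid, dens)
    d.density = d.density / d.norm()
    return d


def combined_density(
    p0: VoltageDensity, pspk: VoltageDensity, I0: float, tau_r: float
) -> VoltageDensity:
    """Time-weighted mixture of subthreshold and spike densities.

    Weights I0/(I0+tau_r) and tau_r/(I0+tau_r) on a merged grid; with both
    inputs normalized the mixture needs no further normalization (A = 1).
    """
    grid = np.union1d(p0.support, pspk.support)
    w0 = I0 / (I0 + tau_r)
    ws = tau_r / (I0 + tau_r)
    dens = w0 * np.interp(grid, p0.support, p0.density, left=0.0, right=0.0)
    dens += ws * np.interp(grid, pspk.support, pspk.density, left=0.0, right=0.0)
    return VoltageDensity(grid, dens)


def self_consistent_means(
    density: VoltageDensity, p: ModelParameters
) -> tuple[float, float]:
    """Density-weighted gating means <x> and <C>.

    <x> = int x_inf(V) p(V) dV and <C> = int C_inf(V, x_inf(V)) p(V) dV
    over the density's full support (subthreshold plus waveform voltages).
    """
    mean_x = density.expect(lambda V: x_inf(V, p))
    mean_C = density.expect(lambda V: calcium_steady_state(V, x_inf(V, p), p))
    return mean_x, mean_C


@dataclass
class IterationRecord:
    index: int
    branch: str                 # "case1" | "case2"
    x_in: float
    C_in: float
    isi: float                  # ms, includes tau_r
    x_out: float
    C_out: float
    mu_star: float


@dataclass
class IterationSummary:
    records: list[IterationRecord]
    pattern: str                # one_spk | periodic_N | aperiodic | degenerate
    period: int
    mean_rate: float            # spk/s over retained iterations
    sd_rate: float
    retained_isis: np.ndarray


def iterate(
    mu: float,
    p: ModelParameters,
    n_transient: int = 20,
    n_keep: int = 20,
    init: tuple[float, float] | None = None,
    rel_tol: float = 1e-3,
    n_max_period: int = 6,
) -> IterationSummary:
    """Run the self-consistent reset iteration at bias ``mu``.

    Starting from gating-equilibrated reset values (unless ``init`` is
    given), each iteration computes mu*(x_r, C_r), branches into Case 1 or
    Case 2, produces one ISI and the next reset values.  The first
    ``n_transient`` ISIs are discarded; the retained ``n_keep`` are
    classified by their smallest repeating period (one_spk / periodic_N /
    aperiodic).  Numerical failure inside an iteration flags the summary
    ``degenerate`` instead of raising.
    """
    w = SpikeWaveform.from_params(p)
    if init is None:
        xi = float(x_inf(p.Vreset, p))
        x_r, C_r = xi, float(calcium_steady_state(p.Vreset, xi, p))
    else:
        x_r, C_r = init
    records: list[IterationRecord] = []
    degenerate = False
    for k in range(n_transient + n_keep):
        ms = mu_star(p, x_r, C_r)
        try:
            if mu > ms:
                p0, I0 = subthreshold_density(mu, x_r, C_r, p)
                pspk = spike_density(w)
                dens = combined_density(p0, pspk, I0, p.tau_r)
                x_next, C_next = self_consistent_means(dens, p)
                isi = I0 + p.tau_r
                branch = "case1"
            else:
                line = adaptation_line(x_r, C_r, p)
                I1 = interval_I1(mu, line, p)
                Istar, _, _ = interval_Istar(mu, x_r, C_r, p, line)
                Istar = max(Istar, 0.0)
                I2, _ = interval_I2(mu, x_r, C_r, p, t_star=Istar)
                Vs = v_star(mu, line, p)
                x_fun, _, C_fun_num = gating_decay(x_r, C_r, Vs, p)
                x_th = float(x_fun(Istar))
                C_th = float(C_fun_num(Istar))
                _, _, x_next, C_next = integrate_gating_through_spike(
                    min(max(x_th, 0.0), 1.0), max(C_th, 0.0), p
                )
                isi = I1 + Istar + I2 + p.tau_r
                branch = "case2"
        except (ValueError, ZeroDivisionError, FloatingPointError):
            degenerate = True
            break
        records.append(
            IterationRecord(k, branch, x_r, C_r, isi, x_next, C_next, ms)
        )
        x_r, C_r = x_next, C_next
    retained = np.array([r.isi for r in records[n_transient:]])
    if degenerate or len(retained) < 4:
        return IterationSummary(records, "degenerate", 0, float("nan"),
                                float("nan"), retained)
    pattern, period = classify_firing_pattern(
        retained, rel_tol=rel_tol, n_discard=0, n_max=n_max_period
    )
    label = {"tonic_1spk": "one_spk", "aperiodic": "aperiodic"}.get(
        pattern, f"periodic_{period}" if period else pattern
    )
    rates = 1000.0 / retained
    return IterationSummary(
        records, label, period, float(rates.mean()), float(rates.std()), retained
    )


def segment_density_case2(
    mu: float,
    x_r: float,
    C_r: float,
    p: ModelParameters,
    n_grid: int = N_GRID_SUB,
) -> dict:
    """Diagnostic per-segment voltage densities for a Case-2 trajectory.

    Occupancy densities of the three segments (reset->V* under F, the
    stall concentrated near Vbar* = (V*+V2)/2, and V2->threshold under the
    starred flow), independently normalized, plus their I1 : I* : I2
    weighted combination.  Not used by the iteration itself.
    """
    line = adaptation_line(x_r, C_r, p)
    Vs = v_star(mu, line, p)
    I1 = interval_I1(mu, line, p)
    Istar, _, _ = interval_Istar(mu, x_r, C_r, p, line)
    Istar = max(Istar, 0.0)
    I2, star = interval_I2(mu, x_r, C_r, p, t_star=Istar)

    g1 = np.linspace(p.Vreset, Vs, n_grid // 2)
    d1 = p.Cm / flow(g1, mu, line, p)
    seg1 = VoltageDensity(g1, d1 / np.trapezoid(d1, g1))

    vbar_s = 0.5 * (Vs + p.V2)
    width = max(abs(Vs - p.V2) / 10.0, 0.05)
    g2_ = np.linspace(vbar_s - 3 * width, vbar_s + 3 * width, 301)
    d2 = np.exp(-0.5 * ((g2_ - vbar_s) / width) ** 2)
    seg2 = VoltageDensity(g2_, d2 / np.trapezoid(d2, g2_))

    g3 = np.linspace(p.V2, p.Vth, n_grid // 2)
    F3 = star.W0 * 0.0 + (mu + p.g2 * (g3 - p.V2) ** 2 - star(g3))
    d3 = p.Cm / np.clip(F3, 1e-9, None)
    seg3 = VoltageDensity(g3, d3 / np.trapezoid(d3, g3))

    total = I1 + Istar + I2
    weights = np.array([I1, Istar, I2]) / total
    grid = np.union1d(np.union1d(g1, g2_), g3)
    comb = sum(
        wgt * np.interp(grid, s.support, s.density, left=0.0, right=0.0)
        for wgt, s in zip(weights, (seg1, seg2, seg3))
    )
    combined = VoltageDensity(grid, comb)
    combined.density = combined.density / combined.norm()  # segments may overlap
    return {
        "segments": (seg1, seg2, seg3),
        "weights": weights,
        "combined": combined,
        "intervals": (I1, Istar, I2),
    }
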