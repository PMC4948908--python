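"""Simulation and spike-train analysis of the conductance-based model.

The workhorse is a fixed-step RK4 integrator (compiled, ``dt`` = 0.01 ms by
default) chosen so that traces, interspike intervals and burst
classifications are exactly reproducible; an adaptive dense-output
integrator (``integrator="adaptive"``) is provided behind the same contract
for convergence cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernels as _k
from .core import calcium_steady_state, default_initial_state, hh_rhs, n_inf, x_inf
from .params import ModelParameters, State

__all__ = [
    "SimulationTrace",
    "ISISequence",
    "simulate_hh",
    "hh_spike_times",
    "detect_spikes",
    "classify_firing_pattern",
    "distinct_isi_values",
    "detect_ahp",
    "fi_curve",
    "isi_return_map",
]

#: default voltage whose upward crossings define spike times (mV)
V_DETECT = 0.0
#: absolute-refractory guard merging crossings closer than this (ms)
SPIKE_GUARD = 2.0


@dataclass
class SimulationTrace:
    """Time-sampled model state with simulation metadata."""

    times: np.ndarray          # ms, strictly increasing
    states: np.ndarray         # (n, k) rows of (V, n, x, C) or (V, x, C)
    mu: float
    dt: float
    integrator_id: str

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0]

    def to_frame(self) -> pd.DataFrame:
        cols = ["V", "n", "x", "C"] if self.states.shape[1] == 4 else ["V", "x", "C"]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "t", self.times)
        return df


@dataclass
class ISISequence:
    """Spike times, interspike intervals and their classification."""

    spike_times: np.ndarray
    pattern: str = "quiescent"          # quiescent | tonic_1spk | burst_N | aperiodic
    period: int = 0                     # repeating length (0 if none found)
    distinct_isis: list = field(default_factory=list)
    ahp_bidirectional: np.ndarray | None = None

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)

    @property
    def mean_rate(self) -> float:
        """Mean of 1/ISI in spk/s (0 when fewer than 2 spikes)."""
        isis = self.isis
        if len(isis) == 0:
            return 0.0
        return float(np.mean(1000.0 / isis))


def simulate_hh(
    p: ModelParameters,
    mu: float,
    duration: float,
    dt: float = 0.01,
    initial: State | None = None,
    record_stride: int = 1,
    integrator: str = "rk4",
) -> SimulationTrace:
    """Integrate the 4-variable model for ``duration`` ms at bias ``mu``.

    Raises ``FloatingPointError`` if the state leaves the finite range
    (integration blow-up).  The default initial condition is the
    gating-equilibrated state at the reset voltage.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    y0 = (initial or default_initial_state(p)).as_array()
    if integrator == "rk4":
        n_steps = int(round(duration / dt))
        states = _k.hh_rk4_trace(y0, mu, p.as_vector(), dt, n_steps, record_stride)
        if np.isnan(states[-1, 0]):
            raise FloatingPointError("HH integration blew up (non-finite state)")
        times = np.arange(len(states)) * (dt * record_stride)
        return SimulationTrace(times, states, mu, dt, f"rk4:dt={dt}")
    if integrator == "adaptive":
        sol = solve_ivp(
            lambda t, y: hh_rhs(State(*y), mu, p),
            (0.0, duration),
            y0,
            method="RK45",
            rtol=1e-8,
            atol=1e-10,
            dense_output=False,
            max_step=1.0,
            t_eval=np.arange(0.0, duration + 0.5 * dt, dt * record_stride),
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise FloatingPointError("adaptive HH integration failed")
        return SimulationTrace(sol.t, sol.y.T.copy(), mu, dt, "rk45-adaptive")
    raise ValueError(f"unknown integrator {integrator!r}")


def hh_spike_times(
    p: ModelParameters,
    mu: float,
    duration: float,
    dt: float = 0.01,
    initial: State | None = None,
    v_detect: float = V_DETECT,
    guard: float = SPIKE_GUARD,
) -> np.ndarray:
    """Spike times only (memory-light path used by f-I sweeps)."""
    y0 = (initial or default_initial_state(p)).as_array()
    spikes, _, ok = _k.hh_rk4_spikes(
        y0, mu, p.as_vector(), dt, int(round(duration / dt)), v_detect, guard
    )
    if not ok:
        raise FloatingPointError("HH integration blew up (non-finite state)")
    return spikes


def detect_spikes(
    trace: SimulationTrace, v_detect: float = V_DETECT, guard: float = SPIKE_GUARD
) -> np.ndarray:
    """Upward-crossing times of ``v_detect``, linearly interpolated.

    Crossings closer than ``guard`` ms are merged (absolute refractory
    guard against double detection on noisy waveforms).
    """
    V = trace.V
    t = trace.times
    below = V[:-1] < v_detect
    above = V[1:] >= v_detect
    idx = np.nonzero(below & above)[0]
    if len(idx) == 0:
        return np.array([])
    frac = (v_detect - V[idx]) / (V[idx + 1] - V[idx])
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    keep = [0]
    for i in range(1, len(times)):
        if times[i] - times[keep[-1]] >= guard:
            keep.append(i)
    return times[keep]


def classify_firing_pattern(
    isis: np.ndarray,
    rel_tol: float = 1e-3,
    n_discard: int = 20,
    n_max: int = 6,
) -> tuple[str, int]:
    """Classify a retained ISI sequence as tonic, burst-N or aperiodic.

    Discards the first ``n_discard`` ISIs as transient, then finds the
    smallest period N <= ``n_max`` such that isis[i+N] agrees with isis[i]
    to relative tolerance ``rel_tol`` for all retained i.  Returns
    (pattern, period); fewer than ``n_discard`` + 4 ISIs classify as
    ``quiescent`` with period 0.
    """
    isis = np.asarray(isis, dtype=float)
    if len(isis) < n_discard + 4:
        return "quiescent", 0
    kept = isis[n_discard:]
    for N in range(1, n_max + 1):
        if len(kept) <= N:
            break
        if np.all(np.abs(kept[N:] - kept[:-N]) <= rel_tol * np.abs(kept[:-N])):
            return ("tonic_1spk", 1) if N == 1 else (f"burst_{N}", N)
    return "aperiodic", 0


def distinct_isi_values(isis: np.ndarray, rel_tol: float = 1e-3) -> list[float]:
    """Representative ISI values after clustering at relative tolerance."""
    isis = np.sort(np.asarray(isis, dtype=float))
    out: list[float] = []
    for v in isis:
        if not out or abs(v - out[-1]) > rel_tol * out[-1]:
            out.append(float(v))
    return out


def analyze_spike_train(
    spike_times: np.ndarray,
    rel_tol: float = 1e-3,
    n_discard: int = 20,
    n_max: int = 6,
) -> ISISequence:
    """Bundle classification and distinct-ISI extraction for a spike train."""
    spike_times = np.asarray(spike_times, dtype=float)
    isis = np.diff(spike_times)
    pattern, period = classify_firing_pattern(isis, rel_tol, n_discard, n_max)
    kept = isis[n_discard:] if len(isis) > n_discard else isis
    return ISISequence(
        spike_times=spike_times,
        pattern=pattern,
        period=period,
        distinct_isis=distinct_isi_values(kept, rel_tol) if len(kept) else [],
    )


def detect_ahp(
    trace: SimulationTrace,
    spike_times: np.ndarray,
    refractory_min: float = 3.0,
    smooth_ms: float = 0.5,
    v_eps: float = 0.02,
) -> np.ndarray:
    """Flag interspike intervals containing a bidirectional AHP.

    For each segment between consecutive spikes (skipping the first
    ``refractory_min`` ms after the spike peak), the trace is smoothed with
    a ``smooth_ms`` boxcar and the number of sign changes of dV/dt is
    counted, ignoring excursions smaller than ``v_eps`` mV.  A monotone
    approach to the next spike gives 0 changes, a simple AHP 1, and the
    bidirectional AHP signature (down-up-down-up) at least 2.  Returns one
    boolean per interval: True iff the direction changes at least twice.
    """
    if len(spike_times) < 2:
        return np.zeros(0, dtype=bool)
    t = trace.times
    V = trace.V
    dt_samp = np.median(np.diff(t))
    win = max(int(round(smooth_ms / dt_samp)), 1)
    kernel = np.ones(win) / win
    Vs = np.convolve(V, kernel, mode="same")
    flags = []
    for a, b in zip(spike_times[:-1], spike_times[1:]):
        lo = np.searchsorted(t, a + refractory_min)
        hi = np.searchsorted(t, b - smooth_ms)
        seg = Vs[lo:hi]
        if len(seg) < 4:
            flags.append(False)
            continue
        # count direction reversals with amplitude hysteresis v_eps
        changes = 0
        direction = 0
        ref = seg[0]
        for v in seg[1:]:
            if direction >= 0 and v < ref - v_eps:
                changes += direction != 0
                direction = -1
                ref = v
            elif direction <= 0 and v > ref + v_eps:
                changes += direction != 0
                direction = 1
                ref = v
            elif (direction >= 0 and v > ref) or (direction <= 0 and v < ref):
                ref = v
        flags.append(changes >= 2)
    return np.array(flags, dtype=bool)


def fi_curve(
    p: ModelParameters,
    mu_grid: np.ndarray,
    duration: float = 3000.0,
    dt: float = 0.01,
    n_discard: int = 20,
    rel_tol: float = 1e-3,
    v_detect: float = V_DETECT,
) -> pd.DataFrame:
    """f-I curve: per bias current, the mean and distinct values of 1/ISI.

    Bursting solutions contribute several distinct 1/ISI values (the dots
    of an f-I plot); quiescent inputs report rate 0.  Columns: mu,
    rate_mean (spk/s), n_distinct, rate_values (spk/s list), pattern,
    period.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if np.any(np.diff(mu_grid) < 0):
        raise ValueError("mu_grid must be sorted")
    rows = []
    for mu in mu_grid:
        spikes = hh_spike_times(p, mu, duration, dt, v_detect=v_detect)
        seq = analyze_spike_train(spikes, rel_tol, n_discard)
        kept = seq.isis[n_discard:] if len(seq.isis) > n_discard else np.array([])
        rate = float(np.mean(1000.0 / kept)) if len(kept) else 0.0
        rows.append(
            {
                "mu": mu,
                "rate_mean": rate,
                "n_distinct": len(seq.distinct_isis),
                "rate_values": [1000.0 / v for v in seq.distinct_isis],
                "pattern": seq.pattern,
                "period": seq.period,
            }
        )
    return pd.DataFrame(rows)


def isi_return_map(isis: np.ndarray) -> tuple[np.ndarray, float]:
    """Consecutive ISI pairs (ISI_k, ISI_{k+1}) and the mean ISI."""
    isis = np.asarray(isis, dtype=float)
    if len(isis) < 2:
        raise ValueError("need at least 2 ISIs for a return map")
    pairs = np.column_stack([isis[:-1], isis[1:]])
    return pairs, float(np.mean(isis))
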