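"""The generalized quadratic integrate-and-fire reduction.

The spike generator (Na/K currents and the recovery variable n) is replaced
by the quadratic drive psi(V) = g2 (V - V2)^2 plus a threshold/reset
boundary condition, keeping the calcium current, the calcium-activated
potassium current and their gating dynamics.  When V reaches Vth a spike is
recorded and the voltage follows a piecewise-linear artificial action
potential for one refractory period (rising to Vmax in t1 ms, decaying to
Vreset by tau_r); the high voltages of that waveform are what activate the
calcium gate.  Three reset rules for (x, C) are supported: integrating the
gating equations through the waveform (state-dependent), adding fixed
increments, or resetting to fixed values (which forbids bursting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .core import calcium_steady_state, m_inf, n_inf, x_inf
from .hh import ISISequence, SimulationTrace, analyze_spike_train
from .params import ModelParameters, ResetMode

__all__ = [
    "SpikeWaveform",
    "spike_waveform_value",
    "integrate_gating_through_spike",
    "simulate_qif",
    "estimate_qif_params",
]

_MODE_CODE = {
    ResetMode.spike_waveform: _k.MODE_SPIKE_WAVEFORM,
    ResetMode.fixed_delta: _k.MODE_FIXED_DELTA,
    ResetMode.fixed_reset: _k.MODE_FIXED_RESET,
}


@dataclass(frozen=True)
class SpikeWaveform:
    """Piecewise-linear artificial action potential.

    Vspk(0) = Vth, Vspk(t1) = Vmax, Vspk(tau_r) = Vreset.
    """

    Vth: float
    Vmax: float
    Vreset: float
    t1: float
    tau_r: float

    @classmethod
    def from_params(cls, p: ModelParameters) -> "SpikeWaveform":
        return cls(p.Vth, p.Vmax, p.Vreset, p.t1, p.tau_r)

    def __call__(self, t):
        return spike_waveform_value(t, self)


def spike_waveform_value(t, w: SpikeWaveform):
    """Voltage of the artificial spike at time ``t`` after threshold.

    Valid for 0 <= t <= tau_r; linear rise to the peak then linear decay.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > w.tau_r):
        raise ValueError("waveform time must lie in [0, tau_r]")
    rise = w.Vth + (w.Vmax - w.Vth) / w.t1 * t
    decay = w.Vmax + (w.Vreset - w.Vmax) / (w.tau_r - w.t1) * (t - w.t1)
    out = np.where(t < w.t1, rise, decay)
    return float(out) if out.ndim == 0 else out


def integrate_gating_through_spike(
    x0: float, C0: float, p: ModelParameters, dt: float = 0.01
) -> tuple[float, float, float, float]:
    """Evolve (x, C) through one artificial action potential.

    V is clamped to the spike waveform while the gating equations run
    (RK4 substeps of at most ``dt`` ms).  Returns (dx, dC, x_end, C_end);
    the increments are what a fixed-delta reset rule would need to mimic
    this initial condition.
    """
    if not 0.0 <= x0 <= 1.0 or C0 < 0.0:
        raise ValueError("require x0 in [0,1] and C0 >= 0")
    x_end, C_end = _k.gating_through_spike(float(x0), float(C0), p.as_vector(), dt)
    return x_end - x0, C_end - C0, x_end, C_end


def simulate_qif(
    p: ModelParameters,
    mu: float,
    duration: float,
    dt: float = 0.01,
    initial: np.ndarray | None = None,
    reset_mode: ResetMode | str | None = None,
    record: bool = False,
    n_discard: int = 20,
    rel_tol: float = 1e-3,
    max_spikes: int = 200_000,
) -> tuple[SimulationTrace | None, ISISequence]:
    """Integrate the QIF with threshold/reset handling.

    Spike times are located by linear interpolation of the threshold
    crossing inside the integration step; the clock then advances by the
    refractory period with the gating variables handled according to the
    reset rule (``reset_mode`` overrides ``p.reset_mode``).  Returns the
    trace (None unless ``record``) and the analyzed spike train.  In the
    recorded trace V is clamped to Vth at the spike sample.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    mode = ResetMode(reset_mode) if reset_mode is not None else p.reset_mode
    if initial is None:
        xi = float(x_inf(p.Vreset, p))
        initial = np.array([p.Vreset, xi, calcium_steady_state(p.Vreset, xi, p)])
    spikes, times, states, final, ok = _k.qif_run(
        np.asarray(initial, dtype=float),
        mu,
        p.as_vector(),
        dt,
        duration,
        _MODE_CODE[mode],
        p.x_reset,
        p.resolved_C_reset(),
        p.dx,
        p.dC,
        max_spikes,
        record,
    )
    if not ok:
        raise FloatingPointError("QIF integration blew up (non-finite state)")
    trace = None
    if record:
        trace = SimulationTrace(times, states, mu, dt, f"rk4-qif:dt={dt}:{mode.value}")
    seq = analyze_spike_train(spikes, rel_tol=rel_tol, n_discard=n_discard)
    return trace, seq


def linearization_coefficients(p: ModelParameters, V0: float = -50.0) -> dict:
    """First-order coefficients of the gating nonlinearities about ``V0``.

    a1 = m_inf^3(V0), a2 = n_inf(V0), a3 = n_inf^4(V0) and b1, b2, b3 their
    voltage slopes: the building blocks of the quadratic reduction of the
    spike-generating currents.
    """

    def slope(f, V):
        h = 1e-5
        return float((f(V + h) - f(V - h)) / (2 * h))

    return {
        "a1": float(m_inf(V0, p) ** 3),
        "a2": float(n_inf(V0, p)),
        "a3": float(n_inf(V0, p) ** 4),
        "b1": slope(lambda V: m_inf(V, p) ** 3, V0),
        "b2": slope(lambda V: n_inf(V, p), V0),
        "b3": slope(lambda V: n_inf(V, p) ** 4, V0),
    }


def estimate_qif_params(
    p: ModelParameters, V0: float = -50.0, half_width: float = 6.0
) -> tuple[float, float]:
    """Estimate (g2, V2) from the reduced HH flow with gCa set to zero.

    The steady-state voltage equation is expanded to second order in V
    around its local minimum near ``V0``: a least-squares quadratic
    mu + k + a (V - h)^2 over [h - half_width, h + half_width] gives
    g2 = a and V2 = h.  Linearizing only the gating nonlinearities
    (m_inf^3 ~ a1 + b1 (V - V0), etc.; see
    :func:`linearization_coefficients`) discards the sodium-activation
    curvature that dominates the coefficient near the minimum, so the full
    second-order expansion is used.  The packaged set lands near the
    adopted values (0.1, -50).
    """
    from .fixed_points import h1_reduced

    q = p.with_(gCa=0.0)
    grid = np.linspace(V0 - 10.0, V0 + 10.0, 2001)
    vals = h1_reduced(grid, 0.0, q)
    h = grid[np.argmin(vals)]
    fit = np.linspace(h - half_width, h + half_width, 241)
    c = np.polyfit(fit, h1_reduced(fit, 0.0, q), 2)
    return float(c[0]), float(-c[1] / (2.0 * c[0]))
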