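"""Gating steady states, ionic currents and right-hand sides.

These are the formulas shared by the conductance-based (HH-type) model and
its quadratic integrate-and-fire reduction:

    Cm dV/dt = mu - I_ions(V, n, x, C)            (HH)
    Cm dV/dt = mu + psi(V) - I_Ca - I_KCa         (QIF), psi(V) = g2 (V-V2)^2

with I_ions = I_Na + I_K + I_leak + I_Ca + I_KCa and first-order gating
kinetics dz/dt = [z_inf(V) - z]/tau_z.  The calcium concentration relaxes
toward C_inf(V, x) = -KR * I_Ca(V, x), which is nonnegative below VCa
because the calcium current is inward there.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters, State

__all__ = [
    "steady_state_activation",
    "m_inf",
    "n_inf",
    "x_inf",
    "ionic_currents",
    "calcium_steady_state",
    "psi",
    "hh_rhs",
    "qif_rhs",
    "default_initial_state",
]


def steady_state_activation(V, a, Vhalf):
    """Sigmoidal steady-state activation z_inf(V) = 1/(1+exp(-2a(V-Vhalf))).

    Strictly increasing in V for a > 0, with value 0.5 at V = Vhalf.
    Saturates smoothly at extreme voltages (no overflow).
    """
    arg = -2.0 * a * (np.asarray(V, dtype=float) - Vhalf)
    out = np.empty_like(arg, dtype=float)
    pos = arg >= 0
    out[pos] = np.exp(-arg[pos]) / (1.0 + np.exp(-arg[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(arg[~pos]))
    if out.ndim == 0:
        return float(out)
    return out


def m_inf(V, p: ModelParameters):
    return steady_state_activation(V, p.a_m, p.Vhalf_m)


def n_inf(V, p: ModelParameters):
    return steady_state_activation(V, p.a_n, p.Vhalf_n)


def x_inf(V, p: ModelParameters):
    return steady_state_activation(V, p.a_x, p.Vhalf_x)


def ionic_currents(state: State, p: ModelParameters):
    """All five ionic currents at the given state.

    Returns (I_Na, I_K, I_leak, I_Ca, I_KCa) in uA/cm^2.  Sign convention:
    positive currents are outward (hyperpolarizing); the Na and Ca currents
    are negative (inward) below their reversal potentials.  The KCa current
    activates as C/(C+Kd); the Ca current as x^2 with no saturation term.
    """
    V, n, x, C = state.V, state.n, state.x, state.C
    mi = m_inf(V, p)
    I_Na = p.gNa * mi**3 * (1.0 - n) * (V - p.VNa)
    I_K = p.gK * n**4 * (V - p.VK)
    I_leak = p.gL * (V - p.VL)
    I_Ca = p.gCa * x**2 * (V - p.VCa)
    I_KCa = p.gKCa * C / (C + p.Kd) * (V - p.VK)
    return I_Na, I_K, I_leak, I_Ca, I_KCa


def calcium_steady_state(V, x, p: ModelParameters, *, strict: bool = False):
    """Calcium equilibrium C_inf(V, x) = -KR * I_Ca(V, x).

    Nonnegative whenever V <= VCa (inward calcium current).  With
    ``strict=True`` a negative result (V above VCa, outside the model's
    operating range) raises instead of being returned.
    """
    c = -p.KR * p.gCa * np.asarray(x, dtype=float) ** 2 * (np.asarray(V, dtype=float) - p.VCa)
    if strict and np.any(c < 0):
        raise ValueError("C_inf < 0: V exceeds VCa, outside operating range")
    if c.ndim == 0:
        return float(c)
    return c


def psi(V, p: ModelParameters):
    """Quadratic spike-generating drive of the QIF reduction, g2 (V-V2)^2."""
    dv = np.asarray(V, dtype=float) - p.V2
    out = p.g2 * dv * dv
    if out.ndim == 0:
        return float(out)
    return out


def hh_rhs(state: State, mu: float, p: ModelParameters) -> np.ndarray:
    """Right-hand side of the 4-variable conductance-based model."""
    I_Na, I_K, I_leak, I_Ca, I_KCa = ionic_currents(state, p)
    dV = (mu - (I_Na + I_K + I_leak + I_Ca + I_KCa)) / p.Cm
    dn = (n_inf(state.V, p) - state.n) / p.tau_n
    dx = (x_inf(state.V, p) - state.x) / p.tau_x
    dC = (calcium_steady_state(state.V, state.x, p) - state.C) / p.tau_C
    return np.array([dV, dn, dx, dC])


def qif_rhs(state, mu: float, p: ModelParameters) -> np.ndarray:
    """Right-hand side of the 3-variable QIF reduction (V, x, C)."""
    if isinstance(state, State):
        V, x, C = state.V, state.x, state.C
    else:
        V, x, C = state
    I_Ca = p.gCa * x**2 * (V - p.VCa)
    I_KCa = p.gKCa * C / (C + p.Kd) * (V - p.VK)
    dV = (mu + psi(V, p) - I_Ca - I_KCa) / p.Cm
    dx = (x_inf(V, p) - x) / p.tau_x
    dC = (calcium_steady_state(V, x, p) - C) / p.tau_C
    return np.array([dV, dx, dC])


def default_initial_state(p: ModelParameters) -> State:
    """Gating-equilibrated state at the reset voltage."""
    V = p.Vreset
    xi = x_inf(V, p)
    return State(V=V, n=n_inf(V, p), x=xi, C=calcium_steady_state(V, xi, p))
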