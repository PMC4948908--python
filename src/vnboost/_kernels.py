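"""Compiled fixed-step integration kernels (numba).

Parameter vectors are packed by :meth:`vnboost.params.ModelParameters.as_vector`;
the index constants below must stay in sync with ``params._VECTOR_FIELDS``.
Fixed-step RK4 is used throughout so that traces and ISI sequences are
bit-reproducible; an adaptive cross-check lives in :mod:`vnboost.hh`.
"""

import numpy as np
from numba import njit

# indices into the packed parameter vector
CM, GNA, GK, GL, VNA, VK, VL = 0, 1, 2, 3, 4, 5, 6
A_M, VH_M, A_N, VH_N, TAU_N = 7, 8, 9, 10, 11
GCA, GKCA, VCA, A_X, VH_X, TAU_X, TAU_C, KRR, KD = 12, 13, 14, 15, 16, 17, 18, 19, 20
G2, V2, VTH, VRESET, VMAX, T1, TAU_R, EPS = 21, 22, 23, 24, 25, 26, 27, 28

# QIF reset modes
MODE_SPIKE_WAVEFORM, MODE_FIXED_DELTA, MODE_FIXED_RESET = 0, 1, 2


@njit(cache=True, inline="always")
def _sig(V, a, Vh):
    arg = -2.0 * a * (V - Vh)
    if arg >= 0.0:
        e = np.exp(-arg)
        return e / (1.0 + e)
    return 1.0 / (1.0 + np.exp(arg))


@njit(cache=True, inline="always")
def _hh_deriv(V, n, x, C, mu, pv):
    mi = _sig(V, pv[A_M], pv[VH_M])
    I_Na = pv[GNA] * mi * mi * mi * (1.0 - n) * (V - pv[VNA])
    I_K = pv[GK] * n * n * n * n * (V - pv[VK])
    I_L = pv[GL] * (V - pv[VL])
    I_Ca = pv[GCA] * x * x * (V - pv[VCA])
    I_KCa = pv[GKCA] * C / (C + pv[KD]) * (V - pv[VK])
    dV = (mu - (I_Na + I_K + I_L + I_Ca + I_KCa)) / pv[CM]
    dn = (_sig(V, pv[A_N], pv[VH_N]) - n) / pv[TAU_N]
    dx = (_sig(V, pv[A_X], pv[VH_X]) - x) / pv[TAU_X]
    dC = (-pv[KRR] * I_Ca - C) / pv[TAU_C]
    return dV, dn, dx, dC


@njit(cache=True)
def hh_rk4_trace(y0, mu, pv, dt, n_steps, stride):
    """Integrate the 4-variable model, recording every ``stride`` steps."""
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, 4))
    V, n, x, C = y0[0], y0[1], y0[2], y0[3]
    out[0, 0], out[0, 1], out[0, 2], out[0, 3] = V, n, x, C
    k = 1
    for i in range(1, n_steps + 1):
        d1V, d1n, d1x, d1C = _hh_deriv(V, n, x, C, mu, pv)
        d2V, d2n, d2x, d2C = _hh_deriv(
            V + 0.5 * dt * d1V, n + 0.5 * dt * d1n, x + 0.5 * dt * d1x, C + 0.5 * dt * d1C, mu, pv
        )
        d3V, d3n, d3x, d3C = _hh_deriv(
            V + 0.5 * dt * d2V, n + 0.5 * dt * d2n, x + 0.5 * dt * d2x, C + 0.5 * dt * d2C, mu, pv
        )
        d4V, d4n, d4x, d4C = _hh_deriv(V + dt * d3V, n + dt * d3n, x + dt * d3x, C + dt * d3C, mu, pv)
        V += dt * (d1V + 2.0 * d2V + 2.0 * d3V + d4V) / 6.0
        n += dt * (d1n + 2.0 * d2n + 2.0 * d3n + d4n) / 6.0
        x += dt * (d1x + 2.0 * d2x + 2.0 * d3x + d4x) / 6.0
        C += dt * (d1C + 2.0 * d2C + 2.0 * d3C + d4C) / 6.0
        if not np.isfinite(V):
            # signal blow-up with a truncated, NaN-terminated record
            out[k, 0] = np.nan
            return out[: k + 1]
        if i % stride == 0:
            out[k, 0], out[k, 1], out[k, 2], out[k, 3] = V, n, x, C
            k += 1
    return out[:k]


@njit(cache=True)
def hh_rk4_spikes(y0, mu, pv, dt, n_steps, v_detect, guard):
    """Integrate and return interpolated upward-crossing times of ``v_detect``.

    ``guard`` (ms) merges crossings closer than an absolute refractory bound.
    Returns (spike_times, final_state, ok_flag).
    """
    V, n, x, C = y0[0], y0[1], y0[2], y0[3]
    spikes = np.empty(int(n_steps * dt / max(guard, dt)) + 8)
    ns = 0
    last = -1e30
    for i in range(1, n_steps + 1):
        Vp = V
        d1V, d1n, d1x, d1C = _hh_deriv(V, n, x, C, mu, pv)
        d2V, d2n, d2x, d2C = _hh_deriv(
            V + 0.5 * dt * d1V, n + 0.5 * dt * d1n, x + 0.5 * dt * d1x, C + 0.5 * dt * d1C, mu, pv
        )
        d3V, d3n, d3x, d3C = _hh_deriv(
            V + 0.5 * dt * d2V, n + 0.5 * dt * d2n, x + 0.5 * dt * d2x, C + 0.5 * dt * d2C, mu, pv
        )
        d4V, d4n, d4x, d4C = _hh_deriv(V + dt * d3V, n + dt * d3n, x + dt * d3x, C + dt * d3C, mu, pv)
        V += dt * (d1V + 2.0 * d2V + 2.0 * d3V + d4V) / 6.0
        n += dt * (d1n + 2.0 * d2n + 2.0 * d3n + d4n) / 6.0
        x += dt * (d1x + 2.0 * d2x + 2.0 * d3x + d4x) / 6.0
        C += dt * (d1C + 2.0 * d2C + 2.0 * d3C + d4C) / 6.0
        if not np.isfinite(V):
            return spikes[:ns], np.array([V, n, x, C]), False
        if Vp < v_detect <= V:
            t = (i - 1) * dt + dt * (v_detect - Vp) / (V - Vp)
            if t - last >= guard:
                if ns < spikes.shape[0]:
                    spikes[ns] = t
                    ns += 1
                last = t
    return spikes[:ns], np.array([V, n, x, C]), True


@njit(cache=True, inline="always")
def _spike_waveform(t, pv):
    if t < pv[T1]:
        return pv[VTH] + (pv[VMAX] - pv[VTH]) / pv[T1] * t
    return pv[VMAX] + (pv[VRESET] - pv[VMAX]) / (pv[TAU_R] - pv[T1]) * (t - pv[T1])


@njit(cache=True, inline="always")
def _gating_deriv(V, x, C, pv):
    dx = (_sig(V, pv[A_X], pv[VH_X]) - x) / pv[TAU_X]
    I_Ca = pv[GCA] * x * x * (V - pv[VCA])
    dC = (-pv[KRR] * I_Ca - C) / pv[TAU_C]
    return dx, dC


@njit(cache=True)
def gating_through_spike(x0, C0, pv, dt):
    """Evolve (x, C) along the artificial spike waveform for one refractory
    period (RK4 with V(t) clamped to the waveform).  Returns (x_end, C_end)."""
    n_sub = max(int(np.ceil(pv[TAU_R] / dt)), 2)
    h = pv[TAU_R] / n_sub
    x, C = x0, C0
    for i in range(n_sub):
        t = i * h
        Va = _spike_waveform(t, pv)
        Vb = _spike_waveform(t + 0.5 * h, pv)
        Vc = _spike_waveform(t + h, pv)
        d1x, d1C = _gating_deriv(Va, x, C, pv)
        d2x, d2C = _gating_deriv(Vb, x + 0.5 * h * d1x, C + 0.5 * h * d1C, pv)
        d3x, d3C = _gating_deriv(Vb, x + 0.5 * h * d2x, C + 0.5 * h * d2C, pv)
        d4x, d4C = _gating_deriv(Vc, x + h * d3x, C + h * d3C, pv)
        x += h * (d1x + 2.0 * d2x + 2.0 * d3x + d4x) / 6.0
        C += h * (d1C + 2.0 * d2C + 2.0 * d3C + d4C) / 6.0
    return x, C


@njit(cache=True, inline="always")
def _qif_deriv(V, x, C, mu, pv):
    dv = V - pv[V2]
    I_Ca = pv[GCA] * x * x * (V - pv[VCA])
    I_KCa = pv[GKCA] * C / (C + pv[KD]) * (V - pv[VK])
    dV = (mu + pv[G2] * dv * dv - I_Ca - I_KCa) / pv[CM]
    dx = (_sig(V, pv[A_X], pv[VH_X]) - x) / pv[TAU_X]
    dC = (-pv[KRR] * I_Ca - C) / pv[TAU_C]
    return dV, dx, dC


@njit(cache=True)
def qif_run(y0, mu, pv, dt, duration, mode, x_reset, C_reset, dx_res, dC_res,
            max_spikes, record):
    """Integrate the QIF with threshold/reset boundary conditions.

    Returns (spike_times, times, states, final_state, ok).  ``record=False``
    returns empty trace arrays.  Threshold crossings are located by linear
    interpolation inside the step; the refractory period advances clock time
    with gating handled per reset mode.
    """
    V, x, C = y0[0], y0[1], y0[2]
    spikes = np.empty(max_spikes)
    ns = 0
    cap = int(duration / dt) + 16 if record else 1
    times = np.empty(cap)
    states = np.empty((cap, 3))
    nr = 0
    t = 0.0
    ok = True
    while t < duration:
        if record and nr < cap:
            times[nr] = t
            states[nr, 0], states[nr, 1], states[nr, 2] = V, x, C
            nr += 1
        d1V, d1x, d1C = _qif_deriv(V, x, C, mu, pv)
        d2V, d2x, d2C = _qif_deriv(V + 0.5 * dt * d1V, x + 0.5 * dt * d1x, C + 0.5 * dt * d1C, mu, pv)
        d3V, d3x, d3C = _qif_deriv(V + 0.5 * dt * d2V, x + 0.5 * dt * d2x, C + 0.5 * dt * d2C, mu, pv)
        d4V, d4x, d4C = _qif_deriv(V + dt * d3V, x + dt * d3x, C + dt * d3C, mu, pv)
        Vn = V + dt * (d1V + 2.0 * d2V + 2.0 * d3V + d4V) / 6.0
        xn = x + dt * (d1x + 2.0 * d2x + 2.0 * d3x + d4x) / 6.0
        Cn = C + dt * (d1C + 2.0 * d2C + 2.0 * d3C + d4C) / 6.0
        if not np.isfinite(Vn):
            ok = False
            break
        if Vn >= pv[VTH]:
            # locate the crossing within the step
            frac = (pv[VTH] - V) / (Vn - V)
            t_spk = t + frac * dt
            if ns >= max_spikes:
                break
            spikes[ns] = t_spk
            ns += 1
            # gating at the moment of threshold (linear within the step)
            x_th = x + frac * (xn - x)
            C_th = C + frac * (Cn - C)
            if mode == MODE_SPIKE_WAVEFORM:
                x, C = gating_through_spike(x_th, C_th, pv, min(dt, 0.01))
            elif mode == MODE_FIXED_DELTA:
                x = x_th + dx_res
                C = C_th + dC_res
            else:
                x = x_reset
                C = C_reset
            if x < 0.0:
                x = 0.0
            if x > 1.0:
                x = 1.0
            if C < 0.0:
                C = 0.0
            V = pv[VRESET]
            if record and nr < cap:
                times[nr] = t_spk
                states[nr, 0], states[nr, 1], states[nr, 2] = pv[VTH], x_th, C_th
                nr += 1
            t = t_spk + pv[TAU_R]
        else:
            V, x, C = Vn, xn, Cn
            t += dt
    return spikes[:ns], times[:nr], states[:nr], np.array([V, x, C]), ok
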