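"""Fixed points, stability and bifurcation structure.

Subthreshold fixed points of both models satisfy a scalar equation in V
obtained by substituting the gating steady states:

    HH :  H1(V) = mu - I_ions(V, n_inf(V), x_inf(V), C_inf(V)) = 0
    QIF:  F1(V) = mu + psi(V) - I_Ca(V, x_inf) - I_KCa(V, C_inf) = 0

Roots are located by a dense scan with sign-change bracketing refined by
bisection; stability comes from the eigenvalues of the analytic Jacobian
(4x4 for the HH model, 3x3 for the QIF, with the structural zeros of the
gating cascade).  Spiking onset is classified saddle-node when the stable
low-voltage fixed point annihilates with the middle one, and Hopf when it
loses stability through a complex pair while the remaining (now unstable)
subthreshold pair annihilates only at a higher bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import calcium_steady_state, m_inf, n_inf, psi, x_inf
from .params import ModelParameters

__all__ = [
    "FixedPointRecord",
    "BifurcationDiagram",
    "h1_reduced",
    "f1_reduced",
    "find_fixed_points",
    "jacobian_matrix",
    "jacobian_eigenvalues",
    "bifurcation_diagram",
    "count_subthreshold_fixed_points",
]

RESIDUAL_TOL = 1e-9
DEDUP_TOL = 1e-6
MARGINAL_BAND = 1e-9


def _sig_prime(z, a):
    # d z_inf / dV for z_inf = 1/(1+exp(-2a(V-Vh)))
    return 2.0 * a * z * (1.0 - z)


def h1_reduced(V, mu, p: ModelParameters):
    """Reduced steady-state function of the 4-variable model.

    All gating variables are at their voltage steady states; the bias
    current enters additively, so raising mu translates the curve up.
    """
    V = np.asarray(V, dtype=float)
    n = n_inf(V, p)
    x = x_inf(V, p)
    C = calcium_steady_state(V, x, p)
    mi = m_inf(V, p)
    out = (
        mu
        - p.gL * (V - p.VL)
        - p.gNa * mi**3 * (1.0 - n) * (V - p.VNa)
        - p.gK * n**4 * (V - p.VK)
        - p.gCa * x**2 * (V - p.VCa)
        - p.gKCa * C / (C + p.Kd) * (V - p.VK)
    )
    return float(out) if out.ndim == 0 else out


def f1_reduced(V, mu, p: ModelParameters):
    """Reduced steady-state function of the QIF model.

    The spike-generating term is the quadratic psi(V) = g2 (V - V2)^2 with
    positive sign (depolarizing), consistent with the QIF voltage equation.
    """
    V = np.asarray(V, dtype=float)
    x = x_inf(V, p)
    C = calcium_steady_state(V, x, p)
    out = (
        mu
        + psi(V, p)
        - p.gCa * x**2 * (V - p.VCa)
        - p.gKCa * C / (C + p.Kd) * (V - p.VK)
    )
    return float(out) if out.ndim == 0 else out


_REDUCED = {"hh": h1_reduced, "qif": f1_reduced}


@dataclass
class FixedPointRecord:
    model: str
    mu: float
    V: float
    n: float
    x: float
    C: float
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool = False
    residual: float = 0.0

    def state_vector(self) -> np.ndarray:
        if self.model == "hh":
            return np.array([self.V, self.n, self.x, self.C])
        return np.array([self.V, self.x, self.C])


def find_fixed_points(
    model: str,
    mu: float,
    p: ModelParameters,
    v_window: tuple[float, float] | None = None,
    scan_dv: float = 0.01,
) -> list[FixedPointRecord]:
    """All fixed points with V in ``v_window`` (default [VK+1, VCa-1]).

    Sign-change brackets on a ``scan_dv``-spaced grid are refined by
    bisection to |residual| < 1e-9 and deduplicated within 1e-6 mV.
    Roots within one grid cell of the window edge trigger a warning-level
    note in the record ordering but are still returned.
    """
    fun = _REDUCED[model]
    lo, hi = v_window if v_window is not None else (p.VK + 1.0, p.VCa - 1.0)
    grid = np.arange(lo, hi + scan_dv, scan_dv)
    vals = fun(grid, mu, p)
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    roots: list[float] = []
    for i in idx:
        a, b = grid[i], grid[i + 1]
        if vals[i] == 0.0:
            roots.append(a)
            continue
        r = brentq(lambda v: fun(v, mu, p), a, b, xtol=1e-13, maxiter=200)
        if abs(fun(r, mu, p)) > RESIDUAL_TOL * max(1.0, abs(mu)):
            # brentq stops on interval width; polish by bisection on residual
            r = brentq(lambda v: fun(v, mu, p), a, b, xtol=1e-15, maxiter=300)
        roots.append(r)
    dedup: list[float] = []
    for r in sorted(roots):
        if not dedup or abs(r - dedup[-1]) > DEDUP_TOL:
            dedup.append(r)
    out = []
    for r in dedup:
        x = float(x_inf(r, p))
        rec = FixedPointRecord(
            model=model,
            mu=mu,
            V=r,
            n=float(n_inf(r, p)) if model == "hh" else float("nan"),
            x=x,
            C=float(calcium_steady_state(r, x, p)),
            eigenvalues=np.array([]),
            stable=False,
            residual=float(fun(r, mu, p)),
        )
        lam = jacobian_eigenvalues(model, rec, p)
        rec.eigenvalues = lam
        mx = lam.real.max()
        rec.stable = bool(mx < 0.0)
        rec.marginal = bool(abs(mx) < MARGINAL_BAND)
        out.append(rec)
    return out


def jacobian_matrix(model: str, V: float, p: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of the flow at a gating-equilibrated point.

    The point need not be a fixed point of V; gating variables are taken at
    their steady states for the given V (as they are at any fixed point).
    Structural zeros: n, x and C do not interact directly except through V,
    and C depends on x through the calcium influx.
    """
    n = float(n_inf(V, p))
    x = float(x_inf(V, p))
    C = float(calcium_steady_state(V, x, p))
    mi = float(m_inf(V, p))
    dmi = _sig_prime(mi, p.a_m)
    dni = _sig_prime(n, p.a_n)
    dxi = _sig_prime(x, p.a_x)
    sig = C / (C + p.Kd)
    dsig_dC = p.Kd / (C + p.Kd) ** 2

    # dV/dt = (mu - I_ions)/Cm  (HH)  or  (mu + psi - I_Ca - I_KCa)/Cm (QIF)
    dICa_dV = p.gCa * x**2
    dICa_dx = 2.0 * p.gCa * x * (V - p.VCa)
    dIKCa_dV = p.gKCa * sig
    dIKCa_dC = p.gKCa * dsig_dC * (V - p.VK)
    # C_inf(V, x) = -KR * I_Ca
    dCinf_dV = -p.KR * dICa_dV
    dCinf_dx = -p.KR * dICa_dx

    if model == "hh":
        dINa_dV = p.gNa * (1.0 - n) * (3.0 * mi**2 * dmi * (V - p.VNa) + mi**3)
        dINa_dn = -p.gNa * mi**3 * (V - p.VNa)
        dIK_dV = p.gK * n**4
        dIK_dn = 4.0 * p.gK * n**3 * (V - p.VK)
        J = np.zeros((4, 4))
        J[0, 0] = -(dINa_dV + dIK_dV + p.gL + dICa_dV + dIKCa_dV) / p.Cm
        J[0, 1] = -(dINa_dn + dIK_dn) / p.Cm
        J[0, 2] = -dICa_dx / p.Cm
        J[0, 3] = -dIKCa_dC / p.Cm
        J[1, 0] = dni / p.tau_n
        J[1, 1] = -1.0 / p.tau_n
        J[2, 0] = dxi / p.tau_x
        J[2, 2] = -1.0 / p.tau_x
        J[3, 0] = dCinf_dV / p.tau_C
        J[3, 2] = dCinf_dx / p.tau_C
        J[3, 3] = -1.0 / p.tau_C
        return J
    if model == "qif":
        dpsi = 2.0 * p.g2 * (V - p.V2)
        J = np.zeros((3, 3))
        J[0, 0] = (dpsi - dICa_dV - dIKCa_dV) / p.Cm
        J[0, 1] = -dICa_dx / p.Cm
        J[0, 2] = -dIKCa_dC / p.Cm
        J[1, 0] = dxi / p.tau_x
        J[1, 1] = -1.0 / p.tau_x
        J[2, 0] = dCinf_dV / p.tau_C
        J[2, 1] = dCinf_dx / p.tau_C
        J[2, 2] = -1.0 / p.tau_C
        return J
    raise ValueError(f"unknown model {model!r}")


def jacobian_eigenvalues(model: str, fp: FixedPointRecord, p: ModelParameters) -> np.ndarray:
    return np.linalg.eigvals(jacobian_matrix(model, fp.V, p))


def count_subthreshold_fixed_points(
    model: str, mu: float, p: ModelParameters, scan_dv: float = 0.01
) -> int:
    """Number of fixed points with Vreset <= V <= Vth."""
    fps = find_fixed_points(model, mu, p, v_window=(p.Vreset, p.Vth), scan_dv=scan_dv)
    return len(fps)


@dataclass
class BifurcationDiagram:
    model: str
    mu_grid: np.ndarray
    fixed_points: list            # list (per mu) of FixedPointRecord lists
    onset_type: str | None        # "saddle_node" | "hopf" | None
    onset_mu: float | None
    subthreshold_annihilation_mu: float | None
    limit_cycle: pd.DataFrame | None = None   # mu, v_min, v_max, v_mean

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mu, fps in zip(self.mu_grid, self.fixed_points):
            for fp in fps:
                rows.append(
                    {"mu": mu, "V": fp.V, "stable": fp.stable,
                     "max_re_eig": fp.eigenvalues.real.max()}
                )
        return pd.DataFrame(rows)


def _max_stable_re(fps: list[FixedPointRecord]) -> float | None:
    """Max real eigenvalue part of the lowest-V fixed point, None if absent."""
    if not fps:
        return None
    return float(fps[0].eigenvalues.real.max())


def bifurcation_diagram(
    model: str,
    p: ModelParameters,
    mu_grid: np.ndarray,
    v_window: tuple[float, float] | None = None,
    scan_dv: float = 0.01,
    limit_cycle: bool = False,
    lc_duration: float = 2000.0,
    lc_dt: float = 0.01,
) -> BifurcationDiagram:
    """Sweep fixed points and stability over ``mu_grid`` and classify onset.

    Onset is the bias at which the lowest-voltage stable fixed point
    disappears or destabilizes: saddle-node when it annihilates with the
    middle root (root count drops), Hopf when a complex-conjugate pair
    crosses the imaginary axis while the root persists.  For the Hopf case
    the later annihilation of the two remaining unstable subthreshold fixed
    points is also located (both refined by bisection in mu).  Optional
    limit-cycle extremes (V min/max/mean over the post-transient trace) are
    measured by direct simulation.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if np.any(np.diff(mu_grid) < 0):
        raise ValueError("mu_grid must be sorted")
    all_fps = [find_fixed_points(model, mu, p, v_window, scan_dv) for mu in mu_grid]

    onset_type = None
    onset_mu = None
    ann_mu = None

    def lowest_stable(fps):
        return bool(fps) and fps[0].stable

    for i in range(1, len(mu_grid)):
        prev, cur = all_fps[i - 1], all_fps[i]
        if lowest_stable(prev) and not lowest_stable(cur):
            lo, hi = mu_grid[i - 1], mu_grid[i]
            # bisect in mu on the event "lowest FP stable"
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                fps_mid = find_fixed_points(model, mid, p, v_window, scan_dv)
                if lowest_stable(fps_mid):
                    lo = mid
                else:
                    hi = mid
            onset_mu = 0.5 * (lo + hi)
            fps_hi = find_fixed_points(model, hi, p, v_window, scan_dv)
            fps_lo = find_fixed_points(model, lo, p, v_window, scan_dv)
            if len(fps_hi) < len(fps_lo):
                onset_type = "saddle_node"
            else:
                # stable FP persists but destabilized: complex pair crossing
                ev = fps_hi[0].eigenvalues
                cross = ev[np.argmax(ev.real)]
                onset_type = "hopf" if abs(cross.imag) > 0 else "saddle_node"
            break

    # subthreshold annihilation of the remaining unstable pair (hopf route)
    if onset_type == "hopf":
        def n_sub(mu):
            return count_subthreshold_fixed_points(model, mu, p, scan_dv)

        counts = [len([f for f in fps if p.Vreset <= f.V <= p.Vth]) for fps in all_fps]
        for i in range(1, len(mu_grid)):
            if counts[i - 1] >= 2 and counts[i] < 2 and mu_grid[i] > onset_mu:
                lo, hi = mu_grid[i - 1], mu_grid[i]
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    if n_sub(mid) >= 2:
                        lo = mid
                    else:
                        hi = mid
                ann_mu = 0.5 * (lo + hi)
                break

    lc = None
    if limit_cycle:
        from .hh import hh_spike_times, simulate_hh
        from .qif import simulate_qif

        rows = []
        for mu in mu_grid:
            if model == "hh":
                tr = simulate_hh(p, mu, lc_duration, lc_dt, record_stride=10)
            else:
                tr, _ = simulate_qif(p, mu, lc_duration, lc_dt, record=True)
            half = tr.V[len(tr.V) // 2:]
            rows.append(
                {"mu": mu, "v_min": float(half.min()), "v_max": float(half.max()),
                 "v_mean": float(half.mean())}
            )
        lc = pd.DataFrame(rows)

    return BifurcationDiagram(
        model=model,
        mu_grid=mu_grid,
        fixed_points=all_fps,
        onset_type=onset_type,
        onset_mu=onset_mu,
        subthreshold_annihilation_mu=ann_mu,
        limit_cycle=lc,
    )
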