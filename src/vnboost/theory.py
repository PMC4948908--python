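"""Analytic firing-rate and gain theory for the fixed-reset QIF.

Under the slow-gating approximation the calcium variables are pinned to
their reset values (x = x_r, C = C_r), collapsing the calcium and KCa
currents into a single linear adaptation current

    Wbar(V) = W0 + Wm V,
    Wm = gCa x_r^2 + gKCa C_r/(C_r + Kd),
    W0 = -(gCa x_r^2 VCa + gKCa C_r/(C_r + Kd) VK),

and the voltage obeys the one-dimensional flow

    Cm dV/dt = F(V) = mu + g2 (V - V2)^2 - Wbar(V)
             = mu_bar + g2 (V - Vbar2)^2,

with Vbar2 = V2 + Wm/(2 g2) and mu_bar = mu - W0 - Wm V2 - Wm^2/(4 g2).
The tangency bias mu* (where min_V F = eps, a small floor keeping 1/F
integrable) separates two regimes:

* mu > mu*  — the interspike trajectory runs monotonically from reset to
  threshold in time I0 (closed-form arctan integral), giving rate
  R = 1/(I0 + tau_r).
* mu < mu*  — the trajectory stalls at the lower intersection V* of the
  parabola with the adaptation line; the interval decomposes into I1
  (reset to V*, log/arctan closed form), I* (gating decay at nearly
  constant voltage until the adaptation current reaches the parabola's
  bottom, first order in time) and I2 (V2 to threshold under the decayed
  adaptation line), giving R = 1/(I1 + I* + I2 + tau_r).

Note mu_bar = mu - mu* + eps exactly, which makes the tangency condition
mu_bar(mu*) = eps transparent.  The gain G = dR/dmu peaks near mu*, with
closed-form approximations G- ~ |B|/(mu - mu*)^2 below and
G+ = sqrt(g2)/(2 pi sqrt(mu_bar)) above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .core import calcium_steady_state, x_inf
from .params import ModelParameters

__all__ = [
    "AdaptationLine",
    "adaptation_line",
    "flow",
    "mu_bar",
    "vbar2",
    "mu_star",
    "interval_I0",
    "v_star",
    "interval_I1",
    "gating_decay",
    "interval_Istar",
    "interval_I2",
    "TheoryResult",
    "firing_rate",
    "gain",
    "theory_error_curves",
]


@dataclass(frozen=True)
class AdaptationLine:
    """Linear-in-V mean adaptation current Wbar(V) = W0 + Wm V."""

    W0: float
    Wm: float

    def __call__(self, V):
        return self.W0 + self.Wm * np.asarray(V, dtype=float)


def adaptation_line(x_r: float, C_r: float, p: ModelParameters) -> AdaptationLine:
    """Adaptation line from frozen gating values (x_r, C_r).

    Equals I_Ca(V, x_r) + I_KCa(V, C_r) pointwise; the slope is
    nonnegative, vanishing only when both conductance pathways are off.
    """
    if not 0.0 <= x_r <= 1.0 or C_r < 0.0:
        raise ValueError("require x_r in [0,1], C_r >= 0")
    sig = C_r / (C_r + p.Kd)
    Wm = p.gCa * x_r**2 + p.gKCa * sig
    W0 = -(p.gCa * x_r**2 * p.VCa + p.gKCa * sig * p.VK)
    return AdaptationLine(W0=W0, Wm=Wm)


def flow(V, mu: float, line: AdaptationLine, p: ModelParameters):
    """1D reduced flow F(V) = mu + g2 (V - V2)^2 - Wbar(V)."""
    V = np.asarray(V, dtype=float)
    return mu + p.g2 * (V - p.V2) ** 2 - line(V)


def vbar2(line: AdaptationLine, p: ModelParameters) -> float:
    """Vertex voltage of F: Vbar2 = V2 + Wm/(2 g2)."""
    return p.V2 + line.Wm / (2.0 * p.g2)


def mu_bar(mu: float, line: AdaptationLine, p: ModelParameters) -> float:
    """Minimum of F over V (completed square): mu - W0 - Wm V2 - Wm^2/(4 g2)."""
    return mu - line.W0 - line.Wm * p.V2 - line.Wm**2 / (4.0 * p.g2)


def mu_star(p: ModelParameters, x_r: float | None = None, C_r: float | None = None) -> float:
    """Tangency bias mu*: for mu > mu* the flow satisfies F > eps everywhere.

    mu* = (2 g2 V2 + Wm)^2/(4 g2) - g2 V2^2 + W0 + eps.  Equivalently
    mu_bar(mu*) = eps.
    """
    if x_r is None:
        x_r = p.x_reset
    if C_r is None:
        C_r = p.resolved_C_reset()
    line = adaptation_line(x_r, C_r, p)
    return (
        (2.0 * p.g2 * p.V2 + line.Wm) ** 2 / (4.0 * p.g2)
        - p.g2 * p.V2**2
        + line.W0
        + p.eps
    )


def _antiderivative(V, mub: float, vb2: float, g2: float):
    """Antiderivative of 1/(mub + g2 (V - vb2)^2) (branch by sign of mub)."""
    u = V - vb2
    if mub > 0:
        s = math.sqrt(g2 * mub)
        return math.atan(math.sqrt(g2 / mub) * u) / s
    if mub < 0:
        m = -mub
        s = math.sqrt(g2 * m)
        r = math.sqrt(g2 / m) * u
        return math.log(abs((r - 1.0) / (r + 1.0))) / (2.0 * s)
    return -1.0 / (g2 * u)


def _closed_interval(Va: float, Vb: float, mub: float, vb2: float, p: ModelParameters) -> float:
    """Cm * integral of dV / (mub + g2 (V - vb2)^2) from Va to Vb."""
    return p.Cm * (
        _antiderivative(Vb, mub, vb2, p.g2) - _antiderivative(Va, mub, vb2, p.g2)
    )


def interval_I0(mu: float, line: AdaptationLine, p: ModelParameters) -> float:
    """Reset-to-threshold time for mu > mu* (closed-form arctan integral)."""
    mub = mu_bar(mu, line, p)
    if mub <= 0:
        raise ValueError("interval_I0 requires mu > mu* (mu_bar > 0)")
    return _closed_interval(p.Vreset, p.Vth, mub, vbar2(line, p), p)


def v_star(mu: float, line: AdaptationLine, p: ModelParameters) -> float:
    """Lower intersection of the parabola with the adaptation line (F = eps).

    Defined for mu < mu*; the minus root of the quadratic, always below
    the vertex Vbar2.
    """
    mub = mu_bar(mu, line, p)
    disc = (p.eps - mub) / p.g2
    if disc < -1e-12:
        raise ValueError("v_star requires mu < mu* (discriminant < 0 otherwise)")
    return vbar2(line, p) - math.sqrt(max(disc, 0.0))


def interval_I1(mu: float, line: AdaptationLine, p: ModelParameters) -> float:
    """Reset-to-V* time for mu < mu* (log closed form when mu_bar < 0).

    The flow stays >= eps on [Vreset, V*], so the integral is finite; the
    singular voltages of the antiderivative lie strictly inside the
    excluded eps-neighbourhood beyond V*.
    """
    vs = v_star(mu, line, p)
    if p.Vreset > vs:
        raise ValueError("interval_I1 requires Vreset <= V*")
    mub = mu_bar(mu, line, p)
    return _closed_interval(p.Vreset, vs, mub, vbar2(line, p), p)


def gating_decay(
    x_r: float,
    C_r: float,
    Vs: float,
    p: ModelParameters,
    t_grid: np.ndarray | None = None,
    dt: float = 0.01,
):
    """Gating relaxation while the voltage stalls between V* and V2.

    With the voltage pinned at Vbar* = (V* + V2)/2, the calcium-channel
    activation relaxes exponentially to x_inf(Vbar*); the analytic calcium
    solution uses the fixed target C_inf(V*, x_inf(Vbar*)), while the
    refined numeric variant (forward Euler, step ``dt``) tracks the moving
    target C_inf(V*, x*(t)), which captures the transient rise of calcium
    before its decay.  Returns (x_fun, C_fun_analytic, C_fun_numeric),
    each mapping a time array to values.
    """
    vbar_s = 0.5 * (Vs + p.V2)
    x_inf_s = float(x_inf(vbar_s, p))
    C_inf_s = float(calcium_steady_state(Vs, x_inf_s, p))

    def x_fun(t):
        t = np.asarray(t, dtype=float)
        return x_inf_s - (x_inf_s - x_r) * np.exp(-t / p.tau_x)

    def C_fun(t):
        t = np.asarray(t, dtype=float)
        return C_inf_s - (C_inf_s - C_r) * np.exp(-t / p.tau_C)

    def C_fun_numeric(t):
        t = np.asarray(t, dtype=float)
        t_end = float(np.max(t)) if t.size else 0.0
        n = max(int(math.ceil(t_end / dt)), 1)
        ts = np.linspace(0.0, n * dt, n + 1)
        Cs = np.empty(n + 1)
        Cs[0] = C_r
        xs = x_fun(ts)
        for i in range(1, n + 1):
            Ci = float(calcium_steady_state(Vs, xs[i - 1], p))
            Cs[i] = Cs[i - 1] + dt * (Ci - Cs[i - 1]) / p.tau_C
        return np.interp(t, ts, Cs)

    return x_fun, C_fun, C_fun_numeric


def interval_Istar(
    mu: float,
    x_r: float,
    C_r: float,
    p: ModelParameters,
    line: AdaptationLine | None = None,
) -> tuple[float, float, float]:
    """Stall time I* from first-order decay of the adaptation current.

    The adaptation current W*(t) at the stalled voltage V* starts at
    A (its value with the reset gating) and decays at rate B (the slopes
    of x^2 and C/(C+Kd) evaluated one time constant into their relaxation,
    carrying the e^-1 factor); the stall ends when W* meets the parabola
    bottom mu - eps, giving I* = (mu - eps - A)/B.  Geometrically, the
    distance W must travel divided by its velocity.  Returns (I*, A, B).
    """
    if line is None:
        line = adaptation_line(x_r, C_r, p)
    Vs = v_star(mu, line, p)
    vbar_s = 0.5 * (Vs + p.V2)
    x_inf_s = float(x_inf(vbar_s, p))
    C_inf_s = float(calcium_steady_state(Vs, x_inf_s, p))

    a1 = x_r**2
    a2 = C_r / (p.Kd + C_r)
    x_tau = x_inf_s - (x_inf_s - x_r) * math.exp(-1.0)
    C_tau = C_inf_s - (C_inf_s - C_r) * math.exp(-1.0)
    b1 = 2.0 * x_tau * (x_inf_s - x_r) / p.tau_x * math.exp(-1.0)
    b2 = p.Kd * (C_inf_s - C_r) / ((p.Kd + C_tau) ** 2 * p.tau_C) * math.exp(-1.0)

    A = p.gCa * a1 * (Vs - p.VCa) + p.gKCa * a2 * (Vs - p.VK)
    B = p.gCa * b1 * (Vs - p.VCa) + p.gKCa * b2 * (Vs - p.VK)
    if abs(B) < 1e-14:
        raise ZeroDivisionError("degenerate adaptation decay: B ~ 0")
    return (mu - p.eps - A) / B, A, B


def interval_I2(
    mu: float,
    x_r: float,
    C_r: float,
    p: ModelParameters,
    t_star: float | None = None,
    c_variant: str = "numeric",
) -> tuple[float, AdaptationLine]:
    """V2-to-threshold time under the decayed adaptation line.

    The gating values decayed over the stall, x*(t*) and C*(t*), define a
    new slope Wm*; the offset is anchored so that Wbar*(V2) = mu - eps
    (the trajectory leaves the stall at the parabola's bottom).  The
    interval is the same closed-form integral as I0 with the starred
    variables.  ``c_variant`` selects the analytic or the refined numeric
    calcium decay (the numeric one tracks the transient calcium rise and
    is the default).  Returns (I2, starred AdaptationLine).
    """
    line = adaptation_line(x_r, C_r, p)
    if t_star is None:
        t_star, _, _ = interval_Istar(mu, x_r, C_r, p, line)
    t_star = max(t_star, 0.0)
    Vs = v_star(mu, line, p)
    x_fun, C_fun, C_fun_num = gating_decay(x_r, C_r, Vs, p)
    x_t = float(x_fun(t_star))
    C_t = float((C_fun_num if c_variant == "numeric" else C_fun)(t_star))

    Wm_s = p.gCa * x_t**2 + p.gKCa * C_t / (p.Kd + C_t)
    W0_s = mu - p.eps - Wm_s * p.V2
    star = AdaptationLine(W0=W0_s, Wm=Wm_s)
    mub_s = mu_bar(mu, star, p)
    if mub_s > 0:
        return _closed_interval(p.V2, p.Vth, mub_s, vbar2(star, p), p), star
    # Strong decayed slope (Wm* > sqrt(4 g2 eps)): the starred line
    # re-intersects the parabola above its bottom and the closed form is
    # undefined.  Treat the flow as floored at eps there (the same floor
    # that regularizes the stall) and integrate numerically.
    grid = np.linspace(p.V2, p.Vth, 4001)
    F = np.maximum(flow(grid, mu, star, p), p.eps)
    return float(p.Cm * np.trapezoid(1.0 / F, grid)), star


@dataclass
class TheoryResult:
    """Per-mu theory sweep for one fixed-reset configuration."""

    mu: np.ndarray
    mu_star: float
    x_r: float
    C_r: float
    table: pd.DataFrame          # columns: mu, branch, I0, I1, Istar, I2,
    #                              V_star, A, B, R_tau (spk/s), R_0 (spk/s)

    def rate(self, with_refractory: bool = True) -> np.ndarray:
        return self.table["R_tau" if with_refractory else "R_0"].to_numpy()


def firing_rate(
    mu_grid: np.ndarray,
    p: ModelParameters,
    x_r: float | None = None,
    C_r: float | None = None,
    c_variant: str = "numeric",
) -> TheoryResult:
    """Analytic steady-state rate across the boosting nonlinearity.

    Branches at mu*: R = 1/(I1 + I* + I2 + tau_r) below, 1/(I0 + tau_r)
    above; both the tau_r and tau_r = 0 variants are reported, in spk/s.
    Biases whose interval decomposition is out of domain (for example
    I* < 0 just below mu*, where the stall vanishes) report NaN rather
    than a fabricated rate.
    """
    if x_r is None:
        x_r = p.x_reset
    if C_r is None:
        C_r = p.resolved_C_reset()
    line = adaptation_line(x_r, C_r, p)
    ms = mu_star(p, x_r, C_r)
    rows = []
    for mu in np.asarray(mu_grid, dtype=float):
        row = {
            "mu": mu, "branch": "high" if mu > ms else "low",
            "I0": np.nan, "I1": np.nan, "Istar": np.nan, "I2": np.nan,
            "V_star": np.nan, "A": np.nan, "B": np.nan,
        }
        try:
            if mu > ms:
                I0 = interval_I0(mu, line, p)
                row["I0"] = I0
                total = I0
            else:
                I1 = interval_I1(mu, line, p)
                Istar, A, B = interval_Istar(mu, x_r, C_r, p, line)
                Istar = max(Istar, 0.0)
                I2, _ = interval_I2(mu, x_r, C_r, p, t_star=Istar, c_variant=c_variant)
                row.update(
                    I1=I1, Istar=Istar, I2=I2, V_star=v_star(mu, line, p), A=A, B=B
                )
                total = I1 + Istar + I2
            row["R_tau"] = 1000.0 / (total + p.tau_r)
            row["R_0"] = 1000.0 / total if total > 0 else np.nan
        except (ValueError, ZeroDivisionError):
            row["R_tau"] = np.nan
            row["R_0"] = np.nan
        rows.append(row)
    return TheoryResult(
        mu=np.asarray(mu_grid, dtype=float),
        mu_star=ms,
        x_r=x_r,
        C_r=C_r,
        table=pd.DataFrame(rows),
    )


def gain(result: TheoryResult, p: ModelParameters) -> pd.DataFrame:
    """Gain G = dR/dmu and its closed-form approximations.

    G (and G for the tau_r = 0 rate) come from central finite differences
    of the analytic rate.  G_minus = |B|/(mu - mu*)^2 applies below mu*
    (the printed reduction with I1 ~ 0, I2 ~ 2 pi ms); G_plus =
    sqrt(g2)/(2 pi sqrt(mu_bar)) applies above.  Both diverge at mu*,
    which is why the gain peaks there.  Units: (spk/s) per unit bias.
    """
    mu = result.mu
    line = adaptation_line(result.x_r, result.C_r, p)
    G_tau = np.gradient(result.rate(True), mu)
    G_0 = np.gradient(result.rate(False), mu)
    G_minus = np.full_like(mu, np.nan)
    G_plus = np.full_like(mu, np.nan)
    below = mu < result.mu_star
    B = result.table["B"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        G_minus[below] = 1000.0 * np.abs(B[below]) / (mu[below] - result.mu_star) ** 2
        mub = np.array([mu_bar(m, line, p) for m in mu])
        above = mub > 0
        G_plus[above] = 1000.0 * math.sqrt(p.g2) / (2.0 * math.pi * np.sqrt(mub[above]))
    return pd.DataFrame(
        {"mu": mu, "G_tau": G_tau, "G_0": G_0, "G_minus": G_minus, "G_plus": G_plus}
    )


def theory_error_curves(
    theory_gain: pd.DataFrame,
    sim_mu: np.ndarray,
    sim_rate: np.ndarray,
    mu_star_value: float,
    guard: float = 1e-6,
    exclude_halfwidth: float = 1.0,
) -> pd.DataFrame:
    """Normalized absolute gain error |G_theory - G_sim| / |G_sim|.

    The simulated gain is the finite difference of ``sim_rate`` on
    ``sim_mu`` (spk/s per bias).  Points within ``exclude_halfwidth`` of
    mu* are masked (both theory branches diverge there), and biases where
    |G_sim| < ``guard`` are excluded from the division.
    """
    sim_mu = np.asarray(sim_mu, dtype=float)
    G_sim = np.gradient(np.asarray(sim_rate, dtype=float), sim_mu)
    G_th = np.interp(sim_mu, theory_gain["mu"], theory_gain["G_tau"])
    err = np.full_like(sim_mu, np.nan)
    ok = (np.abs(G_sim) > guard) & (np.abs(sim_mu - mu_star_value) > exclude_halfwidth)
    err[ok] = np.abs(G_th[ok] - G_sim[ok]) / np.abs(G_sim[ok])
    return pd.DataFrame(
        {"mu": sim_mu, "G_sim": G_sim, "G_theory": G_th, "rel_error": err,
         "branch": np.where(sim_mu < mu_star_value, "low", "high")}
    )


def quadrature_interval(
    Va: float, Vb: float, mu: float, line: AdaptationLine, p: ModelParameters
) -> float:
    """Numeric oracle: Cm * integral of dV/F(V) by adaptive quadrature."""
    val, _ = quad(lambda V: 1.0 / float(flow(V, mu, line, p)), Va, Vb, limit=200,
                  epsabs=1e-12, epsrel=1e-12)
    return p.Cm * val
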