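"""Slow-gating rate theory: closed forms, oracles, scaling laws."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from vnboost import simulate_qif
from vnboost.core import State, ionic_currents
from vnboost.theory import (
    adaptation_line,
    firing_rate,
    flow,
    gain,
    gating_decay,
    interval_I0,
    interval_I1,
    interval_I2,
    interval_Istar,
    mu_bar,
    mu_star,
    quadrature_interval,
    theory_error_curves,
    v_star,
    vbar2,
)


def random_admissible(params, rng):
    """Random (parameter, reset) draw keeping the theory's preconditions."""
    p = params.with_(
        gCa=float(rng.uniform(0.0, 0.4)),
        gKCa=float(rng.uniform(0.2, 1.2)),
        Kd=float(rng.uniform(0.3, 3.0)),
    )
    x_r = float(rng.uniform(0.0, 0.3))
    C_r = float(rng.uniform(0.0, 3.0))
    return p, x_r, C_r


class TestAdaptationLine:
    def test_no_calcium_pathways_no_adaptation(self, params):
        p = params.with_(gCa=0.0, gKCa=0.0)
        line = adaptation_line(0.1, 1.0, p)
        assert line.W0 == 0.0 and line.Wm == 0.0

    def test_pointwise_equals_frozen_currents(self, params, rng):
        """Wbar(V) is exactly I_Ca + I_KCa with gating frozen at resets."""
        for _ in range(100):
            V = float(rng.uniform(-85.0, -25.0))
            x_r = float(rng.uniform(0.0, 1.0))
            C_r = float(rng.uniform(0.0, 5.0))
            line = adaptation_line(x_r, C_r, params)
            s = State(V=V, n=0.0, x=x_r, C=C_r)
            _, _, _, I_Ca, I_KCa = ionic_currents(s, params)
            assert line(V) == pytest.approx(I_Ca + I_KCa, rel=1e-12, abs=1e-12)

    def test_positive_slope_with_active_pathways(self, params):
        assert adaptation_line(0.2, 0.0, params).Wm > 0
        assert adaptation_line(0.0, 1.0, params).Wm > 0


class TestMuStar:
    def test_collapses_to_eps_without_calcium(self, params):
        p = params.with_(gCa=0.0, gKCa=0.0)
        assert mu_star(p, 0.1, 1.0) == pytest.approx(p.eps)

    def test_flow_minimum_equals_eps_at_tangency(self, params_qif02):
        p = params_qif02
        line = adaptation_line(p.x_reset, p.resolved_C_reset(), p)
        ms = mu_star(p)
        res = minimize_scalar(
            lambda V: float(flow(V, ms, line, p)), bounds=(-80.0, -20.0),
            method="bounded",
        )
        assert res.fun == pytest.approx(p.eps, abs=1e-6)

    def test_monotone_in_reset_calcium(self, params):
        """More reset calcium -> stronger KCa adaptation -> higher mu*.

        (The x_r direction is parameter-dependent: raising x_r strengthens
        the depolarizing calcium current, whose reversal lies far above
        threshold, and can lower mu*.)
        """
        assert mu_star(params, 0.1, 1.5) > mu_star(params, 0.1, 0.5)
        # pure-KCa configuration: x_r affects nothing
        p = params.with_(gCa=0.0)
        assert mu_star(p, 0.3, 1.0) == pytest.approx(mu_star(p, 0.05, 1.0))

    def test_mu_bar_is_mu_minus_mu_star_plus_eps(self, params_qif02):
        p = params_qif02
        line = adaptation_line(0.1, 0.4, p)
        ms = mu_star(p, 0.1, 0.4)
        for mu in (2.0, 7.0, 13.0):
            assert mu_bar(mu, line, p) == pytest.approx(mu - ms + p.eps)


class TestClosedFormsAgainstQuadrature:
    def test_i0_matches_quadrature_on_random_draws(self, params, rng):
        checked = 0
        while checked < 100:
            p, x_r, C_r = random_admissible(params, rng)
            line = adaptation_line(x_r, C_r, p)
            ms = mu_star(p, x_r, C_r)
            mu = ms + float(rng.uniform(0.2, 15.0))
            closed = interval_I0(mu, line, p)
            oracle = quadrature_interval(p.Vreset, p.Vth, mu, line, p)
            assert abs(closed - oracle) / oracle < 1e-8
            checked += 1

    def test_i1_matches_quadrature_on_random_draws(self, params, rng):
        checked = 0
        while checked < 100:
            p, x_r, C_r = random_admissible(params, rng)
            line = adaptation_line(x_r, C_r, p)
            ms = mu_star(p, x_r, C_r)
            if ms < 1.0:
                continue
            mu = ms - float(rng.uniform(0.2, min(ms - 0.1, 6.0)))
            try:
                vs = v_star(mu, line, p)
            except ValueError:
                continue
            if vs <= p.Vreset:
                continue
            closed = interval_I1(mu, line, p)
            oracle = quadrature_interval(p.Vreset, vs, mu, line, p)
            assert abs(closed - oracle) / abs(oracle) < 1e-8
            checked += 1

    def test_i2_matches_quadrature_with_starred_line(self, params, rng):
        checked = 0
        while checked < 100:
            p, x_r, C_r = random_admissible(params, rng)
            ms = mu_star(p, x_r, C_r)
            if ms < 1.0:
                continue
            mu = ms - float(rng.uniform(0.2, min(ms - 0.1, 6.0)))
            try:
                t_star, _, _ = interval_Istar(mu, x_r, C_r, p)
                closed, star = interval_I2(mu, x_r, C_r, p, t_star=max(t_star, 0.0))
            except (ValueError, ZeroDivisionError):
                continue
            if mu_bar(mu, star, p) <= 0:
                continue  # floored-quadrature regime, no closed form to check
            oracle = quadrature_interval(p.V2, p.Vth, mu, star, p)
            assert abs(closed - oracle) / oracle < 1e-8
            checked += 1

    def test_plain_qif_limit_recovers_if_interval(self, params):
        """gCa -> 0 gives the bare quadratic model; g2 -> 0 the IF line."""
        p = params.with_(gCa=0.0, gKCa=0.0)
        line = adaptation_line(0.0, 0.0, p)
        assert line.Wm == 0.0
        mu = 10.0
        assert mu_bar(mu, line, p) == pytest.approx(mu)
        assert vbar2(line, p) == pytest.approx(p.V2)
        p_small = p.with_(g2=1e-12)
        line_s = adaptation_line(0.0, 0.0, p_small)
        I_if = (p.Vth - p.Vreset) / mu
        assert interval_I0(mu, line_s, p_small) == pytest.approx(I_if, rel=1e-5)


class TestVStar:
    def test_residual_and_ordering(self, params_qif02, rng):
        p = params_qif02
        line = adaptation_line(p.x_reset, p.resolved_C_reset(), p)
        ms = mu_star(p)
        for _ in range(20):
            mu = ms - float(rng.uniform(0.2, ms - 1.0))
            vs = v_star(mu, line, p)
            assert float(flow(vs, mu, line, p)) == pytest.approx(p.eps, abs=1e-9)
            assert vs < vbar2(line, p)

    def test_tangency_limit_reaches_vertex(self, params_qif02):
        p = params_qif02
        line = adaptation_line(p.x_reset, p.resolved_C_reset(), p)
        ms = mu_star(p)
        assert v_star(ms, line, p) == pytest.approx(vbar2(line, p), abs=1e-6)

    def test_above_tangency_rejected(self, params_qif02):
        p = params_qif02
        line = adaptation_line(p.x_reset, p.resolved_C_reset(), p)
        with pytest.raises(ValueError):
            v_star(mu_star(p) + 1.0, line, p)


class TestGatingDecay:
    def test_initial_conditions(self, params_qif02):
        x_fun, C_fun, C_num = gating_decay(0.1, 0.4, -55.0, params_qif02)
        assert float(x_fun(0.0)) == pytest.approx(0.1)
        assert float(C_fun(0.0)) == pytest.approx(0.4)
        assert float(C_num(0.0)) == pytest.approx(0.4)

    def test_long_time_limits(self, params_qif02):
        from vnboost.core import calcium_steady_state, x_inf

        p = params_qif02
        Vs = -55.0
        x_fun, C_fun, _ = gating_decay(0.1, 0.4, Vs, p)
        vbar_s = 0.5 * (Vs + p.V2)
        assert float(x_fun(1e4)) == pytest.approx(float(x_inf(vbar_s, p)))
        x_inf_s = float(x_inf(vbar_s, p))
        assert float(C_fun(1e4)) == pytest.approx(
            calcium_steady_state(Vs, x_inf_s, p)
        )

    def test_numeric_variant_captures_nonmonotone_calcium(self, params_qif02):
        """Calcium first rises (x still high) then decays; the fixed-target
        exponential misses the transient rise."""
        p = params_qif02
        x_r, C_r = 0.35, 0.6
        Vs = -56.0
        _, C_fun, C_num = gating_decay(x_r, C_r, Vs, p)
        t = np.linspace(0.0, 300.0, 3000)
        numeric = C_num(t)
        analytic = C_fun(t)
        assert np.max(numeric[t < 40]) > numeric[0] + 1e-3   # transient rise
        assert np.all(np.diff(analytic) < 1e-12)             # pure decay toward target
        # both relax to the same equilibrium C_inf(V*, x_inf(Vbar*))
        assert numeric[-1] == pytest.approx(analytic[-1], rel=0.02)


class TestIstar:
    def test_a_is_initial_adaptation_current(self, params_qif02, rng):
        p = params_qif02
        ms = mu_star(p, 0.1, 0.4)
        mu = ms - 2.0
        _, A, B = interval_Istar(mu, 0.1, 0.4, p)
        line = adaptation_line(0.1, 0.4, p)
        vs = v_star(mu, line, p)
        assert A == pytest.approx(float(line(vs)))
        assert B < 0  # adaptation decays

    def test_nonnegative_in_valid_regime(self, params_qif02):
        p = params_qif02
        x_r, C_r = p.x_reset, p.resolved_C_reset()
        ms = mu_star(p, x_r, C_r)
        for mu in np.linspace(1.0, ms - 0.3, 12):
            I, A, B = interval_Istar(mu, x_r, C_r, p)
            assert I >= -1e-9

    def test_interval_is_distance_over_velocity(self, params_qif02):
        p = params_qif02
        mu = mu_star(p, 0.1, 0.4) - 2.0
        I, A, B = interval_Istar(mu, 0.1, 0.4, p)
        assert I == pytest.approx((mu - p.eps - A) / B)


class TestI2:
    def test_starred_line_anchored_at_parabola_bottom(self, params_qif02):
        p = params_qif02
        mu = mu_star(p, p.x_reset, p.resolved_C_reset()) - 2.0
        _, star = interval_I2(mu, p.x_reset, p.resolved_C_reset(), p)
        assert float(star(p.V2)) == pytest.approx(mu - p.eps)

    def test_no_decay_consistency_with_case1_integral(self, params):
        """With t* = 0 and Vreset = V2, I2 equals the I0-type integral of
        the original line over [V2, Vth]."""
        p = params.with_(gCa=0.05, gKCa=0.4, Kd=1.0)
        x_r, C_r = 0.05, 0.2
        line = adaptation_line(x_r, C_r, p)
        ms = mu_star(p, x_r, C_r)
        mu = ms - 0.0001  # essentially at tangency: starred == original line
        I2, star = interval_I2(mu, x_r, C_r, p, t_star=0.0)
        # anchoring fixes Wbar*(V2) = mu - eps; at t*=0 the slope is unchanged
        assert star.Wm == pytest.approx(line.Wm)
        oracle = quadrature_interval(p.V2, p.Vth, mu, star, p)
        assert I2 == pytest.approx(oracle, rel=1e-8)


class TestRateAndGain:
    def test_rate_bounds(self, params_qif02):
        res = firing_rate(np.arange(1.0, 20.1, 0.5), params_qif02)
        R = res.rate(True)
        ok = np.isfinite(R)
        assert np.all(R[ok] >= 0.0)
        assert np.all(R[ok] <= 1000.0 / params_qif02.tau_r + 1e-9)

    def test_high_branch_matches_fixed_reset_simulation(self, params_qif02):
        p = params_qif02.with_(reset_mode="fixed_reset")
        res = firing_rate(np.array([10.0, 13.0, 16.0]), p)
        for mu, r_theory in zip(res.mu, res.rate(True)):
            _, seq = simulate_qif(p, mu, 3000.0)
            assert abs(r_theory - seq.mean_rate) / seq.mean_rate < 0.03

    def test_branch_discontinuity_reported_not_hidden(self, params_qif02):
        p = params_qif02
        ms = mu_star(p)
        res = firing_rate(np.array([ms - 0.05, ms + 0.05]), p)
        R = res.rate(True)
        assert np.all(np.isfinite(R))
        assert R[1] != R[0]

    def test_interval_dominance_at_low_bias(self, params_qif02):
        """I* dwarfs I1 and I2 well below the tangency bias."""
        res = firing_rate(np.arange(1.0, 4.1, 0.5), params_qif02)
        t = res.table
        assert (t.Istar > t.I1).all() and (t.Istar > t.I2).all()

    def test_gain_peak_at_mu_star(self, params_qif02):
        p = params_qif02.with_(reset_mode="fixed_reset")
        mu_grid = np.arange(0.5, 16.01, 0.5)
        rates = []
        for mu in mu_grid:
            _, seq = simulate_qif(p, mu, 2500.0)
            rates.append(seq.mean_rate)
        g_sim = np.gradient(np.array(rates), mu_grid)
        peak = mu_grid[int(np.argmax(g_sim))]
        assert abs(peak - mu_star(p)) <= 0.5 + 1e-9

    def test_gain_scaling_laws(self, params_qif02):
        """G- ~ (mu* - mu)^-2 below, G+ ~ mu_bar^-1/2 above."""
        p = params_qif02
        res = firing_rate(np.arange(0.5, 20.01, 0.1), p)
        g = gain(res, p)
        ms = res.mu_star
        below = (g.mu > ms - 4.0) & (g.mu < ms - 0.5) & np.isfinite(g.G_minus)
        s_below = np.polyfit(np.log(ms - g.mu[below]), np.log(g.G_minus[below]), 1)[0]
        assert s_below == pytest.approx(-2.0, abs=0.2)
        line = adaptation_line(res.x_r, res.C_r, p)
        mub = np.array([mu_bar(m, line, p) for m in g.mu])
        above = mub > 0.2
        s_above = np.polyfit(np.log(mub[above]), np.log(g.G_plus[above]), 1)[0]
        assert s_above == pytest.approx(-0.5, abs=0.05)

    def test_gplus_consistent_with_finite_difference_above_tangency(self, params_qif02):
        """The 1/sqrt(mu_bar) gain form is asymptotic to the divergence
        side (arctan span -> pi as mu_bar -> 0+), so it is checked just
        above mu* rather than in the deep linear regime."""
        p = params_qif02
        ms = mu_star(p)
        res = firing_rate(np.arange(ms + 0.3, ms + 3.01, 0.1), p)
        g = gain(res, p)
        # tracks the finite-difference gain up to a slowly varying factor
        ratio = (g.G_0 / g.G_plus).to_numpy()
        ratio = ratio[np.isfinite(ratio)]
        assert ratio.max() / ratio.min() < 1.6
        assert np.nanmedian(np.abs(g.G_plus - g.G_0) / g.G_0) < 0.35

    def test_error_curves_zero_for_identical_inputs(self, params_qif02):
        p = params_qif02
        res = firing_rate(np.arange(8.0, 16.01, 0.5), p)
        g = gain(res, p)
        err = theory_error_curves(g, res.mu, res.rate(True), res.mu_star)
        finite = err.rel_error.dropna()
        assert (finite < 1e-9).all()

    def test_error_guarded_near_mu_star_and_zero_gain(self, params_qif02):
        p = params_qif02
        res = firing_rate(np.arange(1.0, 16.01, 0.5), p)
        g = gain(res, p)
        sim_rate = np.where(res.mu < 3, 0.0, res.rate(True))  # fake dead zone
        err = theory_error_curves(g, res.mu, sim_rate, res.mu_star)
        near = np.abs(err.mu - res.mu_star) < 1.0
        assert err.rel_error[near].isna().all()
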