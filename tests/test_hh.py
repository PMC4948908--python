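"""Conductance-based model: integration, spike detection, classification."""

import numpy as np
import pytest

from vnboost import State, hh_rhs, simulate_hh, hh_spike_times
from vnboost.core import n_inf
from vnboost.fixed_points import find_fixed_points
from vnboost.hh import (
    SimulationTrace,
    classify_firing_pattern,
    detect_ahp,
    detect_spikes,
    distinct_isi_values,
    fi_curve,
    isi_return_map,
)


class TestRhs:
    def test_vanishes_at_fixed_point(self, params):
        fp = find_fixed_points("hh", 3.0, params)[0]
        d = hh_rhs(State(fp.V, fp.n, fp.x, fp.C), 3.0, params)
        assert np.all(np.abs(d) < 1e-9)

    def test_gating_equilibrium_stops_n(self, params):
        s = State(V=-48.0, n=float(n_inf(-48.0, params)), x=0.2, C=1.0)
        d = hh_rhs(s, 5.0, params)
        assert d[1] == pytest.approx(0.0, abs=1e-14)

    def test_no_calcium_pathway_freezes_c(self, params):
        p = params.with_(gCa=0.0)
        d = hh_rhs(State(V=-40.0, n=0.2, x=0.3, C=0.0), 5.0, p)
        assert d[3] == 0.0


class TestSimulate:
    def test_deterministic_bit_identical(self, params):
        a = simulate_hh(params, 19.0, 50.0, record_stride=10)
        b = simulate_hh(params, 19.0, 50.0, record_stride=10)
        assert np.array_equal(a.states, b.states)

    def test_subthreshold_relaxes_to_stable_fixed_point(self, params):
        tr = simulate_hh(params, 3.0, 1500.0, record_stride=100)
        fp = find_fixed_points("hh", 3.0, params)[0]
        assert fp.stable
        assert tr.states[-1, 0] == pytest.approx(fp.V, abs=1e-3)

    def test_halving_dt_moves_spike_times_less_than_dt(self, params):
        s1 = hh_spike_times(params, 22.5, 400.0, dt=0.02)
        s2 = hh_spike_times(params, 22.5, 400.0, dt=0.01)
        n = min(len(s1), len(s2))
        assert n > 10
        # per-spike agreement before phase drift accumulates
        early = slice(0, np.searchsorted(s2[:n], 100.0))
        assert np.max(np.abs(s1[:n][early] - s2[:n][early])) < 0.02

    def test_fixed_and_adaptive_integrators_agree_on_isis(self, params):
        spikes_fixed = hh_spike_times(params, 22.5, 300.0)
        tr = simulate_hh(params, 22.5, 300.0, dt=0.01, integrator="adaptive")
        spikes_adaptive = detect_spikes(tr)
        n = min(len(spikes_fixed), len(spikes_adaptive))
        isi_f = np.diff(spikes_fixed[:n])
        isi_a = np.diff(spikes_adaptive[:n])
        assert np.all(np.abs(isi_f - isi_a) / isi_a < 1e-3)

    def test_invalid_durations_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_hh(params, 5.0, -1.0)


class TestDetectSpikes:
    def test_constant_subthreshold_trace_empty(self):
        t = np.arange(0, 100, 0.1)
        tr = SimulationTrace(t, np.full((len(t), 4), -60.0), 0.0, 0.1, "synthetic")
        assert len(detect_spikes(tr)) == 0

    def test_sawtooth_crossings_counted_and_interpolated(self):
        t = np.arange(0.0, 50.0, 0.01)
        V = -60.0 + 80.0 * ((t / 10.0) % 1.0)  # crosses 0 once per 10 ms
        tr = SimulationTrace(t, np.column_stack([V] * 4), 0.0, 0.01, "synthetic")
        s = detect_spikes(tr, v_detect=0.0)
        assert len(s) == 5
        # upward crossing of 0 happens 7.5 ms into each period
        assert np.allclose(s, 7.5 + 10.0 * np.arange(5), atol=0.02)

    def test_guard_merges_chattering_crossings(self):
        t = np.arange(0.0, 20.0, 0.01)
        V = 5.0 * np.sin(2 * np.pi * t / 0.5) - 1.0  # crosses 0 every 0.5 ms
        tr = SimulationTrace(t, np.column_stack([V] * 4), 0.0, 0.01, "synthetic")
        assert len(detect_spikes(tr, guard=2.0)) < len(detect_spikes(tr, guard=0.0))


class TestClassification:
    @pytest.mark.parametrize(
        "isis,expect",
        [
            ([5.0] * 30, ("tonic_1spk", 1)),
            ([2.0, 9.0] * 15, ("burst_2", 2)),
            ([2.0, 2.5, 9.0] * 12, ("burst_3", 3)),
        ],
    )
    def test_periodic_sequences(self, isis, expect):
        assert classify_firing_pattern(np.array(isis), n_discard=4) == expect

    def test_aperiodic_sequence(self, rng):
        isis = rng.uniform(2.0, 20.0, 60)
        pattern, period = classify_firing_pattern(isis)
        assert pattern == "aperiodic" and period == 0

    def test_too_few_isis_is_quiescent(self):
        assert classify_firing_pattern(np.array([5.0, 5.0]))[0] == "quiescent"

    def test_transient_discard_matters(self):
        isis = np.array([3.0, 17.0, 8.0] + [5.0] * 30)
        assert classify_firing_pattern(isis, n_discard=3) == ("tonic_1spk", 1)

    def test_distinct_isi_clustering(self):
        vals = distinct_isi_values(np.array([5.0, 5.0004, 9.0, 9.0001, 20.0]))
        assert len(vals) == 3


class TestAhpDetection:
    @staticmethod
    def _trace_from_segment(seg, dt=0.05):
        # wrap a constructed interspike voltage segment between two spikes
        spike = np.concatenate([np.linspace(-50, 30, 8), np.linspace(30, -70, 12)])
        V = np.concatenate([spike, seg, spike])
        t = np.arange(len(V)) * dt
        return SimulationTrace(t, np.column_stack([V] * 4), 0.0, dt, "synthetic"), t

    def test_monotone_rise_has_no_ahp(self):
        seg = np.linspace(-70.0, -45.0, 400)
        tr, t = self._trace_from_segment(seg)
        spikes = detect_spikes(tr, v_detect=0.0, guard=1.0)
        flags = detect_ahp(tr, spikes, refractory_min=1.0)
        assert list(flags) == [False]

    def test_double_reversal_is_bidirectional(self):
        up1 = np.linspace(-70.0, -55.0, 150)
        down = np.linspace(-55.0, -65.0, 150)
        up2 = np.linspace(-65.0, -45.0, 150)
        tr, t = self._trace_from_segment(np.concatenate([up1, down, up2]))
        spikes = detect_spikes(tr, v_detect=0.0, guard=1.0)
        flags = detect_ahp(tr, spikes, refractory_min=1.0)
        assert list(flags) == [True]

    def test_hh_low_bias_has_ahp_high_bias_does_not(self, params):
        """Bidirectional AHP accompanies the low-gain region only."""
        lo = simulate_hh(params, 16.0, 1200.0, record_stride=5)
        hi = simulate_hh(params, 24.0, 400.0, record_stride=5)
        s_lo, s_hi = detect_spikes(lo), detect_spikes(hi)
        assert detect_ahp(lo, s_lo[3:]).all()
        assert not detect_ahp(hi, s_hi[10:]).any()


class TestFICurveAndReturnMap:
    def test_quiescent_below_onset_and_single_valued_without_calcium(self, params):
        p = params.with_(gCa=0.0)
        df = fi_curve(p, np.array([0.0, 6.0, 12.0]), duration=1500.0)
        assert df.loc[df.mu == 0.0, "rate_mean"].item() == 0.0
        spiking = df[df.rate_mean > 0]
        assert (spiking.n_distinct == 1).all()

    def test_unsorted_grid_rejected(self, params):
        with pytest.raises(ValueError):
            fi_curve(params, np.array([5.0, 1.0]))

    def test_gain_higher_above_burst_window_than_below(self, params):
        """The f-I slope in the high-bias region exceeds the low-bias one
        (boosting) for the strong-calcium configuration."""

        def rate(mu):
            spikes = hh_spike_times(params, mu, 1500.0)
            isis = np.diff(spikes)[20:]
            return 1000.0 / isis.mean()

        low_gain = (rate(18.0) - rate(14.0)) / 4.0
        high_gain = (rate(28.0) - rate(24.0)) / 4.0
        assert high_gain > 2.0 * low_gain

    def test_return_map_tonic_on_diagonal(self):
        pairs, mean = isi_return_map(np.full(10, 7.0))
        assert np.allclose(pairs[:, 0], pairs[:, 1])
        assert mean == pytest.approx(7.0)

    def test_return_map_burst2_alternates(self):
        pairs, _ = isi_return_map(np.array([2.0, 9.0] * 10))
        off = pairs[pairs[:, 0] != pairs[:, 1]]
        assert len(off) == len(pairs)

    def test_return_map_burst3_three_point_cycle(self):
        pairs, _ = isi_return_map(np.array([2.0, 2.5, 9.0] * 8))
        uniq = {tuple(np.round(r, 6)) for r in pairs}
        assert len(uniq) == 3

    def test_return_map_needs_two_isis(self):
        with pytest.raises(ValueError):
            isi_return_map(np.array([5.0]))
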