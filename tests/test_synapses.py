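"""Receptor kinetics, depression, NMDA gate, GABA-B cascade, minis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from spindlenet import synapses as syn


class TestSynapticCurrent:
    def test_zero_at_reversal(self):
        st = syn.SynapseState(o=0.7)
        kin = syn.RECEPTOR_DEFAULTS["AMPA"]
        assert syn.synaptic_current(0.3, st, kin.e_syn, kin) == 0.0

    def test_zero_when_closed(self):
        st = syn.SynapseState(o=0.0)
        kin = syn.RECEPTOR_DEFAULTS["GABA_A"]
        assert syn.synaptic_current(0.3, st, -55.0, kin) == 0.0

    def test_arithmetic(self):
        # g*D*O*(V-E): 0.15 * 1 * 0.5 * (-70 - 0) = -5.25 (inward, since
        # outward current is positive)
        st = syn.SynapseState(o=0.5, d=1.0)
        kin = syn.RECEPTOR_DEFAULTS["AMPA"]
        i = syn.synaptic_current(0.15, st, -70.0, kin)
        assert i == pytest.approx(-5.25)

    def test_depression_scales_current(self):
        kin = syn.RECEPTOR_DEFAULTS["AMPA"]
        full = syn.synaptic_current(0.15, syn.SynapseState(o=0.5, d=1.0), -70, kin)
        half = syn.synaptic_current(0.15, syn.SynapseState(o=0.5, d=0.5), -70, kin)
        assert half == pytest.approx(0.5 * full)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            syn.synaptic_current(-0.1, syn.SynapseState(), -70,
                                 syn.RECEPTOR_DEFAULTS["AMPA"])


class TestDepression:
    def test_immediate_reuse(self):
        # zero interval from a fully recovered synapse consumes U = 0.2
        assert syn.depression_update(1.0, 0.0, 0.0) == pytest.approx(0.8)

    def test_hand_evaluated_value(self):
        # D_i = 0.8, interval = tau: 1 - (1 - 0.64) e^{-1}
        expected = 1.0 - (1.0 - 0.8 * 0.8) * math.exp(-1.0)
        assert syn.depression_update(0.8, 0.0, 500.0) == pytest.approx(expected)

    def test_full_recovery(self):
        assert syn.depression_update(0.3, 0.0, 1e7) == pytest.approx(1.0)

    def test_rejects_time_reversal(self):
        with pytest.raises(ValueError):
            syn.depression_update(1.0, 100.0, 50.0)

    def test_periodic_fixed_point_matches_closed_form(self):
        # D* = (1 - e^{-D/tau}) / (1 - (1-U) e^{-D/tau}) under periodic drive
        u, tau = 0.2, 500.0
        for interval in (50.0, 120.0, 500.0, 2000.0):
            d, t = 1.0, 0.0
            for _ in range(2000):
                d = syn.depression_update(d, t, t + interval, u, tau)
                t += interval
            e = math.exp(-interval / tau)
            closed = (1.0 - e) / (1.0 - (1.0 - u) * e)
            assert abs(d - closed) < 1e-6

    @given(hst.lists(hst.floats(0.1, 1000.0), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_stays_in_unit_interval(self, intervals):
        d, t = 1.0, 0.0
        for dt in intervals:
            d = syn.depression_update(d, t, t + dt)
            t += dt
            assert 0.0 <= d <= 1.0


class TestNmdaGate:
    def test_midpoint(self):
        assert syn.nmda_voltage_gate(-25.0) == pytest.approx(0.5)

    def test_saturation(self):
        assert syn.nmda_voltage_gate(500.0) == pytest.approx(1.0, abs=1e-6)
        assert syn.nmda_voltage_gate(-500.0) == pytest.approx(0.0, abs=1e-6)

    def test_direct_value(self):
        assert syn.nmda_voltage_gate(-12.5) == pytest.approx(1 / (1 + math.exp(-1)))

    def test_monotone_in_depolarization(self):
        v = np.linspace(-90, 10, 50)
        g = syn.nmda_voltage_gate(v)
        assert np.all(np.diff(g) > 0)


class TestGabaB:
    def test_silent_without_transmitter(self):
        st = syn.SynapseState()
        for _ in range(1000):
            f = syn.gabab_update(st, 0.0, 1.0)
        assert f == 0.0

    def _response(self, spike_times, total=800.0, dt=0.1, pulse=1.0):
        st = syn.SynapseState()
        factors = []
        n = int(total / dt)
        for k in range(n):
            t = k * dt
            on = any(ts <= t < ts + pulse for ts in spike_times)
            factors.append(syn.gabab_update(st, 0.5 if on else 0.0, dt))
        return np.asarray(factors)

    def test_peak_delayed_vs_gaba_a(self):
        # GABA-A response to the same spike peaks within ~1 ms of offset;
        # the G-protein cascade peaks > 50 ms later
        f = self._response([10.0])
        t_peak = np.argmax(f) * 0.1
        assert t_peak - 10.0 >= 50.0

    def test_temporal_summation(self):
        single = self._response([10.0]).max()
        train = self._response([10.0 + 100.0 * k for k in range(6)]).max()
        assert train > single


class TestMinis:
    def test_rate_zero_at_spike(self):
        assert syn.mini_rate(0.0, 0.0) == 0.0

    def test_rate_asymptote(self):
        assert syn.mini_rate(1e9, 0.0) == pytest.approx(1.0 / 250.0)

    def test_rate_at_400ms(self):
        expected = (2.0 / (1.0 + math.exp(-1.0)) - 1.0) / 250.0
        assert syn.mini_rate(400.0, 0.0) == pytest.approx(expected)

    def test_sampler_deterministic(self):
        a = syn.sample_mini_times(0.0, 5000.0, seed=7)
        b = syn.sample_mini_times(0.0, 5000.0, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_sampler_rejects_bad_horizon(self):
        with pytest.raises(ValueError):
            syn.sample_mini_times(0.0, -1.0, seed=0)

    def test_near_zero_rate_window(self):
        # immediately after a presynaptic spike the rate is ~0
        counts = [len(syn.sample_mini_times(0.0, 20.0, seed=s)) for s in range(200)]
        assert np.mean(counts) < 0.05

    def test_empirical_rate_matches_integral(self):
        # Monte-Carlo mean event count vs numeric integral of the rate
        horizon = 3000.0
        tt = np.linspace(0, horizon, 30001)
        expected = np.trapezoid(syn.mini_rate(tt, 0.0), tt)
        rng = np.random.default_rng(123)
        counts = [
            len(syn.sample_mini_times(0.0, horizon, seed=rng))
            for _ in range(1000)
        ]
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3.0 * se

    def test_time_rescaling_ks(self):
        # rescaled inter-event intervals of the inhomogeneous process are
        # Exp(1); KS on 100 pooled trains should not reject
        from scipy import stats as sps

        tt = np.linspace(0, 8000.0, 80001)
        lam = np.concatenate([[0.0], np.cumsum(
            (syn.mini_rate(tt[1:], 0.0) + syn.mini_rate(tt[:-1], 0.0)) / 2
            * np.diff(tt))])
        rescaled = []
        for s in range(100):
            ev = syn.sample_mini_times(0.0, 8000.0, seed=1000 + s)
            lam_ev = np.interp(ev, tt, lam)
            rescaled.extend(np.diff(lam_ev))
        res = sps.kstest(rescaled, "expon")
        assert res.pvalue > 0.01
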