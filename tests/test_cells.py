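"""Single-cell dynamics: rest, rebound bursts, firing phenotypes, accuracy."""

import numpy as np
import pytest

from spindlenet import cells
from spindlenet.cells import (
    CompartmentState,
    CorticalCellParams,
    ThalamicCellParams,
    cortical_currents,
    cortical_initial_state,
    integrate_cortical,
    integrate_thalamic,
    resting_state,
    thalamic_currents,
    thalamic_derivatives,
    thalamic_initial_state,
)


def spike_times(t, v, thresh=-20.0):
    return t[np.flatnonzero((v[:-1] <= thresh) & (v[1:] > thresh))]


@pytest.fixture(scope="module")
def tc_rest():
    return resting_state(ThalamicCellParams.tc(), relax_ms=3000, dt=0.05)


class TestThalamic:
    def test_leak_only_rest_is_e_leak(self):
        p = ThalamicCellParams.tc(g_na=0, g_k=0, g_t=0, g_h=0, g_kl=0)
        st = thalamic_initial_state(p, v=p.e_leak)
        dv, dg, dca = thalamic_derivatives(st, p)
        assert dv == pytest.approx(0.0, abs=1e-12)
        st2 = resting_state(p, relax_ms=1000, dt=0.05)
        assert st2.v == pytest.approx(p.e_leak, abs=1e-6)

    def test_kl_current_zero_at_reversal(self):
        p = ThalamicCellParams.tc()
        st = thalamic_initial_state(p, v=-95.0)
        cur = thalamic_currents(st, p)
        assert cur["kl"] == pytest.approx(0.0, abs=1e-12)

    def test_tc_rest_in_physiological_range(self, tc_rest):
        # relaxation integration is its own oracle: stable hyperpolarized
        # rest set by the g_KL / I_h balance
        assert -80.0 <= tc_rest.v <= -55.0

    def test_resting_state_deterministic(self):
        p = ThalamicCellParams.re()
        a = resting_state(p, relax_ms=1000, dt=0.05)
        b = resting_state(p, relax_ms=1000, dt=0.05)
        assert a.v == b.v
        assert a.gating == b.gating

    def test_tc_rebound_burst(self, tc_rest):
        # release from a hyperpolarizing step rides a low-threshold Ca spike
        p = ThalamicCellParams.tc()

        def inj(t):
            return 0.8 if t < 300 else 0.0  # outward, hyperpolarizing

        t, v, _ = integrate_thalamic(p, 900, dt=0.025, i_inject=inj,
                                     state=tc_rest, record_every=4)
        rebound = spike_times(t, v)
        rebound = rebound[rebound > 300]
        assert len(rebound) >= 2
        assert rebound.max() - rebound.min() < 100.0  # a burst, not tonic firing

    def test_no_spontaneous_firing_at_rest(self):
        for p in (ThalamicCellParams.tc(), ThalamicCellParams.re()):
            t, v, _ = integrate_thalamic(p, 3000, dt=0.05, record_every=20)
            assert len(spike_times(t[t > 1500], v[t > 1500])) == 0

    def test_nonfinite_state_rejected(self):
        p = ThalamicCellParams.tc()
        st = thalamic_initial_state(p)
        st.v = float("nan")
        with pytest.raises(ValueError, match="not finite"):
            thalamic_derivatives(st, p)

    def test_gating_out_of_bounds_rejected(self):
        p = ThalamicCellParams.tc()
        st = thalamic_initial_state(p)
        st.gating["m"] = 1.5
        with pytest.raises(ValueError, match="'m'"):
            thalamic_derivatives(st, p)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            ThalamicCellParams.tc(g_t=-1.0)

    def test_dt_halving_consistency(self):
        # 1 s of subthreshold dynamics changes by < 1 mV RMS when dt halves.
        # The drive is a monotonically growing hyperpolarization: any
        # release would fire a rebound burst whose sub-ms timing jitter
        # dominates a trace metric for every fixed-step integrator.
        p = ThalamicCellParams.tc()

        def inj(t):
            return 0.5 * np.sin(np.pi * t / 2000.0) ** 2

        traces = {}
        for dt, every in ((0.025, 40), (0.0125, 80)):
            rest = resting_state(p, relax_ms=3000, dt=dt)
            _, v, _ = integrate_thalamic(p, 1000, dt=dt, i_inject=inj,
                                         state=rest, record_every=every)
            traces[dt] = v
        n = min(len(traces[0.025]), len(traces[0.0125]))
        rms = np.sqrt(np.mean((traces[0.025][:n] - traces[0.0125][:n]) ** 2))
        assert rms < 1.0


class TestCortical:
    def test_axial_conductance_value(self):
        # g_c = 1/r with r = 10 MOhm
        assert CorticalCellParams.py().g_c == pytest.approx(0.1)

    def test_axial_current_antisymmetric_after_area_scaling(self):
        p = CorticalCellParams.py()
        soma, dend = cortical_initial_state(p, v=-60.0)
        dend.v = -50.0
        i_s, i_d = cortical_currents(soma, dend, p)
        assert i_s["axial"] * p.s_soma == pytest.approx(
            -i_d["axial"] * p.s_dend)

    def test_equal_potentials_zero_axial(self):
        p = CorticalCellParams.py()
        soma, dend = cortical_initial_state(p, v=-65.0)
        i_s, i_d = cortical_currents(soma, dend, p)
        assert i_s["axial"] == 0.0
        assert i_d["axial"] == 0.0

    def test_interneuron_has_no_persistent_sodium(self):
        p = CorticalCellParams.inh()
        assert p.g_nap_soma == 0.0
        assert p.g_nap_dend == 0.0

    def test_rest_in_physiological_range(self):
        for p in (CorticalCellParams.py(), CorticalCellParams.inh()):
            soma, dend = resting_state(p, relax_ms=2000, dt=0.05)
            assert -90.0 < soma.v < -55.0

    def test_py_regular_vs_in_fast_spiking(self):
        # same dendritic drive: the interneuron (small area ratio) fires
        # much faster than the strongly adapting pyramid
        rates = {}
        for name, p in (("PY", CorticalCellParams.py()),
                        ("IN", CorticalCellParams.inh())):
            pair = resting_state(p, relax_ms=1500, dt=0.05)

            def inj(t):
                return -1.5 if 100 < t < 1000 else 0.0

            t, vs, _, _ = integrate_cortical(p, 1100, dt=0.025,
                                             i_inject_dend=inj, state=pair,
                                             record_every=4)
            rates[name] = len(spike_times(t, vs))
        assert rates["PY"] >= 1
        assert rates["IN"] >= 5 * rates["PY"]

    def test_gating_stays_bounded_under_drive(self):
        p = CorticalCellParams.py()
        pair = resting_state(p, relax_ms=1000, dt=0.05)

        def inj(t):
            return -3.0 if t > 50 else 0.0

        _, _, _, (soma, dend) = integrate_cortical(p, 800, dt=0.025,
                                                   i_inject_dend=inj,
                                                   state=pair, record_every=100)
        for st in (soma, dend):
            st.validate()  # raises if any gate left [0, 1] or V diverged
            assert -120.0 < st.v < 60.0
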