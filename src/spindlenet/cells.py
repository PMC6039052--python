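"""Single-cell Hodgkin-Huxley models: thalamic TC/RE and cortical PY/IN.

Thalamic relay (TC) and reticular (RE) cells are single-compartment:

    Cm dV/dt = -g_leak (V - E_leak) - I_int - I_syn

with I_int = I_Na + I_K + I_T + I_KL (TC cells additionally carry the
anomalous rectifier I_h).  The low-threshold Ca current I_T endows both
cell types with post-inhibitory rebound bursts, the engine of the TC-RE
spindle loop; the Ca-regulated I_h in TC cells slowly depolarizes the cell
over a spindle and contributes to its termination (waxing-and-waning).

Cortical pyramidal (PY) and inhibitory (IN) cells are two-compartment
(axo-somatic + dendritic) models coupled by an axial conductance
g_c = 1/r with r = 10 MOhm.  The dendrite/soma area ratio R sets the
firing pattern: R = 165 gives a regular-spiking PY, R = 50 a fast-spiking
IN.  The axo-somatic compartment carries dense I_Na and delayed-rectifier
I_K; the dendrite carries leak, K-leak, I_Na, I_Na(p) (PY only), I_Km,
I_KCa and I_HVA, plus all synaptic input.

All densities are mS/cm^2, potentials mV, time ms, Ca mM.  Currents are
outward-positive.  The module doubles as the reference implementation
against which the vectorized network kernel is cross-checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _rates as R

__all__ = [
    "CompartmentState",
    "ThalamicCellParams",
    "CorticalCellParams",
    "thalamic_derivatives",
    "cortical_derivatives",
    "integrate_thalamic",
    "integrate_cortical",
    "resting_state",
    "E_NA",
    "E_K_THAL",
    "E_K_CORT",
    "E_H",
]

E_NA = 50.0
E_K_THAL = -95.0
E_K_CORT = -90.0
E_H = -40.0
E_KL = -95.0

THAL_GATES = ("m", "h", "n", "mt", "ht", "o1", "p1", "o2")
SOMA_GATES = ("m", "h", "n", "mnap")
DEND_GATES = ("m", "h", "mnap", "mkm", "mkca", "mhva", "hhva")


@dataclass
class CompartmentState:
    """Voltage, gating variables and intracellular Ca of one compartment."""

    v: float
    gating: dict[str, float] = field(default_factory=dict)
    ca: float = R.CA_INF

    def validate(self) -> None:
        if not math.isfinite(self.v):
            raise ValueError("membrane potential is not finite")
        if self.ca < 0:
            raise ValueError(f"negative calcium concentration {self.ca}")
        for name, x in self.gating.items():
            if not math.isfinite(x):
                raise ValueError(f"gating variable {name!r} is not finite")
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gating variable {name!r}={x} outside [0, 1]")

    def copy(self) -> "CompartmentState":
        return CompartmentState(self.v, dict(self.gating), self.ca)


@dataclass(frozen=True)
class ThalamicCellParams:
    """Parameters of a single-compartment thalamic cell.

    Defaults are the published sleep-state values: TC cells with
    g_leak = 0.01 mS/cm^2 (E_leak = -70 mV), g_KL = 0.03, g_Na = 90,
    g_K = 10, g_T = 2.2, g_h = 0.017; RE cells with g_leak = 0.05
    (E_leak = -77 mV), g_Na = 100, g_K = 10, g_T = 2.3 and no I_h.
    Two RE leak values are in circulation for this model family (0.05 and
    0.005 mS/cm^2); 0.05 is the default because it leaves an isolated RE
    cell quiescent at rest while still bursting on depolarization, whereas
    0.005 turns it into a spontaneous oscillator.  Both are config choices.
    """

    cell_class: str = "TC"
    cm: float = 1.0          # uF/cm^2
    g_leak: float = 0.01     # mS/cm^2
    e_leak: float = -70.0
    g_kl: float = 0.03
    e_kl: float = E_KL
    g_na: float = 90.0
    g_k: float = 10.0
    g_t: float = 2.2
    g_h: float = 0.017
    area: float = 2.9e-4     # cm^2
    ca_tau: float = 5.0      # ms, Ca-pool decay

    def __post_init__(self):
        for name in ("g_leak", "g_kl", "g_na", "g_k", "g_t", "g_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def tc(cls, **kw) -> "ThalamicCellParams":
        return cls(**kw)

    @classmethod
    def re(cls, **kw) -> "ThalamicCellParams":
        defaults = dict(
            cell_class="RE", g_leak=0.05, e_leak=-77.0, g_kl=0.005,
            g_na=100.0, g_k=10.0, g_t=2.3, g_h=0.0, area=1.43e-4,
        )
        defaults.update(kw)
        return cls(**defaults)

    @property
    def is_tc(self) -> bool:
        return self.cell_class == "TC"


@dataclass(frozen=True)
class CorticalCellParams:
    """Parameters of a two-compartment cortical cell.

    ``rho`` is the dendrite/soma area ratio (165 for PY, 50 for IN);
    ``r_axial`` the inter-compartment resistance in MOhm (g_c = 1/r).
    Interneurons carry no persistent sodium current.
    """

    cell_class: str = "PY"
    rho: float = 165.0
    r_axial: float = 10.0        # MOhm
    s_soma: float = 1.0e-6       # cm^2
    cm_dend: float = 0.75        # uF/cm^2
    cm_soma: float = 0.75
    g_na_soma: float = 3000.0
    g_k_soma: float = 200.0
    g_nap_soma: float = 0.07
    g_na_dend: float = 1.5
    g_l_dend: float = 0.033
    g_kl_dend: float = 0.0025
    g_hva_dend: float = 0.01
    g_kca_dend: float = 0.3
    g_km_dend: float = 0.01
    g_nap_dend: float = 0.07
    e_leak: float = -68.0
    e_kl: float = E_KL
    ca_tau: float = 165.0

    @classmethod
    def py(cls, **kw) -> "CorticalCellParams":
        return cls(**kw)

    @classmethod
    def inh(cls, **kw) -> "CorticalCellParams":
        defaults = dict(cell_class="IN", rho=50.0, g_nap_soma=0.0,
                        g_nap_dend=0.0, e_leak=-75.0)
        defaults.update(kw)
        return cls(**defaults)

    @property
    def s_dend(self) -> float:
        return self.s_soma * self.rho

    @property
    def g_c(self) -> float:
        """Axial conductance in uS (1/r with r in MOhm)."""
        return 1.0 / self.r_axial

    @property
    def g_c_soma(self) -> float:
        """Axial conductance density seen by the soma (mS/cm^2)."""
        return self.g_c * 1e-3 / self.s_soma  # uS -> mS, then per cm^2

    @property
    def g_c_dend(self) -> float:
        return self.g_c_soma / self.rho


def _f(x) -> float:
    return float(np.asarray(x))


# ---------------------------------------------------------------------------
# derivatives (reference implementation)
# ---------------------------------------------------------------------------

def thalamic_initial_state(params: ThalamicCellParams, v: float = -70.0) -> CompartmentState:
    """State with all gating variables at steady state for voltage ``v``."""
    g = {
        "m": _f(R.thal_na_m(v)[0]), "h": _f(R.thal_na_h(v)[0]),
        "n": _f(R.thal_k_n(v)[0]),
    }
    if params.is_tc:
        g["mt"], g["ht"] = _f(R.tc_t_m(v)[0]), _f(R.tc_t_h(v)[0])
        g["o1"], g["p1"], g["o2"] = _f(R.tc_h_o(v)[0]), 0.0, 0.0
    else:
        g["mt"], g["ht"] = _f(R.re_t_m(v)[0]), _f(R.re_t_h(v)[0])
        g["o1"] = g["p1"] = g["o2"] = 0.0
    return CompartmentState(v=v, gating=g, ca=R.CA_INF)


def thalamic_currents(state: CompartmentState, params: ThalamicCellParams) -> dict[str, float]:
    """Individual intrinsic current densities (uA/cm^2, outward positive)."""
    v, g = state.v, state.gating
    cur = {
        "leak": params.g_leak * (v - params.e_leak),
        "kl": params.g_kl * (v - params.e_kl),
        "na": params.g_na * g["m"] ** 3 * g["h"] * (v - E_NA),
        "k": params.g_k * g["n"] ** 4 * (v - E_K_THAL),
        "t": params.g_t * g["mt"] ** 2 * g["ht"] * (v - _f(R.eca_nernst(state.ca))),
    }
    if params.is_tc and params.g_h > 0:
        cur["h"] = params.g_h * (g["o1"] + R.IH_GINC * g["o2"]) * (v - E_H)
    return cur


def thalamic_derivatives(
    state: CompartmentState, params: ThalamicCellParams, i_syn: float = 0.0
) -> tuple[float, dict[str, float], float]:
    """Time derivatives (dV/dt, d(gating)/dt, dCa/dt) of a thalamic cell.

    ``i_syn`` is a synaptic current density in uA/cm^2 (outward positive).
    """
    state.validate()
    v, g = state.v, state.gating
    cur = thalamic_currents(state, params)
    dv = -(sum(cur.values()) + i_syn) / params.cm

    dg = {}
    for name, fn in (("m", R.thal_na_m), ("h", R.thal_na_h), ("n", R.thal_k_n)):
        inf, tau = fn(v)
        dg[name] = (_f(inf) - g[name]) / _f(tau)
    mt_fn, ht_fn = (R.tc_t_m, R.tc_t_h) if params.is_tc else (R.re_t_m, R.re_t_h)
    for name, fn in (("mt", mt_fn), ("ht", ht_fn)):
        inf, tau = fn(v)
        dg[name] = (_f(inf) - g[name]) / _f(tau)

    if params.is_tc and params.g_h > 0:
        h_inf, tau_s = (_f(x) for x in R.tc_h_o(v))
        c1 = 1.0 - g["o1"] - g["o2"]
        dg["o1"] = (h_inf * c1 - (1.0 - h_inf) * g["o1"]) / tau_s \
            - R.IH_K3 * g["p1"] * g["o1"] + R.IH_K4 * g["o2"]
        dg["p1"] = R.IH_K1 * state.ca ** 4 * (1.0 - g["p1"]) - R.IH_K2 * g["p1"]
        dg["o2"] = R.IH_K3 * g["p1"] * g["o1"] - R.IH_K4 * g["o2"]
    else:
        dg["o1"] = dg["p1"] = dg["o2"] = 0.0

    dca = -R.CA_DRIVE_THAL * min(cur["t"], 0.0) + (R.CA_INF - state.ca) / params.ca_tau
    return dv, dg, dca


def cortical_initial_state(
    params: CorticalCellParams, v: float = -70.0
) -> tuple[CompartmentState, CompartmentState]:
    soma = CompartmentState(v=v, gating={
        "m": _f(R.cort_na_m(v)[0]), "h": _f(R.cort_na_h(v)[0]),
        "n": _f(R.cort_k_n(v)[0]), "mnap": _f(R.cort_nap_m(v)[0]),
    })
    dend = CompartmentState(v=v, gating={
        "m": _f(R.cort_na_m(v)[0]), "h": _f(R.cort_na_h(v)[0]),
        "mnap": _f(R.cort_nap_m(v)[0]), "mkm": _f(R.cort_km_n(v)[0]),
        "mkca": _f(R.kca_rates(R.CA_INF)[0]),
        "mhva": _f(R.cort_hva_m(v)[0]), "hhva": _f(R.cort_hva_h(v)[0]),
    })
    return soma, dend


def cortical_currents(
    soma: CompartmentState, dend: CompartmentState, params: CorticalCellParams
) -> tuple[dict[str, float], dict[str, float]]:
    """Intrinsic + axial current densities per compartment (uA/cm^2)."""
    vs, vd = soma.v, dend.v
    gs, gd = soma.gating, dend.gating
    i_s = {
        "na": params.g_na_soma * gs["m"] ** 3 * gs["h"] * (vs - E_NA),
        "k": params.g_k_soma * gs["n"] * (vs - E_K_CORT),  # first-order kv
        "nap": params.g_nap_soma * gs["mnap"] * (vs - E_NA),
        "axial": params.g_c_soma * (vs - vd),
    }
    e_ca = _f(R.eca_nernst(dend.ca))
    i_d = {
        "leak": params.g_l_dend * (vd - params.e_leak),
        "kl": params.g_kl_dend * (vd - params.e_kl),
        "na": params.g_na_dend * gd["m"] ** 3 * gd["h"] * (vd - E_NA),
        "nap": params.g_nap_dend * gd["mnap"] * (vd - E_NA),
        "hva": params.g_hva_dend * gd["mhva"] ** 2 * gd["hhva"] * (vd - e_ca),
        "kca": params.g_kca_dend * gd["mkca"] * (vd - E_K_CORT),
        "km": params.g_km_dend * gd["mkm"] * (vd - E_K_CORT),
        "axial": params.g_c_dend * (vd - vs),
    }
    return i_s, i_d


def cortical_derivatives(
    soma: CompartmentState,
    dend: CompartmentState,
    params: CorticalCellParams,
    i_syn: float = 0.0,
):
    """Derivatives for both compartments; ``i_syn`` enters the dendrite.

    Returns (dVs, d soma gating, dVd, d dend gating, dCa).  The axial
    current is antisymmetric after area scaling: I_axial_soma * S_soma =
    -I_axial_dend * S_dend.
    """
    soma.validate()
    dend.validate()
    i_s, i_d = cortical_currents(soma, dend, params)
    dvs = -sum(i_s.values()) / params.cm_soma
    dvd = -(sum(i_d.values()) + i_syn) / params.cm_dend

    dgs = {}
    for name, fn in (("m", R.cort_na_m), ("h", R.cort_na_h),
                     ("n", R.cort_k_n), ("mnap", R.cort_nap_m)):
        inf, tau = fn(soma.v)
        dgs[name] = (_f(inf) - soma.gating[name]) / _f(tau)
    dgd = {}
    for name, fn in (("m", R.cort_na_m), ("h", R.cort_na_h),
                     ("mnap", R.cort_nap_m), ("mkm", R.cort_km_n),
                     ("mhva", R.cort_hva_m), ("hhva", R.cort_hva_h)):
        inf, tau = fn(dend.v)
        dgd[name] = (_f(inf) - dend.gating[name]) / _f(tau)
    inf, tau = R.kca_rates(dend.ca)
    dgd["mkca"] = (_f(inf) - dend.gating["mkca"]) / _f(tau)

    dca = -R.CA_DRIVE_CORT * min(i_d["hva"], 0.0) + (R.CA_INF - dend.ca) / params.ca_tau
    return dvs, dgs, dvd, dgd, dca


# ---------------------------------------------------------------------------
# single-cell integration (exponential Euler / Rush-Larsen)
# ---------------------------------------------------------------------------

def _rl(x: float, inf: float, tau: float, dt: float) -> float:
    return inf + (x - inf) * math.exp(-dt / tau)


def integrate_thalamic(
    params: ThalamicCellParams,
    duration: float,
    dt: float = 0.025,
    i_inject=None,
    state: CompartmentState | None = None,
    record_every: int = 1,
):
    """Integrate a thalamic cell for ``duration`` ms.

    ``i_inject(t)`` (optional) is an injected current density in uA/cm^2,
    outward positive (negative values depolarize).  Voltage uses exponential
    Euler with conductances frozen over the step; gating uses Rush-Larsen.
    Returns (t, V, final_state).
    """
    st = state.copy() if state is not None else thalamic_initial_state(params)
    n = int(round(duration / dt))
    ts, vs = [], []
    g = st.gating
    mt_fn, ht_fn = (R.tc_t_m, R.tc_t_h) if params.is_tc else (R.re_t_m, R.re_t_h)
    for k in range(n):
        t = k * dt
        v = st.v
        # conductance-weighted sums for the exponential-Euler voltage update
        g_na = params.g_na * g["m"] ** 3 * g["h"]
        g_k = params.g_k * g["n"] ** 4
        g_t = params.g_t * g["mt"] ** 2 * g["ht"]
        e_ca = _f(R.eca_nernst(st.ca))
        gtot = params.g_leak + params.g_kl + g_na + g_k + g_t
        gesum = (params.g_leak * params.e_leak + params.g_kl * params.e_kl
                 + g_na * E_NA + g_k * E_K_THAL + g_t * e_ca)
        if params.is_tc and params.g_h > 0:
            g_h = params.g_h * (g["o1"] + R.IH_GINC * g["o2"])
            gtot += g_h
            gesum += g_h * E_H
        i_ext = i_inject(t) if i_inject is not None else 0.0
        v_inf = (gesum - i_ext) / gtot
        st.v = v_inf + (v - v_inf) * math.exp(-dt * gtot / params.cm)

        i_t = g_t * (v - e_ca)
        st.ca += dt * (-R.CA_DRIVE_THAL * min(i_t, 0.0) + (R.CA_INF - st.ca) / params.ca_tau)

        for name, fn in (("m", R.thal_na_m), ("h", R.thal_na_h),
                         ("n", R.thal_k_n), ("mt", mt_fn), ("ht", ht_fn)):
            inf, tau = fn(v)
            g[name] = _rl(g[name], _f(inf), _f(tau), dt)
        if params.is_tc and params.g_h > 0:
            h_inf, tau_s = (_f(x) for x in R.tc_h_o(v))
            c1 = 1.0 - g["o1"] - g["o2"]
            do1 = (h_inf * c1 - (1.0 - h_inf) * g["o1"]) / tau_s \
                - R.IH_K3 * g["p1"] * g["o1"] + R.IH_K4 * g["o2"]
            dp1 = R.IH_K1 * st.ca ** 4 * (1.0 - g["p1"]) - R.IH_K2 * g["p1"]
            do2 = R.IH_K3 * g["p1"] * g["o1"] - R.IH_K4 * g["o2"]
            g["o1"] = min(max(g["o1"] + dt * do1, 0.0), 1.0)
            g["p1"] = min(max(g["p1"] + dt * dp1, 0.0), 1.0)
            g["o2"] = min(max(g["o2"] + dt * do2, 0.0), 1.0)
        if k % record_every == 0:
            ts.append(t)
            vs.append(st.v)
    return np.asarray(ts), np.asarray(vs), st


def integrate_cortical(
    params: CorticalCellParams,
    duration: float,
    dt: float = 0.025,
    i_inject_dend=None,
    state: tuple[CompartmentState, CompartmentState] | None = None,
    record_every: int = 1,
):
    """Integrate a two-compartment cortical cell for ``duration`` ms.

    ``i_inject_dend(t)``: injected dendritic current density (uA/cm^2,
    outward positive).  Returns (t, V_soma, V_dend, (soma, dend) state).
    """
    if state is None:
        soma, dend = cortical_initial_state(params)
    else:
        soma, dend = (s.copy() for s in state)
    n = int(round(duration / dt))
    ts, vss, vds = [], [], []
    gs, gd = soma.gating, dend.gating
    for k in range(n):
        t = k * dt
        vs, vd = soma.v, dend.v
        # soma
        g_na = params.g_na_soma * gs["m"] ** 3 * gs["h"]
        g_k = params.g_k_soma * gs["n"]
        g_nap = params.g_nap_soma * gs["mnap"]
        gtot_s = g_na + g_k + g_nap + params.g_c_soma
        ge_s = g_na * E_NA + g_k * E_K_CORT + g_nap * E_NA + params.g_c_soma * vd
        v_inf = ge_s / gtot_s
        soma.v = v_inf + (vs - v_inf) * math.exp(-dt * gtot_s / params.cm_soma)
        # dendrite
        e_ca = _f(R.eca_nernst(dend.ca))
        g_na_d = params.g_na_dend * gd["m"] ** 3 * gd["h"]
        g_nap_d = params.g_nap_dend * gd["mnap"]
        g_hva = params.g_hva_dend * gd["mhva"] ** 2 * gd["hhva"]
        g_kca = params.g_kca_dend * gd["mkca"]
        g_km = params.g_km_dend * gd["mkm"]
        gtot_d = (params.g_l_dend + params.g_kl_dend + g_na_d + g_nap_d
                  + g_hva + g_kca + g_km + params.g_c_dend)
        ge_d = (params.g_l_dend * params.e_leak + params.g_kl_dend * params.e_kl
                + (g_na_d + g_nap_d) * E_NA + g_hva * e_ca
                + (g_kca + g_km) * E_K_CORT + params.g_c_dend * vs)
        i_ext = i_inject_dend(t) if i_inject_dend is not None else 0.0
        v_inf_d = (ge_d - i_ext) / gtot_d
        dend.v = v_inf_d + (vd - v_inf_d) * math.exp(-dt * gtot_d / params.cm_dend)

        i_hva = g_hva * (vd - e_ca)
        dend.ca += dt * (-R.CA_DRIVE_CORT * min(i_hva, 0.0)
                         + (R.CA_INF - dend.ca) / params.ca_tau)

        for name, fn in (("m", R.cort_na_m), ("h", R.cort_na_h),
                         ("n", R.cort_k_n), ("mnap", R.cort_nap_m)):
            inf, tau = fn(vs)
            gs[name] = _rl(gs[name], _f(inf), _f(tau), dt)
        for name, fn in (("m", R.cort_na_m), ("h", R.cort_na_h),
                         ("mnap", R.cort_nap_m), ("mkm", R.cort_km_n),
                         ("mhva", R.cort_hva_m), ("hhva", R.cort_hva_h)):
            inf, tau = fn(vd)
            gd[name] = _rl(gd[name], _f(inf), _f(tau), dt)
        inf, tau = R.kca_rates(dend.ca)
        gd["mkca"] = _rl(gd["mkca"], _f(inf), _f(tau), dt)
        if k % record_every == 0:
            ts.append(t)
            vss.append(soma.v)
            vds.append(dend.v)
    return np.asarray(ts), np.asarray(vss), np.asarray(vds), (soma, dend)


def resting_state(params, relax_ms: float = 5000.0, dt: float = 0.05):
    """Resting state found by relaxation integration with zero input.

    For thalamic parameters returns a single :class:`CompartmentState`; for
    cortical parameters a (soma, dend) pair.  Raises if the relaxed voltage
    falls outside [-110, -40] mV (no physiological fixed point).
    """
    if isinstance(params, ThalamicCellParams):
        _, _, st = integrate_thalamic(params, relax_ms, dt=dt, record_every=10 ** 9)
        v = st.v
        out = st
    elif isinstance(params, CorticalCellParams):
        _, _, _, pair = integrate_cortical(params, relax_ms, dt=dt, record_every=10 ** 9)
        v = pair[1].v
        out = pair
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    if not -110.0 <= v <= -40.0:
        raise RuntimeError(
            f"no resting fixed point in [-110, -40] mV (relaxed to {v:.1f} mV)"
        )
    return out
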