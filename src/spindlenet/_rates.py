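"""Voltage-dependent gating kinetics of the intrinsic currents.

The published parameter tables of this model family fix the maximal
conductances but defer the rate equations to earlier single-cell papers.
The functions here implement that standard kinetics set:

* thalamic I_Na / I_K: Traub-type rates with a -63 mV threshold shift
  (spike threshold near -50 mV);
* TC-cell I_T: low-threshold Ca current with slow inactivation (rates
  temperature-scaled to 36 C with Q10 = 3);
* RE-cell I_T: the reticular variant with its more depolarized activation;
* TC-cell I_h: anomalous rectifier with activity-dependent upregulation --
  Ca2+-bound messenger locks open channels in a higher-conductance state,
  producing the waxing-and-waning spindle envelope;
* cortical I_Na, I_K(delayed rectifier), I_Na(p), I_Km, I_HVA: the
  regular-/fast-spiking two-compartment kinetics set (rates Q10-scaled to
  36 C, factor ~2.95);
* I_KCa: first-order Ca-activated K current, rates 0.01*[Ca] / 0.02;
* Ca pools: influx 5.18e-5 * (-I_Ca) mM cm^2 / (ms uA) (1 um shell) with
  first-order return to 0.24 uM (tau 5 ms thalamus, 165 ms cortex).

Every function returns (x_inf, tau) in ms for use either directly (the
reference single-cell integrator) or via precomputed lookup tables (the
network kernel).
"""

from __future__ import annotations

import numpy as np

# temperature scaling for the cortical rate set (Q10 = 2.3, 23 -> 36 C)
Q_CORT = 2.3 ** 1.3
# thalamic I_T temperature factors (Q10 = 3 resp. 3, 24 -> 36 C)
PHI_TC_T_M = 3.73
PHI_TC_T_H = 3.73
PHI_RE_T_M = 5.0 ** 1.2
PHI_RE_T_H = 3.0 ** 1.2

CA_OUT = 2.0        # extracellular Ca (mM)
CA_INF = 2.4e-4     # resting intracellular Ca (mM)
CA_DRIVE_THAL = 5.18e-5  # mM cm^2 / (ms uA), 1 um shell
CA_DRIVE_CORT = 5.18e-4  # 0.1 um submembrane shell: strong spike transients
NERNST_CA = 13.31   # RT/2F at 36 C, mV per ln unit


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with its limit y at x -> 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    safe = np.where(small, 1.0, x)
    return np.where(small, y * (1.0 - x / (2.0 * y)), safe / np.expm1(safe / y))


def eca_nernst(ca):
    """Calcium reversal potential (mV) from intracellular concentration (mM)."""
    return NERNST_CA * np.log(CA_OUT / np.maximum(ca, 1e-8))


# ---------------------------------------------------------------------------
# thalamic sodium / potassium (Traub rates, shifted)
# ---------------------------------------------------------------------------

def thal_na_m(v, shift=63.0):
    u = np.asarray(v, dtype=float) + shift
    a = 0.32 * _vtrap(13.0 - u, 4.0)
    b = 0.28 * _vtrap(u - 40.0, 5.0)
    return a / (a + b), 1.0 / (a + b)


def thal_na_h(v, shift=63.0):
    u = np.asarray(v, dtype=float) + shift
    a = 0.128 * np.exp((17.0 - u) / 18.0)
    b = 4.0 / (1.0 + np.exp((40.0 - u) / 5.0))
    return a / (a + b), 1.0 / (a + b)


def thal_k_n(v, shift=63.0):
    u = np.asarray(v, dtype=float) + shift
    a = 0.032 * _vtrap(15.0 - u, 5.0)
    b = 0.5 * np.exp((10.0 - u) / 40.0)
    return a / (a + b), 1.0 / (a + b)


# ---------------------------------------------------------------------------
# low-threshold calcium current I_T
# ---------------------------------------------------------------------------

def tc_t_m(v):
    v = np.asarray(v, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(v + 57.0) / 6.2))
    tau = (0.612 + 1.0 / (np.exp(-(v + 132.0) / 16.7) + np.exp((v + 16.8) / 18.2)))
    return m_inf, tau / PHI_TC_T_M


def tc_t_h(v):
    v = np.asarray(v, dtype=float)
    h_inf = 1.0 / (1.0 + np.exp((v + 81.0) / 4.0))
    tau = np.where(
        v < -80.0,
        np.exp((v + 467.0) / 66.6),
        28.0 + np.exp(-(v + 22.0) / 10.5),
    )
    return h_inf, tau / PHI_TC_T_H


def re_t_m(v):
    v = np.asarray(v, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(v + 52.0) / 7.4))
    tau = 3.0 + 1.0 / (np.exp((v + 27.0) / 10.0) + np.exp(-(v + 102.0) / 15.0))
    return m_inf, tau / PHI_RE_T_M


def re_t_h(v):
    v = np.asarray(v, dtype=float)
    h_inf = 1.0 / (1.0 + np.exp((v + 80.0) / 5.0))
    tau = 85.0 + 1.0 / (np.exp((v + 48.0) / 4.0) + np.exp(-(v + 407.0) / 50.0))
    return h_inf, tau / PHI_RE_T_H


# ---------------------------------------------------------------------------
# TC-cell h-current with calcium-dependent upregulation
# ---------------------------------------------------------------------------

# messenger binding: P0 + 4 Ca <-> P1, half-activation at IH_CAC;
# open-channel locking: O + P1 <-> O_locked, conductance factor IH_GINC
IH_K2 = 4e-4     # 1/ms, unbinding
IH_CAC = 1.5e-3  # mM, messenger half-activation
IH_K4 = 1e-3     # 1/ms, unlocking
IH_K3 = 0.1      # 1/ms, locking (times bound messenger)
IH_GINC = 2.0    # conductance of the locked state relative to open
IH_K1 = IH_K2 / IH_CAC ** 4


def tc_h_o(v):
    """Voltage gating of the open fraction of I_h."""
    v = np.asarray(v, dtype=float)
    h_inf = 1.0 / (1.0 + np.exp((v + 75.0) / 5.5))
    tau = 20.0 + 1000.0 / (np.exp((v + 71.5) / 14.2) + np.exp(-(v + 89.0) / 11.6))
    return h_inf, tau


# ---------------------------------------------------------------------------
# cortical kinetics (two-compartment regular-/fast-spiking set)
# ---------------------------------------------------------------------------

def _safe_exprel(x, y):
    """x / (1 - exp(-x/y)) with limit y at x -> 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    safe = np.where(small, 1.0, x)
    return np.where(small, y * (1.0 + x / (2.0 * y)), safe / -np.expm1(-safe / y))


def cort_na_m(v):
    x = np.asarray(v, dtype=float) + 25.0
    a = 0.182 * _safe_exprel(x, 9.0)
    b = 0.124 * _safe_exprel(-x, 9.0)
    return a / (a + b), 1.0 / (a + b) / Q_CORT


def cort_na_h(v):
    v = np.asarray(v, dtype=float)
    a = 0.024 * _safe_exprel(v + 40.0, 5.0)
    b = 0.0091 * _safe_exprel(-(v + 65.0), 5.0)
    h_inf = 1.0 / (1.0 + np.exp((v + 55.0) / 6.2))
    tau = 1.0 / (a + b) / Q_CORT
    return h_inf, tau


def cort_k_n(v):
    v = np.asarray(v, dtype=float)
    a = 0.02 * _safe_exprel(v - 25.0, 9.0)
    b = 0.002 * _safe_exprel(-(v - 25.0), 9.0)
    return a / (a + b), 1.0 / (a + b) / Q_CORT


def cort_nap_m(v):
    # the model family's functional form carries a 0.02 open-fraction scale;
    # without it the persistent Na current latches the dendrite near -15 mV
    v = np.asarray(v, dtype=float)
    m_inf = 0.02 / (1.0 + np.exp(-(v + 42.0) / 5.0))
    return m_inf, np.full_like(v, 0.2)


def cort_km_n(v):
    v = np.asarray(v, dtype=float)
    a = 0.001 * _safe_exprel(v + 30.0, 9.0)
    b = 0.001 * _safe_exprel(-(v + 30.0), 9.0)
    return a / (a + b), 1.0 / (a + b) / Q_CORT


def cort_hva_m(v):
    v = np.asarray(v, dtype=float)
    a = 0.055 * _vtrap(-27.0 - v, 3.8)
    b = 0.94 * np.exp((-75.0 - v) / 17.0)
    return a / (a + b), 1.0 / (a + b) / Q_CORT


def cort_hva_h(v):
    v = np.asarray(v, dtype=float)
    a = 4.57e-4 * np.exp((-13.0 - v) / 50.0)
    b = 6.5e-3 / (np.exp((-15.0 - v) / 28.0) + 1.0)
    return a / (a + b), 1.0 / (a + b) / Q_CORT


# Ca-activated K current rates (per ms); tau floor keeps integration stable
KCA_RA = 0.01   # 1/(ms mM)
KCA_RB = 0.02   # 1/ms


def kca_rates(ca):
    a = KCA_RA * np.asarray(ca, dtype=float)
    b = KCA_RB
    return a / (a + b), 1.0 / (a + b) / Q_CORT


# ---------------------------------------------------------------------------
# lookup tables for the network kernel
# ---------------------------------------------------------------------------

V_MIN, V_MAX, V_STEP = -130.0, 60.0, 0.05


def build_tables(dt: float):
    """Precompute (x_inf, exp(-dt/tau)) on a voltage grid for every gate.

    Returns (v_min, inv_step, inf_table, rl_table) with tables of shape
    (n_gates, n_points).  Gate order: thalamic m/h/n, TC T m/h, RE T m/h,
    Ih open; cortical Na m/h, K n, Nap m, Km n, HVA m/h.
    """
    v = np.arange(V_MIN, V_MAX + V_STEP, V_STEP)
    gates = [
        thal_na_m(v), thal_na_h(v), thal_k_n(v),
        tc_t_m(v), tc_t_h(v), re_t_m(v), re_t_h(v), tc_h_o(v),
        cort_na_m(v), cort_na_h(v), cort_k_n(v), cort_nap_m(v),
        cort_km_n(v), cort_hva_m(v), cort_hva_h(v),
    ]
    inf = np.stack([g[0] for g in gates]).astype(np.float64)
    rl = np.stack([np.exp(-dt / np.maximum(g[1], 1e-4)) for g in gates])
    return V_MIN, 1.0 / V_STEP, inf, rl.astype(np.float64)


# gate indices into the tables
(G_THAL_NA_M, G_THAL_NA_H, G_THAL_K_N, G_TC_T_M, G_TC_T_H, G_RE_T_M,
 G_RE_T_H, G_TC_H_O, G_C_NA_M, G_C_NA_H, G_C_K_N, G_C_NAP_M, G_C_KM_N,
 G_C_HVA_M, G_C_HVA_H) = range(15)
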