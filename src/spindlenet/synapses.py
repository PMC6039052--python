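"""Synaptic receptor kinetics and short-term plasticity.

Chemical synapses are modeled with first-order transmitter-gated channel
kinetics: while the presynaptic membrane is depolarized above the release
threshold, a square pulse of transmitter ``T`` (mM) drives the open channel
fraction ``O`` as

    dO/dt = alpha * T * (1 - O) - beta * O

and the postsynaptic current is ``I = g_max * D * O * gate * (V - E_syn)``
(outward positive), where ``D`` is a short-term depression factor and
``gate`` is a voltage-dependent magnesium-block factor for NMDA receptors
(1 otherwise).

GABA-B responses are metabotropic: transmitter activates receptor ``R``,
which catalyzes G-protein production ``G``; the K+ channel opens
cooperatively, with conductance factor ``G**4 / (G**4 + K_d)``.  This makes
the GABA-B conductance slow (peak ~100 ms after a spike) and selectively
responsive to presynaptic bursts.

Short-term depression follows a single-resource phenomenological model:
at each presynaptic event a fraction ``U`` of resources is consumed and
recovers with time constant ``tau``; only intracortical excitatory
connections depress.

Miniature PSPs ("minis") are spontaneous release events timed by an
inhomogeneous Poisson process whose rate recovers sigmoidally after each
presynaptic spike, saturating at 1/250 events per ms (4 Hz per synapse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReceptorKinetics",
    "SynapseState",
    "GababParams",
    "MiniProcess",
    "RECEPTOR_DEFAULTS",
    "synaptic_current",
    "depression_update",
    "nmda_voltage_gate",
    "gabab_update",
    "gabab_conductance_factor",
    "mini_rate",
    "sample_mini_times",
    "MINI_RATE_MAX",
]

#: saturation rate of the miniature-release process, events per ms
MINI_RATE_MAX = 1.0 / 250.0


@dataclass
class ReceptorKinetics:
    """Kinetic constants of one receptor type.

    Parameters
    ----------
    receptor:
        One of ``"AMPA"``, ``"NMDA"``, ``"GABA_A"``, ``"GABA_B"``.
    alpha, beta:
        Opening / closing rates (1/(mM ms) and 1/ms).  Unused for GABA_B,
        which follows the G-protein cascade instead.
    t_max, t_dur:
        Amplitude (mM) and duration (ms) of the transmitter pulse.
    e_syn:
        Reversal potential (mV).
    """

    receptor: str
    alpha: float
    beta: float
    t_max: float = 0.5
    t_dur: float = 0.3
    e_syn: float = 0.0


#: Default kinetics.  Rise/decay constants follow the standard first-order
#: fits of the kinetic-model family used for network simulations of this
#: kind (fast AMPA, slow NMDA, ~6 ms GABA-A decay, 0.5 mM / 0.3 ms pulse).
#: Reversals: 0 mV for AMPA/NMDA; -70 mV for GABA-A onto cortical cells and
#: RE cells, -85 mV onto TC cells (set per connection; the deeper relay-cell
#: chloride reversal, required for I_T rebound); -95 mV for GABA-B.
RECEPTOR_DEFAULTS: dict[str, ReceptorKinetics] = {
    "AMPA": ReceptorKinetics("AMPA", alpha=1.1, beta=0.67, e_syn=0.0),
    "NMDA": ReceptorKinetics("NMDA", alpha=0.072, beta=0.0066, e_syn=0.0),
    "GABA_A": ReceptorKinetics("GABA_A", alpha=5.0, beta=0.18, e_syn=-70.0),
    "GABA_B": ReceptorKinetics("GABA_B", alpha=0.0, beta=0.0, e_syn=-95.0),
}

#: GABA-A reversal is target dependent.
GABA_A_REVERSAL = {"TC": -85.0, "RE": -70.0, "PY": -70.0, "IN": -70.0}


@dataclass
class GababParams:
    """G-protein cascade constants for GABA-B receptors.

    ``r`` is the activated-receptor fraction, ``g`` the G-protein
    concentration (dimensionless units): dr/dt = k1*T*(1-r) - k2*r,
    dg/dt = k3*r - k4*g, conductance factor g**4/(g**4 + kd).
    """

    k1: float = 0.52   # 1/(mM ms)
    k2: float = 0.0013  # 1/ms
    k3: float = 0.098   # 1/ms
    k4: float = 0.033   # 1/ms
    kd: float = 100.0
    n: int = 4


@dataclass
class SynapseState:
    """Dynamic state of a single synapse."""

    o: float = 0.0       # open channel fraction, in [0, 1]
    d: float = 1.0       # depression resource factor, in [0, 1]
    t_last: float = -1e9  # time of last presynaptic event (ms)
    r: float = 0.0       # GABA-B activated receptor fraction
    g: float = 0.0       # GABA-B G-protein concentration


@dataclass
class MiniProcess:
    """Bookkeeping for one miniature-release stream."""

    t0: float = -1e9     # time of last presynaptic spike (ms)
    amplitude: float = 0.0  # conductance increment per mini (fraction of O)
    seed: int = 0


def synaptic_current(
    g_max: float,
    state: SynapseState,
    v_post: float,
    kin: ReceptorKinetics,
    nmda_gate: float = 1.0,
) -> float:
    """Instantaneous synaptic current (outward positive).

    ``I = g_max * D * O * gate * (V_post - E_syn)``; for non-NMDA receptors
    the gate is 1.  Units follow ``g_max`` (a conductance in uS gives a
    current in 1e-3 uA when V is in mV).
    """
    if g_max < 0:
        raise ValueError("g_max must be non-negative")
    return g_max * state.d * state.o * nmda_gate * (v_post - kin.e_syn)


def depression_update(
    d_i: float, t_i: float, t: float, u: float = 0.2, tau: float = 500.0
) -> float:
    """Depression factor at a presynaptic event.

    ``D = 1 - (1 - D_i (1 - U)) * exp(-(t - t_i)/tau)`` where ``D_i`` is the
    factor used at the previous event at time ``t_i``, ``U`` the fraction of
    resources consumed per event and ``tau`` the recovery time constant (ms).
    """
    if t < t_i:
        raise ValueError(f"event time t={t} precedes previous event t_i={t_i}")
    if not 0.0 <= d_i <= 1.0:
        raise ValueError(f"D_i={d_i} outside [0, 1]")
    return 1.0 - (1.0 - d_i * (1.0 - u)) * math.exp(-(t - t_i) / tau)


def nmda_voltage_gate(v_post, v_th: float = -25.0, delta: float = 12.5):
    """Magnesium-block relief factor of NMDA receptors.

    Sigmoid in the postsynaptic voltage, ``1/(1 + exp(-(V - V_th)/delta))``:
    0.5 at -25 mV, approaching 1 with depolarization.
    """
    return 1.0 / (1.0 + np.exp(-(np.asarray(v_post, dtype=float) - v_th) / delta))


def gabab_conductance_factor(g: float, params: GababParams | None = None) -> float:
    """Fraction of GABA-B-gated K+ channels open at G-protein level ``g``."""
    if params is None:
        params = GababParams()
    gn = g ** params.n
    return gn / (gn + params.kd)


def gabab_update(
    state: SynapseState,
    transmitter: float,
    dt: float,
    params: GababParams | None = None,
) -> float:
    """Advance the GABA-B cascade by ``dt`` ms and return the conductance factor.

    ``transmitter`` is the current transmitter concentration (mM); pass the
    pulse amplitude while the presynaptic cell is releasing and 0 otherwise.
    """
    if params is None:
        params = GababParams()
    r, g = state.r, state.g
    state.r = r + dt * (params.k1 * transmitter * (1.0 - r) - params.k2 * r)
    state.g = g + dt * (params.k3 * r - params.k4 * g)
    return gabab_conductance_factor(state.g, params)


def mini_rate(t, t0):
    """Miniature-release rate (events/ms) at time ``t`` after a spike at ``t0``.

    ``mu = (2/(1 + exp(-(t - t0)/400)) - 1)/250``: zero immediately after a
    presynaptic spike, recovering sigmoidally to 1/250 per ms.
    """
    dt = np.asarray(t, dtype=float) - t0
    mu = (2.0 / (1.0 + np.exp(-dt / 400.0)) - 1.0) / 250.0
    return np.maximum(mu, 0.0)


def sample_mini_times(
    t0: float,
    horizon: float,
    seed: int | np.random.Generator,
    t_start: float | None = None,
) -> np.ndarray:
    """Sample miniature-event times on ``[t_start, t_start + horizon)`` ms.

    Inhomogeneous Poisson process with rate :func:`mini_rate` relative to the
    last presynaptic spike at ``t0``, sampled by thinning against the
    saturation rate.  Deterministic given ``seed``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if t_start is None:
        t_start = t0
    t = float(t_start)
    end = t_start + horizon
    out = []
    while True:
        t -= math.log(rng.random()) / MINI_RATE_MAX
        if t >= end:
            break
        if rng.random() * MINI_RATE_MAX < mini_rate(t, t0):
            out.append(t)
    return np.asarray(out, dtype=float)
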