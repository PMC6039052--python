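"""Drivers for the model's parameter-sweep experiments.

Each driver rebuilds the network for a condition, simulates it, runs the
detection + statistics pipeline on the estimated LFP of both systems, and
returns one tidy row per (condition, seed).  Three experiments are
provided:

* ``fanout_sweep`` -- vary the matrix/core thalamocortical fanout ratio
  over the radius quadruples (core TC->L3/4, L6->core TC, matrix TC->L5,
  L5->matrix TC) = (10, 2, 10r, 2r);
* ``interlaminar_sweep`` -- scale the AMPA+NMDA interlaminar totals in one
  direction (L3/4->L5 or L5->L3/4) while everything else stays fixed;
* ``one_layer_model`` -- a reduced single-layer, single-system network for
  probing thalamocortical/corticothalamic strength and fanout without the
  input-count weight normalization.

Desk-scale runs divide population sizes (and the printed thalamocortical
radii) by ``scale``; intracortical and intrathalamic footprints are kept
in absolute cell counts (see NetworkSpec.scaled).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import stats as st
from .detect import DetectorParams, detect_spindles
from .io import config_hash
from .lfp import estimate_lfp
from .network import ConnectionRule, Network, NetworkSpec, Population, build_network
from .simulator import SimConfig, SimResult, run_simulation

__all__ = [
    "SweepSpec",
    "analyze_result",
    "run_condition",
    "fanout_sweep",
    "interlaminar_sweep",
    "one_layer_model",
    "FANOUT_RADII",
]

#: printed radius quadruples of the fanout experiment, keyed by ratio
FANOUT_RADII = {
    1.0: (10, 2, 10, 2),
    2.5: (10, 2, 25, 5),
    5.0: (10, 2, 50, 10),
    7.5: (10, 2, 75, 15),
    10.0: (10, 2, 100, 20),
    12.5: (10, 2, 125, 25),
    15.0: (10, 2, 150, 30),
}


@dataclass(frozen=True)
class SweepSpec:
    """One sweep request: which variable, which values, how many seeds."""

    kind: str                 # fanout | interlaminar_up | interlaminar_down
    values: tuple[float, ...]
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    scale: float = 5.0        # network-size divisor
    duration: float = 120.0   # simulated seconds per condition
    transient: float = 5.0
    mini_amp: float = 0.07

    def __post_init__(self):
        if not self.values:
            raise ValueError("values must be non-empty")
        if not self.seeds:
            raise ValueError("need at least one seed")


def _sim_config(sweep: SweepSpec, seed: int) -> SimConfig:
    return SimConfig(duration=sweep.duration + sweep.transient,
                     transient_discard=sweep.transient, seed=seed,
                     mini_amp=sweep.mini_amp)


def analyze_result(
    res: SimResult,
    detector: DetectorParams | None = None,
    n_groups: int = 10,
    layers: tuple[str, str] = ("L34", "L5"),
) -> dict:
    """Detection + statistics for one simulation.

    Returns a flat dict of the headline quantities (densities,
    co-occurrence both ways, mean onset delay, ISI samples, spatial
    correlation means) plus the per-layer event lists under ``events``.
    """
    if detector is None:
        detector = DetectorParams.model()
    out: dict = {"events": {}, "lfp": {}}
    per_layer_events = {}
    for layer in layers:
        cur = res.lfp_currents[layer]
        group_size = max(cur.shape[0] // n_groups, 1)
        ser = estimate_lfp(cur, res.record_rate, layer, group_size=group_size)
        evs = []
        for ch in range(ser.n_groups):
            evs.extend(detect_spindles(ser.data[:, ch], ser.rate, detector,
                                       channel=ch))
        per_layer_events[layer] = evs
        out["events"][layer] = evs
        out["lfp"][layer] = ser
        dens = st.spindle_density(evs, res.duration, n_channels=ser.n_groups)
        out[f"density_{layer}"] = float(dens.mean())
        out[f"density_{layer}_per_channel"] = dens
        # layer-level initiation rate: channel events merged into system
        # events (a global spindle counts once, however many channels it
        # lights up)
        out[f"event_rate_{layer}"] = len(st.merge_events(evs)) / res.duration * 60.0
        out[f"duration_{layer}"] = float(np.mean([e.duration for e in evs])) if evs else float("nan")
        per_ch = [[e for e in evs if e.channel == c] for c in range(ser.n_groups)]
        out[f"isi_{layer}"] = st.isi_pooled(per_ch)
        try:
            sc = st.spatial_correlation(ser.data, ser.rate, evs)
            out[f"spatial_corr_{layer}"] = float(sc["corr"].mean())
            out[f"spatial_corr_{layer}_curve"] = sc
        except ValueError:
            out[f"spatial_corr_{layer}"] = float("nan")
    uniq = list(dict.fromkeys(layers))
    if len(uniq) == 2:
        core, matrix = per_layer_events[uniq[0]], per_layer_events[uniq[1]]
        out["p_core_given_matrix"] = st.cooccurrence_probability(matrix, core)
        out["p_matrix_given_core"] = st.cooccurrence_probability(core, matrix)
        delays = st.onset_delays(core, matrix)
        out["delays"] = delays
        out["mean_delay"] = float(delays.mean()) if len(delays) else float("nan")
    return out


def run_condition(spec: NetworkSpec, config: SimConfig,
                  detector: DetectorParams | None = None) -> dict:
    """Build, simulate and analyze one condition."""
    net = build_network(spec)
    res = run_simulation(net, config)
    out = analyze_result(res, detector)
    out["config_hash"] = config_hash(spec, config)
    out["seed"] = config.seed
    out["result"] = res
    return out


def _summary_row(out: dict) -> dict:
    keep = ("density_L34", "density_L5", "duration_L34", "duration_L5",
            "p_core_given_matrix", "p_matrix_given_core", "mean_delay",
            "spatial_corr_L34", "spatial_corr_L5", "config_hash", "seed")
    return {k: out.get(k) for k in keep}


def fanout_sweep(sweep: SweepSpec) -> pd.DataFrame:
    """Fig-style fanout experiment: matrix radii scale with the ratio,
    core radii stay fixed.  Returns one row per (ratio, seed)."""
    rows = []
    for ratio in sweep.values:
        if ratio in FANOUT_RADII:
            r = FANOUT_RADII[ratio]
        else:
            r = (10, 2, 10 * ratio, 2 * ratio)
        spec = replace(
            NetworkSpec(),
            radius_tc_core=r[0], radius_ct_core=r[1],
            radius_tc_matrix=r[2], radius_ct_matrix=r[3],
        ).scaled(sweep.scale)
        if spec.radius_tc_matrix * spec.n_py_per_layer / spec.n_tc_per_system < 1:
            raise ValueError(
                f"ratio {ratio}: scaled matrix radius below one index unit")
        for seed in sweep.seeds:
            out = run_condition(spec, _sim_config(sweep, seed))
            rows.append({"ratio": ratio, **_summary_row(out)})
    return pd.DataFrame(rows)


def interlaminar_sweep(direction: str, sweep: SweepSpec) -> pd.DataFrame:
    """Scale the interlaminar AMPA+NMDA totals in one direction.

    ``direction`` is ``"up"`` (L3/4 -> L5) or ``"down"`` (L5 -> L3/4);
    sweep values are percentages (100 = baseline = half the intralaminar
    strength)."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    rows = []
    for pct in sweep.values:
        kw = {f"interlaminar_{direction}": pct / 100.0}
        spec = replace(NetworkSpec(), **kw).scaled(sweep.scale)
        for seed in sweep.seeds:
            out = run_condition(spec, _sim_config(sweep, seed))
            rows.append({"strength_pct": pct, "direction": direction,
                         **_summary_row(out)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-layer reduced model
# ---------------------------------------------------------------------------

def one_layer_network(
    spec: NetworkSpec,
    tc_strength: float = 1.0,
    ct_strength: float = 1.0,
    tc_radius: float | None = None,
    ct_radius: float | None = None,
    normalize: bool = False,
) -> Network:
    """Single cortical layer + one thalamic system, direct reciprocal loop.

    Synaptic totals are multiplied by ``tc_strength`` (thalamus -> cortex)
    and ``ct_strength`` (cortex -> thalamus); with ``normalize=False`` the
    per-synapse weight equals the rule total regardless of fanout.
    """
    g = spec.conductances
    tc_r = tc_radius if tc_radius is not None else spec.radius_tc_core
    ct_r = ct_radius if ct_radius is not None else spec.radius_ct_core
    pops = [
        Population("PY_L34", spec.n_py_per_layer),
        Population("IN_L34", spec.n_in_per_layer),
        Population("TC_core", spec.n_tc_per_system),
        Population("RE_core", spec.n_re_per_system),
    ]
    # per-synapse weights at the unnormalized default: the rule totals divided
    # by the baseline input count, so strength multipliers stay comparable
    rules = [
        ConnectionRule("PY_L34", "PY_L34", "AMPA", spec.radius_py_py,
                       g["py_py_ampa"], True, depressing=True, minis=True),
        ConnectionRule("PY_L34", "PY_L34", "NMDA", spec.radius_py_py,
                       g["py_py_nmda"], True, depressing=True),
        ConnectionRule("PY_L34", "IN_L34", "AMPA", spec.radius_py_in,
                       g["py_in_ampa"], True, minis=True),
        ConnectionRule("PY_L34", "IN_L34", "NMDA", spec.radius_py_in,
                       g["py_in_nmda"], True),
        ConnectionRule("IN_L34", "PY_L34", "GABA_A", spec.radius_in_py,
                       g["in_py_gabaa"], True, minis=True),
        ConnectionRule("TC_core", "PY_L34", "AMPA", tc_r,
                       _per_syn(g["tc_py_ampa"], normalize) * tc_strength, normalize),
        ConnectionRule("TC_core", "IN_L34", "AMPA", tc_r,
                       _per_syn(g["tc_in_ampa"], normalize) * tc_strength, normalize),
        ConnectionRule("PY_L34", "TC_core", "AMPA", ct_r,
                       _per_syn(g["py_tc_ampa"], normalize) * ct_strength, normalize),
        ConnectionRule("PY_L34", "RE_core", "AMPA", ct_r,
                       _per_syn(g["py_re_ampa"], normalize) * ct_strength, normalize),
        ConnectionRule("TC_core", "RE_core", "AMPA", spec.radius_thal,
                       g["tc_re_ampa"], True),
        ConnectionRule("RE_core", "TC_core", "GABA_A", spec.radius_thal,
                       g["re_tc_gabaa"], True),
        ConnectionRule("RE_core", "TC_core", "GABA_B", spec.radius_thal,
                       g["re_tc_gabab"], True),
        ConnectionRule("RE_core", "RE_core", "GABA_A", spec.radius_thal,
                       g["re_re_gabaa"], True),
    ]
    return Network(pops, rules)


def _per_syn(g_total: float, normalize: bool, typical_inputs: int = 10) -> float:
    # without normalization the rule value is the per-synapse weight; use the
    # baseline total split over a typical input count so strength sweeps start
    # from a comparable operating point
    return g_total if normalize else g_total / typical_inputs


def one_layer_model(
    sweep: SweepSpec,
    tc_strengths: tuple[float, ...] = (1.0,),
    ct_strengths: tuple[float, ...] = (1.0,),
    tc_radii: tuple[float, ...] | None = None,
    normalize: bool = False,
) -> pd.DataFrame:
    """Reduced-model sweeps over TC/CT strength and fanout.

    Reports spindle density, duration, mean ISI and cross-channel phase
    locking (mean spindle-epoch LFP correlation) of the single cortical
    layer, one row per condition and seed."""
    base = NetworkSpec().scaled(sweep.scale)
    rows = []
    conditions = []
    for ts in tc_strengths:
        for cs in ct_strengths:
            conditions.append({"tc_strength": ts, "ct_strength": cs,
                               "tc_radius": None})
    if tc_radii:
        for r in tc_radii:
            conditions.append({"tc_strength": 1.0, "ct_strength": 1.0,
                               "tc_radius": r})
    for cond in conditions:
        net = one_layer_network(
            base, tc_strength=cond["tc_strength"],
            ct_strength=cond["ct_strength"],
            tc_radius=cond["tc_radius"], normalize=normalize,
        )
        for seed in sweep.seeds:
            res = run_simulation(net, _sim_config(sweep, seed))
            out = analyze_result(res, n_groups=10, layers=("L34",))
            isi = out["isi_L34"]
            rows.append({
                "tc_strength": cond["tc_strength"],
                "ct_strength": cond["ct_strength"],
                "tc_radius": cond["tc_radius"] if cond["tc_radius"] is not None
                             else base.radius_tc_core,
                "seed": seed,
                "density": out["density_L34"],
                "duration": out["duration_L34"],
                "mean_isi": float(np.mean(isi)) if len(isi) else float("nan"),
                "phase_locking": out["spatial_corr_L34"],
            })
    return pd.DataFrame(rows)
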