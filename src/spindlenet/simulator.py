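"""Time-stepped integration of the full thalamocortical network.

``run_simulation`` packs a built :class:`~spindlenet.network.Network` and a
:class:`SimConfig` into flat arrays, advances them with the numba kernel,
and returns a :class:`SimResult` holding the spike raster, the dendritic
synaptic currents of the recorded pyramidal layers (the LFP source signal,
downsampled to the recording rate) and optional voltage traces.

Determinism: the kernel draws all randomness from a single seeded stream,
and initial-state jitter uses a separate seeded generator, so a given
(network, config) pair reproduces bit-identical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels, cells
from ._rates import (
    CA_DRIVE_CORT,
    CA_DRIVE_THAL,
    CA_INF,
    IH_GINC,
    IH_K1,
    IH_K2,
    IH_K3,
    IH_K4,
    build_tables,
)
from .network import Network
from .synapses import RECEPTOR_DEFAULTS, GababParams

__all__ = ["SimConfig", "SimResult", "run_simulation", "extract_spikes"]


@dataclass(frozen=True)
class SimConfig:
    """Integration and recording settings.

    ``duration`` and ``transient_discard`` are in seconds of model time;
    the transient is simulated but stripped from all outputs.  ``dt`` is
    the integration step in ms; 0.025 ms keeps the stiff axo-somatic
    compartment accurate under the exponential-Euler update.  ``mini_amp``
    is the open-fraction increment delivered by one miniature release
    (for comparison, an evoked release transiently opens roughly 0.15 of
    the channels of one synapse).
    """

    dt: float = 0.025
    duration: float = 20.0
    transient_discard: float = 5.0
    seed: int = 0
    record_rate: float = 1000.0          # Hz, for currents/voltages
    record_layers: tuple[str, ...] = ("L34", "L5")
    record_v: tuple[tuple[str, int], ...] = ()
    v_jitter: float = 2.0                # mV, symmetry-breaking initial jitter
    v_init_offset: tuple[tuple[str, float], ...] = ()  # (population, mV) kicks at t=0
    mini_amp: float = 0.1
    spike_threshold: float = -20.0
    refractory: float = 2.0              # ms
    tc_params: cells.ThalamicCellParams = field(default_factory=cells.ThalamicCellParams.tc)
    re_params: cells.ThalamicCellParams = field(default_factory=cells.ThalamicCellParams.re)
    py_params: cells.CorticalCellParams = field(default_factory=cells.CorticalCellParams.py)
    in_params: cells.CorticalCellParams = field(default_factory=cells.CorticalCellParams.inh)
    gabab: GababParams = field(default_factory=GababParams)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= self.transient_discard:
            raise ValueError("duration must exceed transient_discard")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimResult:
    """Output of one network simulation (transient already stripped).

    ``spikes`` has columns (population, index_in_pop, time_ms) with time
    measured from the end of the transient.  ``lfp_currents`` maps a
    recorded layer to an (n_cells, n_samples) float32 array of dendritic
    synaptic currents (uA, inward negative) at ``record_rate``.
    """

    spikes: pd.DataFrame
    lfp_currents: dict[str, np.ndarray]
    v_traces: dict[str, np.ndarray]
    record_rate: float
    duration: float             # analyzed seconds (post-transient)
    config: SimConfig
    status: str = "ok"

    def spike_times(self, population: str, index: int | None = None) -> np.ndarray:
        sel = self.spikes[self.spikes.population == population]
        if index is not None:
            sel = sel[sel.index_in_pop == index]
        return sel.time_ms.to_numpy()

    def population_rate(self, population: str, n_cells: int) -> float:
        """Mean firing rate (Hz) over the analyzed window."""
        n = int((self.spikes.population == population).sum())
        return n / n_cells / self.duration


def extract_spikes(
    v: np.ndarray, rate: float, threshold: float = -20.0, refractory: float = 2.0
) -> np.ndarray:
    """Spike times (ms) from a uniformly sampled voltage trace.

    Upward threshold crossings; crossings closer than ``refractory`` ms to
    the previous accepted spike are discarded.
    """
    v = np.asarray(v, dtype=float)
    idx = np.flatnonzero((v[:-1] <= threshold) & (v[1:] > threshold)) + 1
    times = idx * 1000.0 / rate
    out = []
    last = -np.inf
    for t in times:
        if t - last > refractory:
            out.append(t)
            last = t
    return np.asarray(out)


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

_REST_CACHE: dict = {}


def _class_rest(params) -> dict:
    """Relaxed resting state per cell class (cached per parameter set)."""
    if params not in _REST_CACHE:
        if isinstance(params, cells.ThalamicCellParams):
            st = cells.resting_state(params, relax_ms=3000.0, dt=0.05)
            _REST_CACHE[params] = {"v": st.v, "gating": dict(st.gating), "ca": st.ca}
        else:
            soma, dend = cells.resting_state(params, relax_ms=3000.0, dt=0.05)
            _REST_CACHE[params] = {
                "vs": soma.v, "vd": dend.v, "soma": dict(soma.gating),
                "dend": dict(dend.gating), "ca": dend.ca,
            }
    return _REST_CACHE[params]


def run_simulation(net: Network, config: SimConfig | None = None) -> SimResult:
    """Integrate ``net`` for ``config.duration`` seconds of model time."""
    cfg = config if config is not None else SimConfig()
    dt = cfg.dt
    rng = np.random.default_rng(cfg.seed)

    pops = net.populations
    cortical = [p for p in pops if p.cell_class in ("PY", "IN")]
    thalamic = [p for p in pops if p.cell_class in ("TC", "RE")]
    n_c = sum(p.size for p in cortical)
    n_t = sum(p.size for p in thalamic)

    goff: dict[str, int] = {}
    off = 0
    for p in cortical:
        goff[p.name] = off
        off += p.size
    toff: dict[str, int] = {}
    off = 0
    for p in thalamic:
        toff[p.name] = off
        off += p.size

    # -- cortical parameter arrays ---------------------------------------
    c_eleak = np.empty(n_c)
    c_gnap_s = np.empty(n_c)
    c_gnap_d = np.empty(n_c)
    c_gcs = np.empty(n_c)
    c_gcd = np.empty(n_c)
    c_area_d = np.empty(n_c)
    for p in cortical:
        par = cfg.py_params if p.cell_class == "PY" else cfg.in_params
        sl = slice(goff[p.name], goff[p.name] + p.size)
        c_eleak[sl] = par.e_leak
        c_gnap_s[sl] = par.g_nap_soma
        c_gnap_d[sl] = par.g_nap_dend
        c_gcs[sl] = par.g_c_soma
        c_gcd[sl] = par.g_c_dend
        c_area_d[sl] = par.s_dend

    # -- cortical state ---------------------------------------------------
    vs = np.empty(n_c)
    vd = np.empty(n_c)
    s_m, s_h, s_n, s_p = (np.empty(n_c) for _ in range(4))
    d_m, d_h, d_p, d_km, d_kca, d_hm, d_hh = (np.empty(n_c) for _ in range(7))
    d_ca = np.full(n_c, CA_INF)
    for p in cortical:
        par = cfg.py_params if p.cell_class == "PY" else cfg.in_params
        rest = _class_rest(par)
        sl = slice(goff[p.name], goff[p.name] + p.size)
        jit = rng.uniform(-cfg.v_jitter, cfg.v_jitter, p.size)
        vs[sl] = rest["vs"] + jit
        vd[sl] = rest["vd"] + jit
        for arr, k in ((s_m, "m"), (s_h, "h"), (s_n, "n"), (s_p, "mnap")):
            arr[sl] = rest["soma"][k]
        for arr, k in ((d_m, "m"), (d_h, "h"), (d_p, "mnap"), (d_km, "mkm"),
                       (d_kca, "mkca"), (d_hm, "mhva"), (d_hh, "hhva")):
            arr[sl] = rest["dend"][k]
        d_ca[sl] = rest["ca"]

    # -- thalamic parameter arrays ----------------------------------------
    t_is_tc = np.zeros(n_t, dtype=np.uint8)
    t_gleak, t_eleak, t_gkl, t_gna, t_gk, t_gt, t_gh, t_area = (
        np.empty(n_t) for _ in range(8))
    for p in thalamic:
        par = cfg.tc_params if p.cell_class == "TC" else cfg.re_params
        sl = slice(toff[p.name], toff[p.name] + p.size)
        t_is_tc[sl] = 1 if p.cell_class == "TC" else 0
        t_gleak[sl] = par.g_leak
        t_eleak[sl] = par.e_leak
        t_gkl[sl] = par.g_kl
        t_gna[sl] = par.g_na
        t_gk[sl] = par.g_k
        t_gt[sl] = par.g_t
        t_gh[sl] = par.g_h
        t_area[sl] = par.area

    tv = np.empty(n_t)
    t_m, t_h, t_n, t_tm, t_th = (np.empty(n_t) for _ in range(5))
    t_ca = np.full(n_t, CA_INF)
    t_o1 = np.zeros(n_t)
    t_p1 = np.zeros(n_t)
    t_o2 = np.zeros(n_t)
    for p in thalamic:
        par = cfg.tc_params if p.cell_class == "TC" else cfg.re_params
        rest = _class_rest(par)
        sl = slice(toff[p.name], toff[p.name] + p.size)
        tv[sl] = rest["v"] + rng.uniform(-cfg.v_jitter, cfg.v_jitter, p.size)
        g = rest["gating"]
        t_m[sl], t_h[sl], t_n[sl] = g["m"], g["h"], g["n"]
        t_tm[sl], t_th[sl] = g["mt"], g["ht"]
        t_o1[sl], t_p1[sl], t_o2[sl] = g["o1"], g["p1"], g["o2"]
        t_ca[sl] = rest["ca"]

    for pname, dv in cfg.v_init_offset:
        if pname in goff:
            sl = slice(goff[pname], goff[pname] + net.size(pname))
            vs[sl] += dv
            vd[sl] += dv
        else:
            sl = slice(toff[pname], toff[pname] + net.size(pname))
            tv[sl] += dv

    # -- synapses ----------------------------------------------------------
    names = [p.name for p in pops]
    is_cortical_pop = np.array([p.cell_class in ("PY", "IN") for p in pops])
    ns = net.n_edges

    s_pre = np.empty(ns, dtype=np.int64)
    s_post = np.empty(ns, dtype=np.int64)
    s_postkind = np.empty(ns, dtype=np.uint8)
    s_area = np.empty(ns)
    pre_cortical = is_cortical_pop[net.pre_pop]
    post_cortical = is_cortical_pop[net.post_pop]
    goff_arr = np.array([goff.get(nm, 0) for nm in names], dtype=np.int64)
    toff_arr = np.array([toff.get(nm, 0) for nm in names], dtype=np.int64)
    s_pre = np.where(
        pre_cortical,
        goff_arr[net.pre_pop] + net.pre_idx,
        n_c + toff_arr[net.pre_pop] + net.pre_idx,
    ).astype(np.int64)
    cort_post = goff_arr[net.post_pop] + net.post_idx
    thal_post = toff_arr[net.post_pop] + net.post_idx
    s_post = np.where(post_cortical, cort_post, thal_post).astype(np.int64)
    s_postkind = np.where(post_cortical, 0, 1).astype(np.uint8)
    cort_area = c_area_d[np.clip(cort_post, 0, n_c - 1)] if n_c else np.zeros(ns)
    thal_area = t_area[np.clip(thal_post, 0, n_t - 1)] if n_t else np.zeros(ns)
    s_area = np.where(post_cortical, cort_area, thal_area)

    s_rec = net.receptor.astype(np.uint8)
    s_w = net.weight.astype(float)
    s_dep = net.depressing.astype(np.uint8)
    s_E = net.e_syn.astype(float)
    syn_o = np.zeros(ns)
    syn_d = np.ones(ns)
    syn_tlast = np.full(ns, -1e9)
    syn_r = np.zeros(ns)
    syn_g = np.zeros(ns)
    mini_sidx = np.flatnonzero(net.minis).astype(np.int64)
    mini_next = np.full(ns, -1.0)
    mini_t0 = np.full(ns, -1e4)   # start fully recovered

    # CSR adjacency: presynaptic global cell -> its synapses
    order = np.argsort(s_pre, kind="stable").astype(np.int64)
    pre_counts = np.bincount(s_pre, minlength=n_c + n_t)
    pre_ptr = np.zeros(n_c + n_t + 1, dtype=np.int64)
    np.cumsum(pre_counts, out=pre_ptr[1:])

    # -- receptor constants ------------------------------------------------
    rec_alpha = np.array([RECEPTOR_DEFAULTS["AMPA"].alpha,
                          RECEPTOR_DEFAULTS["NMDA"].alpha,
                          RECEPTOR_DEFAULTS["GABA_A"].alpha, 0.0])
    rec_beta = np.array([RECEPTOR_DEFAULTS["AMPA"].beta,
                         RECEPTOR_DEFAULTS["NMDA"].beta,
                         RECEPTOR_DEFAULTS["GABA_A"].beta, 0.0])
    gb = cfg.gabab

    # -- recording ----------------------------------------------------------
    record_every = max(int(round(1000.0 / (cfg.record_rate * dt))), 1)
    actual_rate = 1000.0 / (record_every * dt)
    n_steps = int(round(cfg.duration * 1000.0 / dt))
    n_bins = (n_steps + record_every - 1) // record_every

    rec_rows = np.full(n_c, -1, dtype=np.int64)
    layer_rows: dict[str, tuple[int, int]] = {}
    row = 0
    for layer in cfg.record_layers:
        pname = f"PY_{layer}"
        if pname not in goff:
            continue
        size = net.size(pname)
        rec_rows[goff[pname]: goff[pname] + size] = np.arange(row, row + size)
        layer_rows[layer] = (row, row + size)
        row += size
    rec_i = np.zeros((row, n_bins), dtype=np.float64)

    vrec_kind = np.empty(len(cfg.record_v), dtype=np.uint8)
    vrec_idx = np.empty(len(cfg.record_v), dtype=np.int64)
    for k, (pname, idx) in enumerate(cfg.record_v):
        if pname in goff:
            vrec_kind[k] = 0
            vrec_idx[k] = goff[pname] + idx
        else:
            vrec_kind[k] = 1
            vrec_idx[k] = toff[pname] + idx
    rec_v = np.zeros((len(cfg.record_v), n_bins), dtype=np.float64)

    cap = int(min((n_c + n_t) * cfg.duration * 100 + 10000, 3e7))
    spk_cell = np.empty(cap, dtype=np.int64)
    spk_t = np.empty(cap, dtype=np.float64)
    last_spk = np.full(n_c + n_t, -1e9)

    tab_vmin, tab_inv_step, tab_inf, tab_rl = build_tables(dt)

    py = cfg.py_params
    n_spk, status, where = _kernels.run_network(
        n_c, n_t, dt, n_steps, int(cfg.seed) % (2 ** 31 - 1), record_every,
        c_eleak, c_gnap_s, c_gnap_d, c_gcs, c_gcd, c_area_d,
        py.g_na_soma, py.g_k_soma, py.g_na_dend, py.g_l_dend, py.g_kl_dend,
        py.g_hva_dend, py.g_kca_dend, py.g_km_dend,
        py.cm_soma, py.cm_dend, py.ca_tau, CA_DRIVE_CORT, py.e_kl,
        vs, vd, s_m, s_h, s_n, s_p, d_m, d_h, d_p, d_km, d_kca, d_hm, d_hh, d_ca,
        t_is_tc, t_gleak, t_eleak, t_gkl, t_gna, t_gk, t_gt, t_gh, t_area,
        cfg.tc_params.ca_tau, CA_DRIVE_THAL, IH_K1, IH_K2, IH_K3, IH_K4, IH_GINC,
        tv, t_m, t_h, t_n, t_tm, t_th, t_ca, t_o1, t_p1, t_o2,
        tab_vmin, tab_inv_step, tab_inf, tab_rl,
        s_pre, s_postkind, s_post, s_rec, s_w, s_dep, s_E, s_area,
        syn_o, syn_d, syn_tlast, syn_r, syn_g,
        mini_sidx, mini_next, mini_t0, cfg.mini_amp,
        pre_ptr, order,
        rec_alpha, rec_beta, RECEPTOR_DEFAULTS["AMPA"].t_max, -25.0, 12.5,
        gb.k1, gb.k2, gb.k3, gb.k4, gb.kd, 0.2, 500.0,
        rec_rows, rec_i, vrec_kind, vrec_idx, rec_v,
        spk_cell, spk_t, last_spk, cfg.spike_threshold, cfg.refractory,
        np.zeros(n_c), np.zeros(n_c), np.zeros(n_c),
        np.zeros(n_t), np.zeros(n_t), np.zeros(n_t),
        np.zeros(n_c, dtype=np.uint8), np.zeros(n_t, dtype=np.uint8),
    )
    if status == 2:
        raise RuntimeError(f"numerical blow-up: |V| > 150 mV at global cell {where}")
    result_status = "ok" if status == 0 else "spike-buffer-overflow"

    # -- unpack, strip transient -------------------------------------------
    trans_ms = cfg.transient_discard * 1000.0
    cell_ids = spk_cell[:n_spk]
    times = spk_t[:n_spk]
    keep = times >= trans_ms

    bounds = [(goff[p.name], goff[p.name] + p.size, p.name) for p in cortical]
    bounds += [(n_c + toff[p.name], n_c + toff[p.name] + p.size, p.name)
               for p in thalamic]
    cid = cell_ids[keep]
    pop_col = np.empty(len(cid), dtype=object)
    idx_col = np.empty(len(cid), dtype=np.int64)
    for lo, hi, name in bounds:
        m = (cid >= lo) & (cid < hi)
        pop_col[m] = name
        idx_col[m] = cid[m] - lo
    spikes = pd.DataFrame({
        "population": pop_col,
        "index_in_pop": idx_col,
        "time_ms": times[keep] - trans_ms,
    }).sort_values("time_ms", ignore_index=True)

    skip_bins = int(round(cfg.transient_discard * actual_rate))
    lfp_currents = {
        layer: rec_i[a:b, skip_bins:].astype(np.float32)
        for layer, (a, b) in layer_rows.items()
    }
    v_traces = {
        f"{pname}[{idx}]": rec_v[k, skip_bins:].copy()
        for k, (pname, idx) in enumerate(cfg.record_v)
    }

    result = SimResult(
        spikes=spikes,
        lfp_currents=lfp_currents,
        v_traces=v_traces,
        record_rate=actual_rate,
        duration=cfg.duration - cfg.transient_discard,
        config=cfg,
        status=result_status,
    )
    result.final_state = {
        "vs": vs, "vd": vd, "tv": tv, "t_o1": t_o1, "t_p1": t_p1,
        "t_o2": t_o2, "t_ca": t_ca, "t_th": t_th, "syn_g": syn_g,
        "syn_r": syn_r, "syn_o": syn_o, "syn_d": syn_d, "d_ca": d_ca,
    }
    return result
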