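"""Numba time-stepping kernel for the full network.

One fused loop advances every cell and synapse with a fixed step:
voltages by exponential Euler (conductances frozen over the step, which
makes the stiff axo-somatic compartment relax to its quasi-steady value),
gating variables by Rush-Larsen with table-interpolated steady states and
relaxation factors, and synapse open fractions by forward Euler.  Synapses
are skipped while fully closed, so the cost per step tracks network
activity rather than synapse count.

All randomness (miniature-release times, nothing else) is drawn from
numba's per-thread numpy RandomState, seeded once at kernel entry:
identical inputs and seed give bit-identical trajectories.

Unit conventions: mV, ms, mS/cm^2 for densities, uS for absolute synaptic
conductances, uA/cm^2 for current densities, mM for Ca.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._rates import (
    G_C_HVA_H, G_C_HVA_M, G_C_K_N, G_C_KM_N, G_C_NA_H, G_C_NA_M, G_C_NAP_M,
    G_RE_T_H, G_RE_T_M, G_TC_H_O, G_TC_T_H, G_TC_T_M, G_THAL_K_N,
    G_THAL_NA_H, G_THAL_NA_M,
)

# receptor codes (match network.RECEPTORS order)
REC_AMPA, REC_NMDA, REC_GABA_A, REC_GABA_B = 0, 1, 2, 3

E_NA = 50.0
E_K_THAL = -95.0
E_K_CORT = -90.0
E_H = -40.0
CA_OUT = 2.0
CA_INF = 2.4e-4
NERNST_CA = 13.31

O_EPS = 1e-6     # open fraction below which a synapse is idle
G_EPS = 5e-2     # GABA-B G-protein level below which conductance is negligible
MINI_RATE_MAX = 1.0 / 250.0


@njit(cache=True, fastmath=True)
def _lk(tab, gate, v, vmin, inv_step, npts):
    """Linear interpolation into a (gate, voltage) table."""
    x = (v - vmin) * inv_step
    if x < 0.0:
        x = 0.0
    elif x > npts - 1.001:
        x = npts - 1.001
    i0 = int(x)
    f = x - i0
    return tab[gate, i0] * (1.0 - f) + tab[gate, i0 + 1] * f


@njit(cache=True, fastmath=True)
def run_network(
    # -- sizes / timing
    n_c, n_t, dt, n_steps, seed, record_every,
    # -- cortical per-cell parameters
    c_eleak, c_gnap_s, c_gnap_d, c_gcs, c_gcd, c_area_d,
    # -- cortical scalar parameters
    gna_s, gk_s, gna_d, gl_d, gkl_d, ghva_d, gkca_d, gkm_d,
    cm_s, cm_d, ca_tau_c, ca_drive_c, e_kl,
    # -- cortical state (modified in place)
    vs, vd, s_m, s_h, s_n, s_p, d_m, d_h, d_p, d_km, d_kca, d_hm, d_hh, d_ca,
    # -- thalamic per-cell parameters
    t_is_tc, t_gleak, t_eleak, t_gkl, t_gna, t_gk, t_gt, t_gh, t_area,
    # -- thalamic scalars
    ca_tau_t, ca_drive_t, ih_k1, ih_k2, ih_k3, ih_k4, ih_ginc,
    # -- thalamic state
    tv, t_m, t_h, t_n, t_tm, t_th, t_ca, t_o1, t_p1, t_o2,
    # -- gating tables
    tab_vmin, tab_inv_step, tab_inf, tab_rl,
    # -- synapses
    s_pre, s_postkind, s_post, s_rec, s_w, s_dep, s_E, s_area,
    syn_o, syn_d, syn_tlast, syn_r, syn_g,
    mini_sidx, mini_next, mini_t0, mini_amp,
    pre_ptr, pre_sidx,
    # -- receptor constants
    rec_alpha, rec_beta, t_pulse, nmda_vth, nmda_delta,
    gb_k1, gb_k2, gb_k3, gb_k4, gb_kd, dep_u, dep_tau,
    # -- recording
    rec_rows, rec_i, vrec_kind, vrec_idx, rec_v,
    spk_cell, spk_t, last_spk, spike_thresh, refractory,
    # -- scratch (preallocated by caller)
    acc_g, acc_ge, acc_isyn, acc_gt, acc_get, acc_isynt,
    prev_fire_c, prev_fire_t,
):
    """Advance the network ``n_steps`` steps.  Returns (n_spikes, status, where)
    with status 0 = ok, 1 = spike-buffer overflow, 2 = voltage blow-up."""
    np.random.seed(seed)
    npts = tab_inf.shape[1]
    n_spk = 0
    status = 0
    where = -1
    n_mini = mini_sidx.shape[0]
    n_bins = rec_i.shape[1] if rec_i.shape[0] > 0 else (n_steps + record_every - 1) // record_every
    inv_re = 1.0 / record_every

    # initialize mini candidate times
    for k in range(n_mini):
        if mini_next[mini_sidx[k]] < 0.0:
            mini_next[mini_sidx[k]] = -math.log(np.random.random()) / MINI_RATE_MAX

    for step in range(n_steps):
        t = step * dt
        bin_idx = step // record_every
        if bin_idx >= n_bins:
            bin_idx = n_bins - 1

        # -- reset accumulators -------------------------------------------
        for i in range(n_c):
            acc_g[i] = 0.0
            acc_ge[i] = 0.0
            acc_isyn[i] = 0.0
        for i in range(n_t):
            acc_gt[i] = 0.0
            acc_get[i] = 0.0
            acc_isynt[i] = 0.0

        # -- miniature releases -------------------------------------------
        for k in range(n_mini):
            s = mini_sidx[k]
            if t >= mini_next[s]:
                # thinning: accept with mu(t - t0)/mu_max
                rel = t - mini_t0[s]
                mu = (2.0 / (1.0 + math.exp(-rel / 400.0)) - 1.0) / 250.0
                if mu > 0.0 and np.random.random() * MINI_RATE_MAX < mu:
                    syn_o[s] += mini_amp * (1.0 - syn_o[s])
                mini_next[s] = t - math.log(np.random.random()) / MINI_RATE_MAX

        # -- synapse accumulation and state update ------------------------
        ns = s_pre.shape[0]
        for s in range(ns):
            rec = s_rec[s]
            o = syn_o[s]
            g_level = syn_g[s]
            pre = s_pre[s]
            if pre < n_c:
                pre_on = vs[pre] > 0.0
            else:
                pre_on = tv[pre - n_c] > 0.0
            if (not pre_on) and o <= O_EPS and (rec != REC_GABA_B or
                                                (g_level <= G_EPS and syn_r[s] <= 1e-6)):
                continue

            post = s_post[s]
            if s_postkind[s] == 0:
                v_post = vd[post]
            else:
                v_post = tv[post]

            # conductance contribution (uS)
            if rec == REC_GABA_B:
                g4 = g_level ** 4
                geff = s_w[s] * g4 / (g4 + gb_kd)
            else:
                geff = s_w[s] * syn_d[s] * o
                if rec == REC_NMDA:
                    geff *= 1.0 / (1.0 + math.exp(-(v_post - nmda_vth) / nmda_delta))
            if geff > 0.0:
                ga = geff * 1e-3 / s_area[s]  # mS/cm^2 on the target compartment
                if s_postkind[s] == 0:
                    acc_g[post] += ga
                    acc_ge[post] += ga * s_E[s]
                    acc_isyn[post] += geff * (v_post - s_E[s]) * 1e-3  # uA
                else:
                    acc_gt[post] += ga
                    acc_get[post] += ga * s_E[s]
                    acc_isynt[post] += geff * (v_post - s_E[s]) * 1e-3

            # kinetics update
            trans = t_pulse if pre_on else 0.0
            if rec == REC_GABA_B:
                r = syn_r[s]
                syn_r[s] = r + dt * (gb_k1 * trans * (1.0 - r) - gb_k2 * r)
                syn_g[s] = g_level + dt * (gb_k3 * r - gb_k4 * g_level)
            else:
                do = rec_alpha[rec] * trans * (1.0 - o) - rec_beta[rec] * o
                o = o + dt * do
                if o < 0.0:
                    o = 0.0
                elif o > 1.0:
                    o = 1.0
                syn_o[s] = o

        # -- cortical cells -----------------------------------------------
        for i in range(n_c):
            v_s = vs[i]
            v_d = vd[i]
            # soma conductances
            g_na = gna_s * s_m[i] * s_m[i] * s_m[i] * s_h[i]
            g_k = gk_s * s_n[i]  # first-order delayed rectifier
            g_p = c_gnap_s[i] * s_p[i]
            gtot = g_na + g_p + g_k + c_gcs[i]
            ge = (g_na + g_p) * E_NA + g_k * E_K_CORT + c_gcs[i] * v_d
            vinf = ge / gtot
            new_vs = vinf + (v_s - vinf) * math.exp(-dt * gtot / cm_s)
            # dendrite conductances
            eca = NERNST_CA * math.log(CA_OUT / max(d_ca[i], 1e-8))
            g_nad = gna_d * d_m[i] * d_m[i] * d_m[i] * d_h[i]
            g_pd = c_gnap_d[i] * d_p[i]
            g_hva = ghva_d * d_hm[i] * d_hm[i] * d_hh[i]
            g_kca = gkca_d * d_kca[i]
            g_km = gkm_d * d_km[i]
            gsyn = acc_g[i]
            gtot_d = (gl_d + gkl_d + g_nad + g_pd + g_hva + g_kca + g_km
                      + c_gcd[i] + gsyn)
            ge_d = (gl_d * c_eleak[i] + gkl_d * e_kl + (g_nad + g_pd) * E_NA
                    + g_hva * eca + (g_kca + g_km) * E_K_CORT
                    + c_gcd[i] * v_s + acc_ge[i])
            vinf_d = ge_d / gtot_d
            new_vd = vinf_d + (v_d - vinf_d) * math.exp(-dt * gtot_d / cm_d)
            vs[i] = new_vs
            vd[i] = new_vd

            i_hva = g_hva * (v_d - eca)
            dca = (CA_INF - d_ca[i]) / ca_tau_c
            if i_hva < 0.0:
                dca -= ca_drive_c * i_hva
            d_ca[i] += dt * dca

            # gating (Rush-Larsen via tables)
            inf = _lk(tab_inf, G_C_NA_M, v_s, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_C_NA_M, v_s, tab_vmin, tab_inv_step, npts)
            s_m[i] = inf + (s_m[i] - inf) * rl
            inf = _lk(tab_inf, G_C_NA_H, v_s, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_C_NA_H, v_s, tab_vmin, tab_inv_step, npts)
            s_h[i] = inf + (s_h[i] - inf) * rl
            inf = _lk(tab_inf, G_C_K_N, v_s, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_C_K_N, v_s, tab_vmin, tab_inv_step, npts)
            s_n[i] = inf + (s_n[i] - inf) * rl
            inf = _lk(tab_inf, G_C_NAP_M, v_s, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_C_NAP_M, v_s, tab_vmin, tab_inv_step, npts)
            s_p[i] = inf + (s_p[i] - inf) * rl

            inf = _lk(tab_inf, G_C_NA_M, v_d, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_C_NA_M, v_d, tab_vmin, tab_inv_step, npts)
            d_m[i] = inf + (d_m[i] - inf) * rl
            inf = _lk(tab_inf, G_C_NA_H, v_d, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_C_NA_H, v_d, tab_vmin, tab_inv_step, npts)
            d_h[i] = inf + (d_h[i] - inf) * rl
            inf = _lk(tab_inf, G_C_NAP_M, v_d, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_C_NAP_M, v_d, tab_vmin, tab_inv_step, npts)
            d_p[i] = inf + (d_p[i] - inf) * rl
            inf = _lk(tab_inf, G_C_KM_N, v_d, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_C_KM_N, v_d, tab_vmin, tab_inv_step, npts)
            d_km[i] = inf + (d_km[i] - inf) * rl
            inf = _lk(tab_inf, G_C_HVA_M, v_d, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_C_HVA_M, v_d, tab_vmin, tab_inv_step, npts)
            d_hm[i] = inf + (d_hm[i] - inf) * rl
            inf = _lk(tab_inf, G_C_HVA_H, v_d, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_C_HVA_H, v_d, tab_vmin, tab_inv_step, npts)
            d_hh[i] = inf + (d_hh[i] - inf) * rl
            # KCa: Ca-dependent first-order rates (forward Euler)
            a = 0.01 * d_ca[i]
            d_kca[i] += dt * 2.95 * (a * (1.0 - d_kca[i]) - 0.02 * d_kca[i])
            if d_kca[i] < 0.0:
                d_kca[i] = 0.0
            elif d_kca[i] > 1.0:
                d_kca[i] = 1.0

        # -- thalamic cells -----------------------------------------------
        for i in range(n_t):
            v = tv[i]
            g_na = t_gna[i] * t_m[i] * t_m[i] * t_m[i] * t_h[i]
            g_k = t_gk[i] * t_n[i] ** 4
            g_t = t_gt[i] * t_tm[i] * t_tm[i] * t_th[i]
            eca = NERNST_CA * math.log(CA_OUT / max(t_ca[i], 1e-8))
            gtot = t_gleak[i] + t_gkl[i] + g_na + g_k + g_t + acc_gt[i]
            ge = (t_gleak[i] * t_eleak[i] + t_gkl[i] * e_kl + g_na * E_NA
                  + g_k * E_K_THAL + g_t * eca + acc_get[i])
            if t_is_tc[i] == 1 and t_gh[i] > 0.0:
                g_h = t_gh[i] * (t_o1[i] + ih_ginc * t_o2[i])
                gtot += g_h
                ge += g_h * E_H
            vinf = ge / gtot
            tv[i] = vinf + (v - vinf) * math.exp(-dt * gtot / 1.0)  # Cm = 1

            i_t = g_t * (v - eca)
            dca = (CA_INF - t_ca[i]) / ca_tau_t
            if i_t < 0.0:
                dca -= ca_drive_t * i_t
            t_ca[i] += dt * dca

            inf = _lk(tab_inf, G_THAL_NA_M, v, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_THAL_NA_M, v, tab_vmin, tab_inv_step, npts)
            t_m[i] = inf + (t_m[i] - inf) * rl
            inf = _lk(tab_inf, G_THAL_NA_H, v, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_THAL_NA_H, v, tab_vmin, tab_inv_step, npts)
            t_h[i] = inf + (t_h[i] - inf) * rl
            inf = _lk(tab_inf, G_THAL_K_N, v, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, G_THAL_K_N, v, tab_vmin, tab_inv_step, npts)
            t_n[i] = inf + (t_n[i] - inf) * rl
            if t_is_tc[i] == 1:
                gm, gh = G_TC_T_M, G_TC_T_H
            else:
                gm, gh = G_RE_T_M, G_RE_T_H
            inf = _lk(tab_inf, gm, v, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, gm, v, tab_vmin, tab_inv_step, npts)
            t_tm[i] = inf + (t_tm[i] - inf) * rl
            inf = _lk(tab_inf, gh, v, tab_vmin, tab_inv_step, npts)
            rl = _lk(tab_rl, gh, v, tab_vmin, tab_inv_step, npts)
            t_th[i] = inf + (t_th[i] - inf) * rl
            if t_is_tc[i] == 1 and t_gh[i] > 0.0:
                h_inf = _lk(tab_inf, G_TC_H_O, v, tab_vmin, tab_inv_step, npts)
                rl = _lk(tab_rl, G_TC_H_O, v, tab_vmin, tab_inv_step, npts)
                # voltage gating toward h_inf among unlocked channels,
                # then Ca-dependent locking (forward Euler, slow rates)
                o1 = t_o1[i]
                o2 = t_o2[i]
                p1 = t_p1[i]
                o1 = h_inf * (1.0 - o2) + (o1 - h_inf * (1.0 - o2)) * rl
                o1 += dt * (-ih_k3 * p1 * o1 + ih_k4 * o2)
                p1 += dt * (ih_k1 * t_ca[i] ** 4 * (1.0 - p1) - ih_k2 * p1)
                o2 += dt * (ih_k3 * t_p1[i] * t_o1[i] - ih_k4 * o2)
                t_o1[i] = min(max(o1, 0.0), 1.0)
                t_p1[i] = min(max(p1, 0.0), 1.0)
                t_o2[i] = min(max(o2, 0.0), 1.0)

        # -- spikes, depression events, mini-rate resets -------------------
        for i in range(n_c + n_t):
            if i < n_c:
                v_now = vs[i]
            else:
                v_now = tv[i - n_c]
            fired_prev = prev_fire_c[i] if i < n_c else prev_fire_t[i - n_c]
            # raster: upward crossing of spike_thresh with refractory
            if v_now > spike_thresh and t - last_spk[i] > refractory:
                was_below = True
                if i < n_c:
                    was_below = prev_fire_c[i] == 0
                else:
                    was_below = prev_fire_t[i - n_c] == 0
                if was_below:
                    last_spk[i] = t
                    if n_spk < spk_cell.shape[0]:
                        spk_cell[n_spk] = i
                        spk_t[n_spk] = t
                        n_spk += 1
                    else:
                        status = 1
                    # presynaptic event: depression + mini-rate reset
                    for q in range(pre_ptr[i], pre_ptr[i + 1]):
                        s = pre_sidx[q]
                        if s_dep[s] == 1:
                            dlt = t - syn_tlast[s]
                            syn_d[s] = 1.0 - (1.0 - syn_d[s] * (1.0 - dep_u)) \
                                * math.exp(-dlt / dep_tau)
                        syn_tlast[s] = t
                        mini_t0[s] = t
            if i < n_c:
                prev_fire_c[i] = 1 if v_now > spike_thresh else 0
            else:
                prev_fire_t[i - n_c] = 1 if v_now > spike_thresh else 0

        # -- recording -----------------------------------------------------
        for i in range(n_c):
            row = rec_rows[i]
            if row >= 0:
                rec_i[row, bin_idx] += acc_isyn[i] * inv_re
        for k in range(vrec_idx.shape[0]):
            if vrec_kind[k] == 0:
                rec_v[k, bin_idx] += vs[vrec_idx[k]] * inv_re
            else:
                rec_v[k, bin_idx] += tv[vrec_idx[k]] * inv_re

        # -- sanity --------------------------------------------------------
        if step % 2000 == 0:
            for i in range(n_c):
                if abs(vs[i]) > 150.0 or abs(vd[i]) > 150.0 or vs[i] != vs[i]:
                    return n_spk, 2, i
            for i in range(n_t):
                if abs(tv[i]) > 150.0 or tv[i] != tv[i]:
                    return n_spk, 2, n_c + i

    return n_spk, status, where
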