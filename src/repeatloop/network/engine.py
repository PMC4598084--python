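"""Numba integration kernel for the branched-chain spiking network.

Neuron dynamics
---------------
HVC_RA (excitatory) neurons are two-compartment conductance-based models.
The soma carries standard sodium/potassium spiking currents with
Wang-Buzsaki rate kinetics; the dendrite carries a high-threshold calcium
current plus a calcium-gated potassium current, producing a stereotyped
regenerative depolarization of roughly 5 ms (a calcium spike) when driven
above threshold.  The compartments are ohmically coupled, so a dendritic
calcium spike drives a burst of somatic action potentials.  HVC_I
(inhibitory) neurons are single-compartment Wang-Buzsaki fast-spiking
neurons with an added high-threshold potassium current supporting rapid
tonic firing.

Free channel constants were calibrated against three phenomenological
targets: ~3 mV somatic subthreshold fluctuations under background noise,
~10 Hz inhibitory baseline rate, and a ~5 ms dendritic calcium spike.  The
calibrated values are frozen here; ``scripts/calibrate_network.py``
reproduces the calibration measurements.

Numerics
--------
A fourth-order Runge-Kutta step integrates membrane and gating variables
with synaptic conductances frozen over the step; conductances then decay
analytically and spike-triggered kicks (chain synapses, inhibitory loop,
noise, drive, depressing feedback) are applied before the next step.
Voltage-dependent rate functions are evaluated through precomputed lookup
tables with linear interpolation.  Spikes are detected by upward threshold
crossing at -20 mV with a 2 ms refractory period.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --- membrane constants (calibrated, frozen) -------------------------------
C_M = 1.0  # uF/cm^2

# sodium / potassium spiking currents (Wang-Buzsaki kinetics)
E_NA = 55.0
E_K = -90.0
PHI = 5.0

# excitatory soma
G_NA_E = 45.0
G_K_E = 18.0
G_L_E = 0.2
E_L_E = -80.0

# excitatory dendrite
G_L_D = 0.8
E_L_D = -80.0
G_CA = 4.0
E_CA = 120.0
G_KCA = 10.0
KD_CA = 5.0
TAU_CA = 9.0  # ms
K_CA = 0.008  # Ca influx per unit Ca current
G_C = 0.4  # soma-dendrite ohmic coupling (mS/cm^2)

# inhibitory neuron
G_NA_I = 35.0
G_K_I = 9.0
G_L_I = 1.2
E_L_I = -67.0
G_KHT = 2.0  # high-threshold potassium current
TAU_W = 2.0  # ms
E_KHT = -90.0

# synapses
E_SYN_E = 0.0
E_SYN_I = -82.0

V_SPIKE = -20.0  # detection threshold (upward crossing)
T_REFRAC = 2.0  # ms

# rate-table layout
V_MIN, V_MAX, DV = -130.0, 60.0, 0.05
N_TAB = int((V_MAX - V_MIN) / DV) + 2
ROW_AM, ROW_BM, ROW_AH, ROW_BH, ROW_AN, ROW_BN, ROW_MCA, ROW_WINF = range(8)


def build_rate_tables() -> np.ndarray:
    """Voltage-dependent rate functions tabulated on a uniform grid."""
    v = V_MIN + DV * np.arange(N_TAB)
    tab = np.empty((8, N_TAB))

    def safe_expm1_ratio(x):
        # x / (1 - exp(-x)) with the x -> 0 limit handled
        x = np.asarray(x)
        small = np.abs(x) < 1e-7
        safe = np.where(small, 1.0, x)
        return np.where(small, 1.0 + x / 2.0, safe / (1.0 - np.exp(-np.clip(safe, -500, 500))))

    tab[ROW_AM] = 1.0 * safe_expm1_ratio((v + 35.0) / 10.0)  # alpha_m = 0.1(V+35)/(1-e^..) = 1.0 * x/(1-e^-x) with x=(V+35)/10
    tab[ROW_BM] = 4.0 * np.exp(-(v + 60.0) / 18.0)
    tab[ROW_AH] = 0.07 * np.exp(-(v + 58.0) / 20.0)
    tab[ROW_BH] = 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    tab[ROW_AN] = 0.1 * safe_expm1_ratio((v + 34.0) / 10.0)  # alpha_n = 0.01(V+34)/(1-e^..)
    tab[ROW_BN] = 0.125 * np.exp(-(v + 44.0) / 80.0)
    tab[ROW_MCA] = 1.0 / (1.0 + np.exp(-(v + 40.0) / 5.0))
    tab[ROW_WINF] = 1.0 / (1.0 + np.exp(-(v + 10.0) / 5.0))
    return tab


@njit(inline="always", cache=False)
def _tb(tab, row, v):
    x = (v - V_MIN) / DV
    if x < 0.0:
        x = 0.0
    elif x > N_TAB - 2:
        x = N_TAB - 2
    i = int(x)
    f = x - i
    return tab[row, i] * (1.0 - f) + tab[row, i + 1] * f


@njit(inline="always", cache=False)
def _d_exc(tab, vs, vd, h, n, ca, ges, gis, ged, gid, i_ext_d):
    """Derivatives of one excitatory neuron's state."""
    am = _tb(tab, ROW_AM, vs)
    bm = _tb(tab, ROW_BM, vs)
    m = am / (am + bm)
    i_na = G_NA_E * m * m * m * h * (vs - E_NA)
    i_k = G_K_E * n * n * n * n * (vs - E_K)
    i_syn_s = ges * (vs - E_SYN_E) + gis * (vs - E_SYN_I)
    dvs = (
        -G_L_E * (vs - E_L_E) - i_na - i_k - G_C * (vs - vd) - i_syn_s
    ) / C_M

    mca = _tb(tab, ROW_MCA, vd)
    i_ca = G_CA * mca * mca * (vd - E_CA)
    i_kca = G_KCA * (ca / (ca + KD_CA)) * (vd - E_K)
    i_syn_d = ged * (vd - E_SYN_E) + gid * (vd - E_SYN_I)
    dvd = (
        -G_L_D * (vd - E_L_D) - i_ca - i_kca - G_C * (vd - vs) - i_syn_d + i_ext_d
    ) / C_M

    dh = PHI * (_tb(tab, ROW_AH, vs) * (1.0 - h) - _tb(tab, ROW_BH, vs) * h)
    dn = PHI * (_tb(tab, ROW_AN, vs) * (1.0 - n) - _tb(tab, ROW_BN, vs) * n)
    dca = -ca / TAU_CA - K_CA * i_ca
    return dvs, dvd, dh, dn, dca


@njit(inline="always", cache=False)
def _d_inh(tab, v, h, n, w, ge, gi):
    """Derivatives of one inhibitory neuron's state."""
    am = _tb(tab, ROW_AM, v)
    bm = _tb(tab, ROW_BM, v)
    m = am / (am + bm)
    i_na = G_NA_I * m * m * m * h * (v - E_NA)
    i_k = G_K_I * n * n * n * n * (v - E_K)
    i_kht = G_KHT * w * (v - E_KHT)
    i_syn = ge * (v - E_SYN_E) + gi * (v - E_SYN_I)
    dv = (-G_L_I * (v - E_L_I) - i_na - i_k - i_kht - i_syn) / C_M
    dh = PHI * (_tb(tab, ROW_AH, v) * (1.0 - h) - _tb(tab, ROW_BH, v) * h)
    dn = PHI * (_tb(tab, ROW_AN, v) * (1.0 - n) - _tb(tab, ROW_BN, v) * n)
    dw = (_tb(tab, ROW_WINF, v) - w) / TAU_W
    return dv, dh, dn, dw


@njit(cache=False)
def run_trial_kernel(
    tab,
    dt,
    n_steps,
    # connectivity
    w_ee,
    w_ei,
    w_ie,
    chain_of,
    pool_of,
    n_chains,
    pools_per_chain,
    # feedback synapses (sorted by source chain)
    fb_src_ptr,  # (n_chains+1,) synapse index ranges per source chain
    fb_tgt,
    fb_tgt_chain,
    fb_g0,
    fb_alpha,
    fb_tau_r,  # ms
    p_fdbk,  # feedback spike probability per synapse per step
    fb_delay,  # ms
    fb_duration,  # ms
    # noise and drive
    p_noise,
    g_noise_soma,
    g_noise_dend,
    g_noise_inh,
    p_drive,
    g_drive_max,
    # synaptic kinetics
    decay_e,
    decay_i,
    delay_steps,  # conduction + synaptic delay for recurrent connections
    # onset detector
    monitored_pool,
    last_pool,
    window_steps,
    thresh_count,
    det_refrac_steps,
    # trial control
    init_mask,
    init_current,
    init_steps,
    silence_timeout,  # ms without any spike before the trial is abandoned
    terminal_chain,
    repeat_chain,
    trace_every,
    trace_neuron,
    seed,
    # outputs (preallocated)
    spikes_t,
    spikes_id,
    onset_t,
    onset_chain,
    end_t,
    end_chain,
    end_fbmean,
    trace_t,
    trace_g,
    trace_vs,  # soma voltage of excitatory neuron 0 (calibration)
    trace_vi,  # voltage of inhibitory neuron 0 (calibration)
    trace_vd,  # dendritic voltage of excitatory neuron 0
):
    np.random.seed(seed)
    ne = w_ee.shape[0]
    ni = w_ie.shape[0]
    n_fb = fb_tgt.shape[0]

    # state
    vs = np.full(ne, E_L_E)
    vd = np.full(ne, E_L_D)
    he = np.full(ne, 0.95)
    ns = np.full(ne, 0.03)
    ca = np.zeros(ne)
    ges = np.zeros(ne)
    gis = np.zeros(ne)
    ged = np.zeros(ne)
    gid = np.zeros(ne)
    vi = np.full(ni, E_L_I)
    hi = np.full(ni, 0.95)
    nni = np.full(ni, 0.03)
    wi = np.zeros(ni)
    gei = np.zeros(ni)
    gii = np.zeros(ni)

    last_spike_e = np.full(ne, -1e9)
    last_spike_i = np.full(ni, -1e9)
    below_e = np.ones(ne, dtype=np.bool_)
    below_i = np.ones(ni, dtype=np.bool_)

    fb_g = fb_g0.copy()
    fb_tlast = np.zeros(n_fb)
    fb_active_from = np.full(n_chains, 1e18)
    fb_active_to = np.full(n_chains, -1e18)

    # detector ring buffers: per-chain spike counts per step
    ring_on = np.zeros((n_chains, window_steps), dtype=np.int64)
    ring_end = np.zeros((n_chains, window_steps), dtype=np.int64)
    sum_on = np.zeros(n_chains, dtype=np.int64)
    sum_end = np.zeros(n_chains, dtype=np.int64)
    next_on_ok = np.zeros(n_chains, dtype=np.int64)
    next_end_ok = np.zeros(n_chains, dtype=np.int64)

    # delay buffers for recurrent (chain, E->I, I->E) kicks
    nd = max(1, delay_steps)
    pend_ged = np.zeros((nd, ne))
    pend_gid = np.zeros((nd, ne))
    pend_gei = np.zeros((nd, ni))

    n_spk = 0
    n_on = 0
    n_end = 0
    n_tr = 0
    last_any_spike = 0.0
    overflow = False
    reached_terminal = False
    stop_step = n_steps

    for step in range(n_steps):
        t = step * dt

        # --- deliver delayed recurrent kicks -----------------------------
        slot_d = step % nd
        for i in range(ne):
            ged[i] += pend_ged[slot_d, i]
            pend_ged[slot_d, i] = 0.0
            gid[i] += pend_gid[slot_d, i]
            pend_gid[slot_d, i] = 0.0
        for i in range(ni):
            gei[i] += pend_gei[slot_d, i]
            pend_gei[slot_d, i] = 0.0

        # --- stochastic inputs -------------------------------------------
        for i in range(ne):
            if np.random.random() < p_noise:
                g = np.random.random() * g_noise_soma
                if np.random.random() < 0.5:
                    ges[i] += g
                else:
                    gis[i] += g
            if np.random.random() < p_noise:
                g = np.random.random() * g_noise_dend
                if np.random.random() < 0.5:
                    ged[i] += g
                else:
                    gid[i] += g
            if np.random.random() < p_drive:
                ges[i] += np.random.random() * g_drive_max
        for i in range(ni):
            if np.random.random() < p_noise:
                g = np.random.random() * g_noise_inh
                if np.random.random() < 0.5:
                    gei[i] += g
                else:
                    gii[i] += g

        # --- depressing feedback drive -----------------------------------
        for s in range(n_chains):
            if fb_active_from[s] <= t < fb_active_to[s]:
                for k in range(fb_src_ptr[s], fb_src_ptr[s + 1]):
                    if np.random.random() < p_fdbk:
                        g_now = fb_g0[k] + (fb_g[k] - fb_g0[k]) * np.exp(
                            -(t - fb_tlast[k]) / fb_tau_r
                        )
                        ged[fb_tgt[k]] += g_now  # feedback drives the dendrite
                        fb_g[k] = (1.0 - fb_alpha) * g_now
                        fb_tlast[k] = t

        # --- RK4 ----------------------------------------------------------
        init_on = step < init_steps
        for i in range(ne):
            iext = init_current if (init_on and init_mask[i]) else 0.0
            v1, d1, h1, n1, c1 = vs[i], vd[i], he[i], ns[i], ca[i]
            a1, a2, a3, a4, a5 = _d_exc(tab, v1, d1, h1, n1, c1, ges[i], gis[i], ged[i], gid[i], iext)
            b1, b2, b3, b4, b5 = _d_exc(
                tab, v1 + 0.5 * dt * a1, d1 + 0.5 * dt * a2, h1 + 0.5 * dt * a3,
                n1 + 0.5 * dt * a4, c1 + 0.5 * dt * a5, ges[i], gis[i], ged[i], gid[i], iext,
            )
            c1k, c2k, c3k, c4k, c5k = _d_exc(
                tab, v1 + 0.5 * dt * b1, d1 + 0.5 * dt * b2, h1 + 0.5 * dt * b3,
                n1 + 0.5 * dt * b4, c1 + 0.5 * dt * b5, ges[i], gis[i], ged[i], gid[i], iext,
            )
            d1k, d2k, d3k, d4k, d5k = _d_exc(
                tab, v1 + dt * c1k, d1 + dt * c2k, h1 + dt * c3k,
                n1 + dt * c4k, c1 + dt * c5k, ges[i], gis[i], ged[i], gid[i], iext,
            )
            vs[i] = v1 + dt / 6.0 * (a1 + 2.0 * b1 + 2.0 * c1k + d1k)
            vd[i] = d1 + dt / 6.0 * (a2 + 2.0 * b2 + 2.0 * c2k + d2k)
            he[i] = h1 + dt / 6.0 * (a3 + 2.0 * b3 + 2.0 * c3k + d3k)
            ns[i] = n1 + dt / 6.0 * (a4 + 2.0 * b4 + 2.0 * c4k + d4k)
            ca[i] = c1 + dt / 6.0 * (a5 + 2.0 * b5 + 2.0 * c5k + d5k)
            if ca[i] < 0.0:
                ca[i] = 0.0
        for i in range(ni):
            v1, h1, n1, w1 = vi[i], hi[i], nni[i], wi[i]
            a1, a2, a3, a4 = _d_inh(tab, v1, h1, n1, w1, gei[i], gii[i])
            b1, b2, b3, b4 = _d_inh(
                tab, v1 + 0.5 * dt * a1, h1 + 0.5 * dt * a2, n1 + 0.5 * dt * a3,
                w1 + 0.5 * dt * a4, gei[i], gii[i],
            )
            c1k, c2k, c3k, c4k = _d_inh(
                tab, v1 + 0.5 * dt * b1, h1 + 0.5 * dt * b2, n1 + 0.5 * dt * b3,
                w1 + 0.5 * dt * b4, gei[i], gii[i],
            )
            d1k, d2k, d3k, d4k = _d_inh(
                tab, v1 + dt * c1k, h1 + dt * c2k, n1 + dt * c3k, w1 + dt * c4k,
                gei[i], gii[i],
            )
            vi[i] = v1 + dt / 6.0 * (a1 + 2.0 * b1 + 2.0 * c1k + d1k)
            hi[i] = h1 + dt / 6.0 * (a2 + 2.0 * b2 + 2.0 * c2k + d2k)
            nni[i] = n1 + dt / 6.0 * (a3 + 2.0 * b3 + 2.0 * c3k + d3k)
            wi[i] = w1 + dt / 6.0 * (a4 + 2.0 * b4 + 2.0 * c4k + d4k)

        # numerical guard: physical voltages only
        for i in range(ne):
            if not (-200.0 < vs[i] < 200.0) or not (-200.0 < vd[i] < 200.0):
                return n_spk, n_on, n_end, n_tr, 2, step  # integrator blow-up
        # conductance decay
        for i in range(ne):
            ges[i] *= decay_e
            ged[i] *= decay_e
            gis[i] *= decay_i
            gid[i] *= decay_i
        for i in range(ni):
            gei[i] *= decay_e
            gii[i] *= decay_i

        # --- spike detection and synaptic kicks ---------------------------
        slot = step % window_steps
        for s in range(n_chains):
            sum_on[s] -= ring_on[s, slot]
            ring_on[s, slot] = 0
            sum_end[s] -= ring_end[s, slot]
            ring_end[s, slot] = 0

        for i in range(ne):
            if vs[i] < V_SPIKE:
                below_e[i] = True
                continue
            if below_e[i] and t - last_spike_e[i] >= T_REFRAC:
                below_e[i] = False
                last_spike_e[i] = t
                last_any_spike = t
                if n_spk < spikes_t.shape[0]:
                    spikes_t[n_spk] = t
                    spikes_id[n_spk] = i
                    n_spk += 1
                else:
                    overflow = True
                wslot = (step + delay_steps) % nd
                for j in range(ne):
                    w = w_ee[i, j]
                    if w > 0.0:
                        pend_ged[wslot, j] += w
                for j in range(ni):
                    w = w_ei[i, j]
                    if w > 0.0:
                        pend_gei[wslot, j] += w
                csrc = chain_of[i]
                if pool_of[i] == monitored_pool:
                    ring_on[csrc, slot] += 1
                    sum_on[csrc] += 1
                if pool_of[i] == last_pool:
                    ring_end[csrc, slot] += 1
                    sum_end[csrc] += 1
        for i in range(ni):
            if vi[i] < V_SPIKE:
                below_i[i] = True
                continue
            if below_i[i] and t - last_spike_i[i] >= T_REFRAC:
                below_i[i] = False
                last_spike_i[i] = t
                if n_spk < spikes_t.shape[0]:
                    spikes_t[n_spk] = t
                    spikes_id[n_spk] = ne + i
                    n_spk += 1
                else:
                    overflow = True
                wslot = (step + delay_steps) % nd
                for j in range(ne):
                    w = w_ie[i, j]
                    if w > 0.0:
                        pend_gid[wslot, j] += w  # WTA inhibition gates dendritic spikes

        # --- detectors ----------------------------------------------------
        for s in range(n_chains):
            if sum_on[s] >= thresh_count and step >= next_on_ok[s]:
                next_on_ok[s] = step + det_refrac_steps
                if n_on < onset_t.shape[0]:
                    onset_t[n_on] = t
                    onset_chain[n_on] = s
                    n_on += 1
                if fb_src_ptr[s + 1] > fb_src_ptr[s]:
                    start = t + fb_delay
                    if start >= fb_active_to[s]:
                        fb_active_from[s] = start
                    fb_active_to[s] = start + fb_duration
            if sum_end[s] >= thresh_count and step >= next_end_ok[s]:
                next_end_ok[s] = step + det_refrac_steps
                if n_end < end_t.shape[0]:
                    end_t[n_end] = t
                    end_chain[n_end] = s
                    # mean recovered strength of feedback synapses onto s
                    tot = 0.0
                    cnt = 0
                    for k in range(n_fb):
                        if fb_tgt_chain[k] == s:
                            tot += fb_g0[k] + (fb_g[k] - fb_g0[k]) * np.exp(
                                -(t - fb_tlast[k]) / fb_tau_r
                            )
                            cnt += 1
                    end_fbmean[n_end] = tot / cnt if cnt > 0 else np.nan
                    n_end += 1
                if s == terminal_chain:
                    reached_terminal = True
                    stop_step = step
        # --- feedback strength trace -------------------------------------
        if step % trace_every == 0 and n_tr < trace_t.shape[0]:
            trace_t[n_tr] = t
            trace_vs[n_tr] = vs[trace_neuron]
            trace_vd[n_tr] = vd[trace_neuron]
            trace_vi[n_tr] = vi[0] if ni > 0 else 0.0
            tot = 0.0
            cnt = 0
            for k in range(n_fb):
                if fb_tgt_chain[k] == repeat_chain:
                    tot += fb_g0[k] + (fb_g[k] - fb_g0[k]) * np.exp(
                        -(t - fb_tlast[k]) / fb_tau_r
                    )
                    cnt += 1
            trace_g[n_tr] = tot / cnt if cnt > 0 else np.nan
            n_tr += 1

        if reached_terminal:
            break
        if t - last_any_spike > silence_timeout:
            stop_step = step  # excitatory activity extinct; cannot restart
            break

    status = 1 if overflow else 0
    return n_spk, n_on, n_end, n_tr, status, stop_step
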