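"""Numba-compiled integrator for the conductance-based cortical network.

Design notes
------------
* Gating variables are advanced with exponential Euler.  For every gate
  the per-step update ``x <- a(V) x + b(V)`` uses two precomputed
  voltage-indexed tables ``a = exp(-dt/tau)`` and ``b = xinf (1 - a)``
  (nearest-neighbour lookup on a 0.05 mV grid), so the inner loop does
  two reads and one fused multiply-add per gate.
* The membrane potential uses a linearized implicit update
  ``V <- (V + dt/C (sum g E + I)) / (1 + dt/C sum g)`` with gate and
  synaptic conductances frozen at their new values — unconditionally
  stable for the stiff spike currents.
* Synapses are difference-of-exponentials; per target compartment only
  two state variables per synapse class (rise and decay accumulators)
  are kept, and a presynaptic spike adds its weight to both after a
  fixed conduction delay.
* Background noise is an independent Poisson train of excitatory events
  per neuron, drawn inside the kernel from a seed-initialized stream so
  a (graph, seed) pair fully determines the raster.
"""

import numpy as np
from numba import njit

OK = 0
ERR_BLOWUP = 1

# gate table layout (pyramidal): index into the stacked tables
G_NAF_M, G_NAF_H, G_KDR_M, G_NAP_M, G_NAP_H, G_KS_M, G_KS_H, G_HVA_M, G_HVA_H = range(9)
# interneuron gates
GI_NAF_M, GI_NAF_H, GI_KDR_M = range(3)


@njit(cache=True, fastmath=True)
def _vidx(V, v_lo, inv_dv, n):
    i = int((V - v_lo) * inv_dv + 0.5)
    if i < 0:
        i = 0
    elif i >= n:
        i = n - 1
    return i


@njit(cache=True, fastmath=True)
def run_network_kernel(
    # time base
    n_steps, settle_steps, dt, seed,
    # compartments
    n_comp, cm, gl, el, area,
    g_naf, g_nap, g_kdr, g_ks, g_kca, g_hva, kdr_scale,
    is_pyr_comp,
    # axial coupling (CSR): per compartment, neighbor list and per-area g
    ax_ptr, ax_idx, ax_g,
    # gate tables: pyr (9 gates) and int (3 gates) + kca (on Vs grid)
    v_lo, inv_dv, n_tab,
    pyr_a, pyr_b, int_a, int_b, kca_a, kca_b, mg_tab,
    # calcium
    ca_phi, ca_tau, ca_rest, e_ca,
    # channel reversals
    e_na, e_k,
    # synapse classes: time constants -> per-step decay factors
    ampa_rise_f, ampa_decay_f, nmda_rise_f, nmda_decay_f,
    gaba_rise_f, gaba_decay_f,
    nmda_ceiling,
    e_glu, e_gaba_pyr, e_gaba_int, mg_mM,
    # network structure
    n_pyr, n_int,
    comp_neuron,
    soma_comp, exc_comp, inh_comp,
    w_ampa, w_nmda, w_gaba,   # (n_pyr, n_cells), (n_pyr, n_cells), (n_int, n_cells)
    alive,
    delay_steps,
    # noise
    noise_rate_per_ms, noise_w_cell,
    # stimulus + ADP
    stim_cells, stim_start, stim_dur, stim_amp,
    adp_amp, adp_tau,
    # spike detection
    spike_thresh, refrac_steps,
    # output
    max_spikes,
    record_v, v_record_every, v_record_comp,
):
    np.random.seed(seed)
    n_cells = n_pyr + n_int

    V = np.full(n_comp, -70.0)
    V_old = np.empty(n_comp)
    ca = np.full(n_comp, ca_rest)

    # gate states initialised at steady state for V0 via tables:
    # x = b/(1-a) (steady state of the exp-Euler update)
    pyr_x = np.zeros((n_comp, 9))
    int_x = np.zeros((n_comp, 3))
    kca_x = np.zeros(n_comp)
    for c in range(n_comp):
        i = _vidx(V[c], v_lo, inv_dv, n_tab)
        if is_pyr_comp[c]:
            for g in range(9):
                a = pyr_a[i, g]
                if a < 1.0:
                    pyr_x[c, g] = pyr_b[i, g] / (1.0 - a)
        else:
            for g in range(3):
                a = int_a[i, g]
                if a < 1.0:
                    int_x[c, g] = int_b[i, g] / (1.0 - a)

    # synaptic accumulators per compartment
    ampa_r = np.zeros(n_comp)
    ampa_d = np.zeros(n_comp)
    nmda_r = np.zeros(n_comp)
    nmda_d = np.zeros(n_comp)
    gaba_r = np.zeros(n_comp)
    gaba_d = np.zeros(n_comp)

    # spike delay ring buffer
    ring_n = delay_steps + 1
    ring_count = np.zeros(ring_n, dtype=np.int64)
    ring_ids = np.zeros((ring_n, n_cells), dtype=np.int64)

    last_spike_step = np.full(n_cells, -10**9, dtype=np.int64)
    spike_n = 0
    spike_neuron = np.empty(max_spikes, dtype=np.int64)
    spike_time = np.empty(max_spikes)

    n_vrec = (n_steps // v_record_every + 1) if record_v else 1
    v_trace = np.zeros((n_vrec, v_record_comp.shape[0]))
    i_vrec = 0

    # exp(-x) lookup for the membrane relaxation factor
    exp_n = 4096
    exp_xmax = 24.0
    exp_scale = (exp_n - 1) / exp_xmax
    exp_tab = np.empty(exp_n)
    for i in range(exp_n):
        exp_tab[i] = np.exp(-i / exp_scale)

    # cached KCa voltage shift 40*log10(1e4*ca), refreshed lazily
    # (calcium moves on a 250 ms timescale)
    kca_shift = np.empty(n_comp)
    for c in range(n_comp):
        kca_shift[c] = 40.0 * np.log10(1e4 * ca_rest)
    kca_refresh = 8

    n_stim = stim_cells.shape[0]
    inv_adp_tau = 1.0 / adp_tau if adp_tau > 0 else 0.0

    for raw_step in range(settle_steps + n_steps):
        step = raw_step - settle_steps
        t = step * dt
        slot = raw_step % ring_n

        # 1. deliver spikes scheduled for this step
        for k in range(ring_count[slot]):
            nid = ring_ids[slot, k]
            if nid < n_pyr:
                for q in range(n_cells):
                    wa = w_ampa[nid, q]
                    wn = w_nmda[nid, q]
                    if wa > 0.0 or wn > 0.0:
                        c = exc_comp[q]
                        ampa_r[c] += wa
                        ampa_d[c] += wa
                        nmda_r[c] += wn
                        nmda_d[c] += wn
            else:
                iid = nid - n_pyr
                for q in range(n_cells):
                    wg = w_gaba[iid, q]
                    if wg > 0.0:
                        c = inh_comp[q]
                        gaba_r[c] += wg
                        gaba_d[c] += wg
        ring_count[slot] = 0

        # 2. background Poisson excitatory noise
        p_noise = noise_rate_per_ms * dt
        for q in range(n_cells):
            if alive[q] and np.random.random() < p_noise:
                c = exc_comp[q]
                w = noise_w_cell[q]
                ampa_r[c] += w
                ampa_d[c] += w

        # 3. decay synaptic accumulators (zero-clamped: exponentials
        # otherwise underflow into denormals and stall the FPU)
        for c in range(n_comp):
            ampa_r[c] = ampa_r[c] * ampa_rise_f if ampa_r[c] > 1e-12 else 0.0
            ampa_d[c] = ampa_d[c] * ampa_decay_f if ampa_d[c] > 1e-12 else 0.0
            nmda_r[c] = nmda_r[c] * nmda_rise_f if nmda_r[c] > 1e-12 else 0.0
            nmda_d[c] = nmda_d[c] * nmda_decay_f if nmda_d[c] > 1e-12 else 0.0
            gaba_r[c] = gaba_r[c] * gaba_rise_f if gaba_r[c] > 1e-12 else 0.0
            gaba_d[c] = gaba_d[c] * gaba_decay_f if gaba_d[c] > 1e-12 else 0.0

        stim_on = step >= 0 and stim_start <= t < stim_start + stim_dur
        t_adp = t - stim_start if step >= 0 else -1.0

        # 4. per-compartment update (neighbor voltages read at step start;
        # compartments of lesioned neurons are skipped entirely)
        V_old[:] = V
        for c in range(n_comp):
            if not alive[comp_neuron[c]]:
                continue
            v = V[c]
            i = _vidx(v, v_lo, inv_dv, n_tab)
            g_sum = gl[c]
            ge_sum = gl[c] * el[c]

            if is_pyr_comp[c]:
                # gate updates (exp euler via tables)
                for g in range(9):
                    pyr_x[c, g] = pyr_a[i, g] * pyr_x[c, g] + pyr_b[i, g]
                # KCa gate on the calcium-shifted voltage Vs
                if raw_step % kca_refresh == 0:
                    cac = ca[c]
                    if cac < 1e-8:
                        cac = 1e-8
                    kca_shift[c] = 40.0 * np.log10(1e4 * cac)
                ik = _vidx(v + kca_shift[c], v_lo, inv_dv, n_tab)
                kca_x[c] = kca_a[ik] * kca_x[c] + kca_b[ik]

                m = pyr_x[c, G_NAF_M]
                gna = g_naf[c] * m * m * m * pyr_x[c, G_NAF_H]
                m = pyr_x[c, G_KDR_M]
                gkdr = g_kdr[c] * kdr_scale[c] * m * m * m * m
                gnap = g_nap[c] * pyr_x[c, G_NAP_M] * pyr_x[c, G_NAP_H]
                gks = g_ks[c] * pyr_x[c, G_KS_M] * pyr_x[c, G_KS_H]
                m = kca_x[c]
                gkca = g_kca[c] * m * m
                m = pyr_x[c, G_HVA_M]
                h = pyr_x[c, G_HVA_H]
                ghva = g_hva[c] * m * m * h * h

                g_sum += gna + gnap + gkdr + gks + gkca + ghva
                ge_sum += (gna + gnap) * e_na + (gkdr + gks + gkca) * e_k + ghva * e_ca

                # calcium influx from the HVA current (inward -> influx)
                i_hva = ghva * (v - e_ca)
                dca = (-ca_phi * i_hva - (ca[c] - ca_rest) / ca_tau) * dt
                ca[c] += dca
                if ca[c] < 1e-8:
                    ca[c] = 1e-8
            else:
                for g in range(3):
                    int_x[c, g] = int_a[i, g] * int_x[c, g] + int_b[i, g]
                m = int_x[c, GI_NAF_M]
                gna = g_naf[c] * m * m * m * int_x[c, GI_NAF_H]
                m = int_x[c, GI_KDR_M]
                gkdr = g_kdr[c] * kdr_scale[c] * m * m * m * m
                g_sum += gna + gkdr
                ge_sum += gna * e_na + gkdr * e_k

            # synaptic conductances (difference of exponentials)
            g_ampa = ampa_d[c] - ampa_r[c]
            g_nmda_raw = nmda_d[c] - nmda_r[c]
            if g_nmda_raw > 1e-9:
                # receptor saturation: smooth ceiling on the summed
                # NMDA conductance (linear for small g)
                xi = g_nmda_raw / nmda_ceiling * exp_scale
                ei = int(xi)
                if ei >= exp_n - 1:
                    e_val = 0.0
                else:
                    w = xi - ei
                    e_val = exp_tab[ei] * (1.0 - w) + exp_tab[ei + 1] * w
                g_sat = nmda_ceiling * (1.0 - e_val)
                g_nmda_eff = g_sat * mg_tab[i]
            else:
                g_nmda_eff = 0.0
            g_gaba = gaba_d[c] - gaba_r[c]
            e_g = e_gaba_pyr if is_pyr_comp[c] else e_gaba_int
            g_sum += g_ampa + g_nmda_eff + g_gaba
            ge_sum += (g_ampa + g_nmda_eff) * e_glu + g_gaba * e_g

            # axial coupling: neighbor voltage explicit (Jacobi), the
            # self term folded into the relaxation conductance
            for a_i in range(ax_ptr[c], ax_ptr[c + 1]):
                g_sum += ax_g[a_i]
                ge_sum += ax_g[a_i] * V_old[ax_idx[a_i]]

            # exponential Euler on V: exact relaxation toward the
            # frozen-conductance steady state, stable for stiff spikes
            v_inf = ge_sum / g_sum
            x = dt * g_sum / cm[c]
            xi = x * exp_scale
            ei = int(xi)
            if ei >= exp_n - 1:
                decay_v = 0.0
            else:
                w = xi - ei
                decay_v = exp_tab[ei] * (1.0 - w) + exp_tab[ei + 1] * w
            V[c] = v_inf + (v - v_inf) * decay_v

        # 5. stimulus and ADP currents (explicit add onto somata)
        if stim_on:
            for k in range(n_stim):
                q = stim_cells[k]
                if alive[q]:
                    c = soma_comp[q]
                    V[c] += dt / cm[c] * stim_amp
        if adp_amp > 0.0 and t_adp > 0.0:
            x = t_adp * inv_adp_tau
            i_adp = adp_amp * x * np.exp(1.0 - x)
            for k in range(n_stim):
                q = stim_cells[k]
                if alive[q]:
                    c = soma_comp[q]
                    V[c] += dt / cm[c] * i_adp

        # 6. spike detection at somata, schedule delivery
        deliver_slot = (raw_step + delay_steps) % ring_n
        for q in range(n_cells):
            if not alive[q]:
                continue
            c = soma_comp[q]
            if V[c] >= spike_thresh and raw_step - last_spike_step[q] > refrac_steps:
                # upward crossing: previous step must have been below
                last_spike_step[q] = raw_step
                if step >= 0 and spike_n < max_spikes:
                    spike_neuron[spike_n] = q
                    spike_time[spike_n] = t
                    spike_n += 1
                ring_ids[deliver_slot, ring_count[deliver_slot]] = q
                ring_count[deliver_slot] += 1
            if V[c] > 200.0 or V[c] < -200.0 or np.isnan(V[c]):
                return (ERR_BLOWUP, spike_neuron[:spike_n], spike_time[:spike_n],
                        v_trace, float(t), q)

        if record_v and step >= 0 and step % v_record_every == 0:
            for k in range(v_record_comp.shape[0]):
                v_trace[i_vrec, k] = V[v_record_comp[k]]
            i_vrec += 1

    return (OK, spike_neuron[:spike_n], spike_time[:spike_n], v_trace, -1.0, -1)
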