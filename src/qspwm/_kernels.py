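"""Numba-compiled inner loops for the receptor-competition synapse.

The kernel advances, with a fixed-step fourth-order Runge-Kutta scheme,
the coupled bound-fraction ODEs of every receptor pool together with the
free-neurotransmitter concentration (exponential clearance punctuated by
quantal release).  Pools are independent of each other — they only share
the free-transmitter trace — so the state is a small (n_pools,
max_ligands) fraction matrix.

Release at each presynaptic spike is the product of the autoreceptor
release law (read at a fixed lag into the past) and the spike-history
facilitation/depression factor; the product is converted to a cleft
concentration increment via ``quantal_increment``.
"""

import numpy as np
from numba import njit

#: return codes of :func:`run_synapse_kernel`
OK = 0
ERR_NEGATIVE_STATE = 1


@njit(cache=True)
def _release_gain(A, rmax, S, B0):
    """Autoreceptor release gain 1 + rmax*(1 - 2*A^S/(A^S + B0^S))."""
    if A <= 0.0:
        frac = 0.0
    else:
        aS = A ** S
        frac = aS / (aS + B0 ** S)
    return 1.0 + rmax * (1.0 - 2.0 * frac)


@njit(cache=True)
def _pool_derivs(f, kon, koff, conc, is_nt, n_lig, C_nt, out):
    """d(bound fraction)/dt for one pool; ligands share the free fraction."""
    free = 1.0
    for l in range(n_lig):
        free -= f[l]
    for l in range(n_lig):
        c = C_nt if is_nt[l] else conc[l]
        out[l] = kon[l] * c * free - koff[l] * f[l]


@njit(cache=True)
def run_synapse_kernel(
    n_steps,
    dt,
    lam_nt,
    C0,
    spike_steps,
    inc_scale,
    r0,
    rmax,
    S,
    B0,
    lag_steps,
    wf,
    wd,
    kf,
    kd,
    n_lig,
    kon,
    koff,
    conc,
    is_nt,
    f0,
    auto_pool,
    auto_lig,
    avg_start,
    trace_every,
):
    """Integrate the synapse for ``n_steps`` of size ``dt`` (ms).

    Returns (status, mean_act, peak_free, t_trace, free_trace, occ_trace,
    release_per_spike).
    """
    n_pools = f0.shape[0]
    max_lig = f0.shape[1]
    f = f0.copy()
    C = C0

    # A(t - lag) ring buffer of autoreceptor neurotransmitter occupancy
    ring = np.empty(lag_steps + 1)
    ring[:] = B0

    n_trace = n_steps // trace_every + 1
    t_trace = np.empty(n_trace)
    free_trace = np.empty(n_trace)
    occ_trace = np.empty((n_pools, max_lig, n_trace))
    n_spikes = spike_steps.shape[0]
    release_per_spike = np.zeros(n_spikes)

    mean_act = np.zeros((n_pools, max_lig))
    n_avg = 0

    k1 = np.empty(max_lig)
    k2 = np.empty(max_lig)
    k3 = np.empty(max_lig)
    k4 = np.empty(max_lig)
    ftmp = np.empty(max_lig)

    decay_full = np.exp(-lam_nt * dt)
    decay_half = np.exp(-lam_nt * 0.5 * dt)

    Ff = 0.0
    Fd = 0.0
    last_spike_t = 0.0
    have_spiked = False
    spike_ptr = 0
    peak_free = C

    i_trace = 0
    for step in range(n_steps):
        t = step * dt

        # autoreceptor state at the step start, for exact-lag readback
        ring[step % (lag_steps + 1)] = f[auto_pool, auto_lig]

        # quantal release at presynaptic spike times
        if spike_ptr < n_spikes and spike_steps[spike_ptr] == step:
            if step >= lag_steps:
                A = ring[(step - lag_steps) % (lag_steps + 1)]
            else:
                A = B0
            if have_spiked:
                delta = t - last_spike_t
                Ff *= np.exp(-kf * delta)
                Fd *= np.exp(-kd * delta)
            fac = 1.0 + Ff - Fd
            if fac < 0.0:
                fac = 0.0
            rel = r0 * _release_gain(A, rmax, S, B0) * fac
            C += rel * inc_scale
            release_per_spike[spike_ptr] = rel
            Ff += wf
            Fd += wd
            last_spike_t = t
            have_spiked = True
            spike_ptr += 1

        if C > peak_free:
            peak_free = C

        if step % trace_every == 0:
            t_trace[i_trace] = t
            free_trace[i_trace] = C
            for p in range(n_pools):
                for l in range(max_lig):
                    occ_trace[p, l, i_trace] = f[p, l]
            i_trace += 1

        if step >= avg_start:
            # trapezoidal accumulation: half weight at the window edges
            w = 0.5 if step == avg_start else 1.0
            n_avg += 1
            for p in range(n_pools):
                for l in range(n_lig[p]):
                    mean_act[p, l] += w * f[p, l]

        # free NT at RK substep times (analytic exponential clearance)
        C_half = C * decay_half
        C_full = C * decay_full

        for p in range(n_pools):
            nl = n_lig[p]
            _pool_derivs(f[p], kon[p], koff[p], conc[p], is_nt[p], nl, C, k1)
            for l in range(nl):
                ftmp[l] = f[p, l] + 0.5 * dt * k1[l]
            _pool_derivs(ftmp, kon[p], koff[p], conc[p], is_nt[p], nl, C_half, k2)
            for l in range(nl):
                ftmp[l] = f[p, l] + 0.5 * dt * k2[l]
            _pool_derivs(ftmp, kon[p], koff[p], conc[p], is_nt[p], nl, C_half, k3)
            for l in range(nl):
                ftmp[l] = f[p, l] + dt * k3[l]
            _pool_derivs(ftmp, kon[p], koff[p], conc[p], is_nt[p], nl, C_full, k4)
            for l in range(nl):
                f[p, l] += dt / 6.0 * (k1[l] + 2.0 * k2[l] + 2.0 * k3[l] + k4[l])
                if f[p, l] < -1e-12 or not np.isfinite(f[p, l]):
                    return (
                        ERR_NEGATIVE_STATE,
                        mean_act,
                        peak_free,
                        t_trace,
                        free_trace,
                        occ_trace,
                        release_per_spike,
                    )

        C = C_full

    if n_avg > 0:
        # closing half-weight sample of the trapezoidal average
        for p in range(n_pools):
            for l in range(n_lig[p]):
                mean_act[p, l] += 0.5 * f[p, l]
        mean_act /= n_avg
    # final sample
    t_trace[i_trace] = n_steps * dt
    free_trace[i_trace] = C
    for p in range(n_pools):
        for l in range(max_lig):
            occ_trace[p, l, i_trace] = f[p, l]

    return (OK, mean_act, peak_free, t_trace, free_trace, occ_trace, release_per_spike)
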