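"""Compiled core of the conductance-based LIF network simulator.

Exponential-Euler integration of the membrane equation

    C_m du/dt = g_l (E_l − u) + Σ g_syn (E_rev − u)

with piecewise-constant conductances within one time step: per step the
membrane relaxes exactly toward the conductance-weighted equilibrium
potential with rate ``g_tot / C_m``.  Synaptic conductances decay
exponentially and are incremented (or, for renewing synapses, reset to the
weight) on spike arrival; Poisson background sources inject conductance
kicks into per-neuron accumulators.  Spikes reset the membrane to the reset
potential, where it is held for the absolute refractory period.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_network(
    n_steps,
    dt,
    # per-neuron parameters
    g_l, C_m, E_l, V_th, V_reset, ref_steps,
    tau_se, tau_si, E_e, E_i, const_ge, const_gi, thr_on,
    # synapses (parallel arrays)
    syn_pre, syn_post, syn_w, syn_exc, syn_delay_steps, syn_renew,
    syn_out_indptr, syn_out_idx,
    # Poisson background sources
    src_lam, src_w, src_exc, src_indptr, src_targets,
    # external stimulus spikes, sorted by step
    stim_step, stim_target, stim_w, stim_exc,
    # recording
    record_idx,
    seed,
):  # pragma: no cover - exercised through the Python wrapper
    np.random.seed(seed)
    N = g_l.size
    S = syn_pre.size
    n_src = src_lam.size

    u = E_l.copy()
    refr = np.zeros(N, dtype=np.int64)
    g_acc_e = np.zeros(N)   # background + stimulus conductance, decays with tau_se
    g_acc_i = np.zeros(N)
    g_syn = np.zeros(S)

    dec_e = np.exp(-dt / tau_se)
    dec_i = np.exp(-dt / tau_si)
    syn_dec = np.empty(S)
    for s in range(S):
        post = syn_post[s]
        syn_dec[s] = dec_e[post] if syn_exc[s] else dec_i[post]

    D = 1
    for s in range(S):
        if syn_delay_steps[s] + 1 > D:
            D = syn_delay_steps[s] + 1
    arrivals = np.zeros((D, S), dtype=np.int64)

    min_ref = n_steps
    for n in range(N):
        if ref_steps[n] < min_ref:
            min_ref = ref_steps[n]
    max_spikes = N * (n_steps // max(1, min_ref) + 2)
    spike_steps = np.empty(max_spikes, dtype=np.int64)
    spike_units = np.empty(max_spikes, dtype=np.int64)
    ns = 0

    n_rec = record_idx.size
    u_rec = np.empty((n_steps if n_rec > 0 else 1, max(1, n_rec)))

    stim_ptr = 0
    n_stim = stim_step.size

    for t in range(n_steps):
        # 1) decay accumulators and synapses
        for n in range(N):
            g_acc_e[n] *= dec_e[n]
            g_acc_i[n] *= dec_i[n]
        for s in range(S):
            g_syn[s] *= syn_dec[s]

        # 2) Poisson background arrivals
        for src in range(n_src):
            k = np.random.poisson(src_lam[src])
            if k > 0:
                add = k * src_w[src]
                for ti in range(src_indptr[src], src_indptr[src + 1]):
                    tgt = src_targets[ti]
                    if src_exc[src]:
                        g_acc_e[tgt] += add
                    else:
                        g_acc_i[tgt] += add

        # 3) external stimulus spikes
        while stim_ptr < n_stim and stim_step[stim_ptr] == t:
            tgt = stim_target[stim_ptr]
            if stim_exc[stim_ptr]:
                g_acc_e[tgt] += stim_w[stim_ptr]
            else:
                g_acc_i[tgt] += stim_w[stim_ptr]
            stim_ptr += 1

        # 4) delayed recurrent arrivals
        row = t % D
        for s in range(S):
            c = arrivals[row, s]
            if c > 0:
                if syn_renew[s]:
                    g_syn[s] = syn_w[s]
                else:
                    g_syn[s] += c * syn_w[s]
                arrivals[row, s] = 0

        # 5) integrate membranes
        ge_tot = const_ge.copy()
        gi_tot = const_gi.copy()
        for n in range(N):
            ge_tot[n] += g_acc_e[n]
            gi_tot[n] += g_acc_i[n]
        for s in range(S):
            if syn_exc[s]:
                ge_tot[syn_post[s]] += g_syn[s]
            else:
                gi_tot[syn_post[s]] += g_syn[s]

        for n in range(N):
            if refr[n] > 0:
                refr[n] -= 1
                u[n] = V_reset[n]
            else:
                g_tot = g_l[n] + ge_tot[n] + gi_tot[n]
                u_inf = (
                    g_l[n] * E_l[n] + ge_tot[n] * E_e[n] + gi_tot[n] * E_i[n]
                ) / g_tot
                u[n] = u_inf + (u[n] - u_inf) * np.exp(-dt * g_tot / C_m[n])
                if thr_on[n] and u[n] >= V_th[n]:
                    spike_steps[ns] = t
                    spike_units[ns] = n
                    ns += 1
                    refr[n] = ref_steps[n]
                    u[n] = V_reset[n]
                    for si in range(syn_out_indptr[n], syn_out_indptr[n + 1]):
                        s = syn_out_idx[si]
                        arrivals[(t + syn_delay_steps[s]) % D, s] += 1

        for ri in range(n_rec):
            u_rec[t, ri] = u[record_idx[ri]]

    return spike_steps[:ns], spike_units[:ns], u_rec[:, :n_rec]
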