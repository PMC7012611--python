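"""Numba time-stepping core for the LIF network.

The membrane potential is advanced with a second-order Runge-Kutta (Heun)
step; the exponential synaptic traces are advanced exactly between spikes
(decay factor exp(-dt/tau) per step, jump 1/tau per presynaptic spike).
Spikes are detected at threshold crossing at the end of the step, without
spike-time interpolation, and the voltage is reset to V_R.

Per postsynaptic neuron the traces of all its presynaptic neurons from
population b are aggregated into a single variable s[i, b]; this is exact
because all those traces share the time constant tau[pop(i), b].
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_BLOWUP = 1
STATUS_OVERFLOW = 2


@njit(cache=True, fastmath=True)
def run_network(
    pop_of,        # int32[N] population index per neuron
    indptr,        # int64[N+1] outgoing adjacency (CSC over presynaptic neurons)
    indices,       # int32[nnz] postsynaptic targets
    w,             # float64[n_pop, n_pop]: j[a,b] * eps[b]  (uA.ms/cm^2)
    jump,          # float64[n_pop, n_pop]: 1/tau[a,b] (0 where absent)
    decay,         # float64[n_pop, n_pop]: exp(-dt/tau[a,b]) (1 where absent)
    gl,            # float64[n_pop] leak conductance (mS/cm^2)
    lam,           # float64[n_pop] constant drive lam_ext + lam_opto (uA/cm^2)
    C_M,           # membrane capacitance (uF/cm^2)
    V_th, V_R,     # threshold / reset (mV)
    dt,            # time step (ms)
    n_steps,       # total steps including warmup
    warmup_steps,  # spikes before this step are not recorded
    V,             # float64[N] in-out: membrane potentials
    s,             # float64[N, n_pop] in-out: aggregated synaptic traces
    rec_ids,       # int32[cap] out: spiking neuron ids
    rec_times,     # float64[cap] out: spike times (ms, relative to warmup end)
):
    N = pop_of.shape[0]
    n_pop = w.shape[0]
    cap = rec_ids.shape[0]
    spk_buf = np.empty(N, dtype=np.int32)
    n_rec = 0
    inv_C = 1.0 / C_M
    for step in range(n_steps):
        n_spk = 0
        for i in range(N):
            p = pop_of[i]
            I0 = lam[p]
            I1 = lam[p]
            for b in range(n_pop):
                sv = s[i, b]
                if sv != 0.0:
                    I0 += w[p, b] * sv
                    sv *= decay[p, b]
                    s[i, b] = sv
                    I1 += w[p, b] * sv
            v = V[i]
            k1 = (-gl[p] * (v - V_R) + I0) * inv_C
            k2 = (-gl[p] * (v + dt * k1 - V_R) + I1) * inv_C
            v = v + 0.5 * dt * (k1 + k2)
            if v >= V_th:
                v = V_R
                spk_buf[n_spk] = i
                n_spk += 1
                if step >= warmup_steps:
                    if n_rec >= cap:
                        return n_rec, STATUS_OVERFLOW
                    rec_ids[n_rec] = i
                    rec_times[n_rec] = (step + 1 - warmup_steps) * dt
                    n_rec += 1
            elif v > 1000.0 or v < -1000.0 or v != v:
                return n_rec, STATUS_BLOWUP
            V[i] = v
        for k in range(n_spk):
            j = spk_buf[k]
            b = pop_of[j]
            for idx in range(indptr[j], indptr[j + 1]):
                tgt = indices[idx]
                s[tgt, b] += jump[pop_of[tgt], b]
    return n_rec, STATUS_OK
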