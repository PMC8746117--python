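"""Numba integration kernel for the spiking network.

One call advances the whole network by a chunk of exponential-Euler steps.
All state arrays are updated in place; spikes are scattered into delay ring
buffers as conductance increments.  Status codes: 0 ok, 1 non-finite membrane
potential (bad neuron/step reported), 2 spike buffer overflow.
"""

import numpy as np
from numba import njit

__all__ = ["run_chunk"]


@njit(cache=True, fastmath=True)
def run_chunk(
    n_steps, head, step0,
    V, m, h, n, ge, gi, gb,
    C, w_bkg, area_of, is_exc,
    indptr, targets, weights, delays, pools,
    ring_e, ring_i, bkg_counts,
    dt, decay_e, decay_i, refr_steps,
    I_ext, g_Na, g_K, g_L, E_Na, E_K, E_L,
    E_exc, E_inh, thresh,
    last_spike, out_E, out_I, out_B, spk_t, spk_id,
):
    n_total = V.shape[0]
    ring_len = ring_e.shape[0]
    nspk = 0
    cap = spk_t.shape[0]
    for s in range(n_steps):
        step = step0 + s
        for i in range(n_total):
            # synaptic conductance decay + arriving delayed increments
            ge[i] = ge[i] * decay_e + ring_e[head, i]
            gi[i] = gi[i] * decay_i + ring_i[head, i]
            gb[i] = gb[i] * decay_e + w_bkg[i] * bkg_counts[s, i]
            ring_e[head, i] = 0.0
            ring_i[head, i] = 0.0
            v = V[i]
            # gate transition rates (1/ms); removable singularities by limit
            xm = v + 16.0
            if xm > 1e-7 or xm < -1e-7:
                am = 0.1 * xm / (1.0 - np.exp(-xm / 10.0))
            else:
                am = 1.0
            bm = 4.0 * np.exp(-(v + 41.0) / 18.0)
            ah = 0.07 * np.exp(-(v + 30.0) / 20.0)
            bh = 1.0 / (1.0 + np.exp(-v / 10.0))
            xn = v + 20.0
            if xn > 1e-7 or xn < -1e-7:
                an = 0.01 * xn / (1.0 - np.exp(-xn / 10.0))
            else:
                an = 0.1
            bn = 0.125 * np.exp(-(v + 30.0) / 80.0)
            # exact gate update for frozen V
            r = am + bm
            xinf = am / r
            m[i] = xinf + (m[i] - xinf) * np.exp(-dt * r)
            r = ah + bh
            xinf = ah / r
            h[i] = xinf + (h[i] - xinf) * np.exp(-dt * r)
            r = an + bn
            xinf = an / r
            n[i] = xinf + (n[i] - xinf) * np.exp(-dt * r)
            # record rectified synaptic currents on excitatory neurons (nA)
            if is_exc[i]:
                a = area_of[i]
                out_E[s, a] += abs(ge[i] * (E_exc - v))
                out_I[s, a] += abs(gi[i] * (E_inh - v))
                out_B[s, a] += abs(gb[i] * (E_exc - v))
            # exponential Euler on the conductance-linearized membrane eq.
            gna = g_Na * m[i] * m[i] * m[i] * h[i]
            gk = g_K * n[i] * n[i] * n[i] * n[i]
            G = gna + gk + g_L + ge[i] + gi[i] + gb[i]
            Isum = (
                gna * E_Na + gk * E_K + g_L * E_L
                + (ge[i] + gb[i]) * E_exc + gi[i] * E_inh + I_ext
            )
            vinf = Isum / G
            vnew = vinf + (v - vinf) * np.exp(-dt * G / C[i])
            if not np.isfinite(vnew):
                return nspk, head, 1, i, s
            V[i] = vnew
            # upward threshold crossing with detection refractory
            if vnew >= thresh and v < thresh and step - last_spike[i] >= refr_steps:
                last_spike[i] = step
                if nspk >= cap:
                    return nspk, head, 2, i, s
                spk_t[nspk] = (step + 1) * dt
                spk_id[nspk] = i
                nspk += 1
                for e in range(indptr[i], indptr[i + 1]):
                    slot = (head + delays[e]) % ring_len
                    if pools[e] == 0:
                        ring_e[slot, targets[e]] += weights[e]
                    else:
                        ring_i[slot, targets[e]] += weights[e]
        head = (head + 1) % ring_len
    return nspk, head, 0, -1, -1
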