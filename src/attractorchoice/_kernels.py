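"""Numba kernel for the session-scale integrator.

Implements exactly the semantics of :meth:`attractorchoice.network.Network.step`
(decay → delayed recurrent delivery → external Poisson arrivals → Euler
update → threshold/reset → enqueue), specialized to flat per-neuron arrays
so multi-second continuous sessions run in seconds.  External Poisson input
is drawn inside the kernel from a per-call seed; per-step arrival
probabilities are ``1 − exp(−rate·dt)``.

The conductance state is laid out (n_neurons, 6) so each neuron's synaptic
states are contiguous; the six columns are AMPA_ext, AMPA_background,
AMPA_recurrent, NMDA rise, NMDA decay, GABA_A.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(uint64(uint64), cache=True, inline="always")
def _xs_next(s):
    s ^= s >> uint64(12)
    s ^= s << uint64(25)
    s ^= s >> uint64(27)
    return s


@njit(cache=True, inline="always")
def _xs_unit(s):
    """Uniform double in [0, 1) from a xorshift64* state word."""
    return float((s * uint64(0x2545F4914F6CDD1D)) >> uint64(11)) * _INV_2_53


@njit(cache=True, fastmath=True)
def simulate_steps(
    n_steps,
    dt,
    t0,
    step0,
    V,
    g,  # (n, 6)
    ref_until,
    pend_exc,
    pend_inh,
    inv_C,
    g_L,
    E_L,
    V_s,
    V_r,
    tau_r,
    v_tab0,
    inv_dv,
    spike_tab,
    gate_tab,
    G_ext,
    G_bg,
    G_rec,
    G_nmda,
    G_gaba,
    I_inj,
    rec_jump,
    inv_nmda_cap,
    nmda_norm,
    E_exc,
    E_gaba,
    decay,  # (6,)
    exc_indptr,
    exc_indices,
    inh_indptr,
    inh_indices,
    delay_steps,
    n_pyr,
    n_sel,
    p_bg,
    p_bg_int,
    p_task_L,
    p_task_R,
    additive,
    group,
    counts,
    record,
    rec_n,
    rec_t,
    seed,
):  # pragma: no cover - exercised via the Network wrapper
    # xorshift64* stream; the SplitMix-style scramble decorrelates seeds
    rs = uint64(seed) * uint64(0x9E3779B97F4A7C15) + uint64(0xD1B54A32D192ED03)
    rs = _xs_next(rs | uint64(1))
    n = V.shape[0]
    ntab = gate_tab.shape[0]
    ring = pend_exc.shape[0]
    n_rec = 0
    t = t0
    d0, d1, d2, d3, d4, d5 = decay[0], decay[1], decay[2], decay[3], decay[4], decay[5]
    for k in range(n_steps):
        slot = (step0 + k) % ring
        enq = (step0 + k + delay_steps) % ring
        pL = p_task_L[k]
        pR = p_task_R[k]
        for i in range(n):
            # 1. conductance decay
            g[i, 0] *= d0
            g[i, 1] *= d1
            g[i, 2] *= d2
            g[i, 3] *= d3
            g[i, 4] *= d4
            g[i, 5] *= d5

            # 2. delayed recurrent arrivals
            ce = pend_exc[slot, i]
            if ce > 0:
                if additive:
                    g[i, 2] += ce * G_rec[i]
                    sat = 1.0 - g[i, 4] * inv_nmda_cap[i]
                    if sat > 0.0:
                        jump = ce * rec_jump[i] * sat
                        g[i, 3] += jump
                        g[i, 4] += jump
                else:
                    g[i, 2] = G_rec[i]
                    g[i, 3] = rec_jump[i]
                    g[i, 4] = rec_jump[i]
                pend_exc[slot, i] = 0
            ci = pend_inh[slot, i]
            if ci > 0:
                if additive:
                    g[i, 5] += ci * G_gaba[i]
                else:
                    g[i, 5] = G_gaba[i]
                pend_inh[slot, i] = 0

            # 3. external Poisson arrivals
            pb = p_bg if i < n_pyr else p_bg_int
            rs = _xs_next(rs)
            if pb > 0.0 and _xs_unit(rs) < pb:
                if additive:
                    g[i, 1] += G_bg[i]
                else:
                    g[i, 1] = G_bg[i]
            if i < n_sel:
                rs = _xs_next(rs)
                if pL > 0.0 and _xs_unit(rs) < pL:
                    if additive:
                        g[i, 0] += G_ext[i]
                    else:
                        g[i, 0] = G_ext[i]
            elif i < 2 * n_sel:
                rs = _xs_next(rs)
                if pR > 0.0 and _xs_unit(rs) < pR:
                    if additive:
                        g[i, 0] += G_ext[i]
                    else:
                        g[i, 0] = G_ext[i]

            # 4-6. integrate, detect spike, enqueue deliveries
            if t < ref_until[i]:
                V[i] = V_r[i]
                continue
            v = V[i]
            # table lookups (linear interpolation) for the spike-initiation
            # term g_L*Delta_T*exp((v-V_T)/Delta_T) and the NMDA Mg gating
            x = (v - v_tab0) * inv_dv
            ix = int(x)
            if ix < 0:
                ix = 0
                fr = 0.0
            elif ix >= ntab - 1:
                ix = ntab - 2
                fr = 1.0
            else:
                fr = x - ix
            cls = 0 if i < n_pyr else 1
            sp = spike_tab[cls, ix] + fr * (spike_tab[cls, ix + 1] - spike_tab[cls, ix])
            gate = gate_tab[ix] + fr * (gate_tab[ix + 1] - gate_tab[ix])

            I = (g[i, 0] + g[i, 1] + g[i, 2]) * (v - E_exc)
            gn = G_nmda[i] * nmda_norm * (g[i, 4] - g[i, 3])
            I += gn * gate * (v - E_exc)
            I += g[i, 5] * (v - E_gaba)
            I -= I_inj[i]
            drive = -g_L[i] * (v - E_L[i]) + sp - I
            v = v + dt * drive * inv_C[i]
            if not np.isfinite(v):
                return n_rec, i, t
            if v >= V_s[i]:
                v = V_r[i]
                ref_until[i] = t + dt + tau_r[i]
                counts[k, group[i]] += 1
                if record and n_rec < rec_n.shape[0]:
                    rec_n[n_rec] = i
                    rec_t[n_rec] = t + dt
                    n_rec += 1
                if i < n_pyr:
                    for jj in range(exc_indptr[i], exc_indptr[i + 1]):
                        pend_exc[enq, exc_indices[jj]] += 1
                else:
                    ii = i - n_pyr
                    for jj in range(inh_indptr[ii], inh_indptr[ii + 1]):
                        pend_inh[enq, inh_indices[jj]] += 1
            V[i] = v
        t += dt
    return n_rec, -1, t
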