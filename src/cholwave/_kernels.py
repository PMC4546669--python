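"""Numba-compiled RK4 integration core shared by single-cell and network runs.

The integrator advances all cells synchronously with classical RK4. Synaptic
conductances are evaluated at each stage time from the per-cell *last* spike
(a new presynaptic spike resets the kernel). Within one step the last-spike
table is frozen at the step start; since the synaptic delay is at least one
time step this is exact.

Parameter vectors (packed to keep the compiled signature manageable):

``pv`` (membrane + gates), length 24::

    0 cm   1 gNa   2 gKdr  3 gKs   4 gl   5 ENa   6 EK   7 El   8 I_tune
    9 alpha_m 10 beta_m
    11 alpha_h 12 beta_h 13 gamma_h 14 eps_h 15 D_h
    16 alpha_n 17 beta_n 18 gamma_n 19 eps_n 20 D_n
    21 alpha_s 22 beta_s 23 tau_s

``sv`` (synapse), length 7::

    0 tau_F  1 tau_S  2 tau_D  3 K  4 E_exc  5 E_inh  6 kernel cutoff (ms)
"""

import numpy as np
from numba import njit

TAU_FLOOR = 0.37  # ms, additive floor of voltage-dependent gate time constants

NO_SPIKE = -1.0e9  # sentinel "never spiked" time


@njit(cache=True, inline="always")
def _logistic(x):
    return 1.0 / (1.0 + np.exp(x))


@njit(cache=True)
def _syn_conductances(ts, last_spike, is_inh, indptr, indices, weights,
                      w_ie, sv, gex, gin):
    """Fill gex/gin with per-cell synaptic conductances at time ts.

    Explicit (CSR) edges are accumulated per presynaptic cell; if ``w_ie >= 0``
    inhibitory cells are taken as globally and uniformly connected to every
    excitatory cell with that weight (they then carry no CSR edges).
    """
    nc = last_spike.shape[0]
    gex[:] = 0.0
    gin[:] = 0.0
    tau_f = sv[0]
    tau_s = sv[1]
    tau_d = sv[2]
    kn = sv[3]
    cutoff = sv[6]
    inh_sum = 0.0
    for j in range(nc):
        tls = last_spike[j]
        if tls <= NO_SPIKE:
            continue
        td = ts - tls - tau_d
        if td <= 0.0 or td > cutoff:
            continue
        kv = kn * (np.exp(-td / tau_s) - np.exp(-td / tau_f))
        if is_inh[j] and w_ie >= 0.0:
            # dense uniform I->E handled analytically; any CSR edges of an
            # inhibitory cell are then its I->I projections
            inh_sum += kv
        for e in range(indptr[j], indptr[j + 1]):
            post = indices[e]
            if is_inh[j]:
                gin[post] += weights[e] * kv
            else:
                gex[post] += weights[e] * kv
    if w_ie > 0.0 and inh_sum > 0.0:
        g = w_ie * inh_sum
        for i in range(nc):
            if not is_inh[i]:
                gin[i] += g


@njit(cache=True)
def _deriv(ts, V, h, n, s, gex, gin, pv, sv,
           stim_amp, stim_on, stim_off, dV, dh, dn, ds):
    cm = pv[0]
    for i in range(V.shape[0]):
        v = V[i]
        m_inf = _logistic((pv[9] - v) / pv[10])
        i_na = pv[1] * m_inf * m_inf * m_inf * h[i] * (v - pv[5])
        i_kdr = pv[2] * n[i] ** 4 * (v - pv[6])
        i_ks = pv[3] * s[i] * (v - pv[6])
        i_l = pv[4] * (v - pv[7])
        i_syn = gex[i] * (v - sv[4]) + gin[i] * (v - sv[5])
        i_ext = pv[8]
        if stim_on[i] <= ts < stim_off[i]:
            i_ext += stim_amp[i]
        dV[i] = (-i_na - i_kdr - i_ks - i_l + i_ext - i_syn) / cm

        h_inf = _logistic((pv[11] - v) / pv[12])
        tau_h = TAU_FLOOR + pv[15] * _logistic((pv[13] + v) / pv[14])
        dh[i] = (h_inf - h[i]) / tau_h

        n_inf = _logistic((pv[16] - v) / pv[17])
        tau_n = TAU_FLOOR + pv[20] * _logistic((pv[18] + v) / pv[19])
        dn[i] = (n_inf - n[i]) / tau_n

        s_inf = _logistic((pv[21] - v) / pv[22])
        ds[i] = (s_inf - s[i]) / pv[23]


@njit(cache=True)
def integrate(V, h, n, s, is_inh, pv, sv,
              indptr, indices, weights, w_ie,
              stim_amp, stim_on, stim_off,
              dt, nsteps, t_start,
              vthresh, lockout,
              last_spike, last_detect,
              spike_cells, spike_times,
              record_idx, rec_stride, V_rec):
    """Advance the whole population by ``nsteps`` RK4 steps of size ``dt``.

    State arrays (V, h, n, s, last_spike, last_detect) are updated in place.
    Detected spikes (upward crossing of ``vthresh`` with refractory
    ``lockout``) are appended to spike_cells/spike_times.

    Returns (n_spikes, bad_cell, bad_time); bad_cell >= 0 flags a non-finite
    state at bad_time, and bad_cell == -2 flags spike-buffer overflow.
    """
    nc = V.shape[0]
    gex1 = np.empty(nc)
    gin1 = np.empty(nc)
    gex2 = np.empty(nc)
    gin2 = np.empty(nc)
    gex4 = np.empty(nc)
    gin4 = np.empty(nc)
    k1V = np.empty(nc); k1h = np.empty(nc); k1n = np.empty(nc); k1s = np.empty(nc)
    k2V = np.empty(nc); k2h = np.empty(nc); k2n = np.empty(nc); k2s = np.empty(nc)
    k3V = np.empty(nc); k3h = np.empty(nc); k3n = np.empty(nc); k3s = np.empty(nc)
    k4V = np.empty(nc); k4h = np.empty(nc); k4n = np.empty(nc); k4s = np.empty(nc)
    Vt = np.empty(nc); ht = np.empty(nc); nt = np.empty(nc); st = np.empty(nc)
    Vold = np.empty(nc)

    nrec = record_idx.shape[0]
    if nrec > 0:
        for r in range(nrec):
            V_rec[0, r] = V[record_idx[r]]

    nsp = 0
    cap = spike_cells.shape[0]
    for k in range(nsteps):
        t0 = t_start + k * dt
        tm = t0 + 0.5 * dt
        t1 = t0 + dt

        _syn_conductances(t0, last_spike, is_inh, indptr, indices, weights,
                          w_ie, sv, gex1, gin1)
        _syn_conductances(tm, last_spike, is_inh, indptr, indices, weights,
                          w_ie, sv, gex2, gin2)
        _syn_conductances(t1, last_spike, is_inh, indptr, indices, weights,
                          w_ie, sv, gex4, gin4)

        _deriv(t0, V, h, n, s, gex1, gin1, pv, sv,
               stim_amp, stim_on, stim_off, k1V, k1h, k1n, k1s)
        for i in range(nc):
            Vt[i] = V[i] + 0.5 * dt * k1V[i]
            ht[i] = h[i] + 0.5 * dt * k1h[i]
            nt[i] = n[i] + 0.5 * dt * k1n[i]
            st[i] = s[i] + 0.5 * dt * k1s[i]
        _deriv(tm, Vt, ht, nt, st, gex2, gin2, pv, sv,
               stim_amp, stim_on, stim_off, k2V, k2h, k2n, k2s)
        for i in range(nc):
            Vt[i] = V[i] + 0.5 * dt * k2V[i]
            ht[i] = h[i] + 0.5 * dt * k2h[i]
            nt[i] = n[i] + 0.5 * dt * k2n[i]
            st[i] = s[i] + 0.5 * dt * k2s[i]
        _deriv(tm, Vt, ht, nt, st, gex2, gin2, pv, sv,
               stim_amp, stim_on, stim_off, k3V, k3h, k3n, k3s)
        for i in range(nc):
            Vt[i] = V[i] + dt * k3V[i]
            ht[i] = h[i] + dt * k3h[i]
            nt[i] = n[i] + dt * k3n[i]
            st[i] = s[i] + dt * k3s[i]
        _deriv(t1, Vt, ht, nt, st, gex4, gin4, pv, sv,
               stim_amp, stim_on, stim_off, k4V, k4h, k4n, k4s)

        for i in range(nc):
            Vold[i] = V[i]
            V[i] += dt / 6.0 * (k1V[i] + 2.0 * k2V[i] + 2.0 * k3V[i] + k4V[i])
            h[i] += dt / 6.0 * (k1h[i] + 2.0 * k2h[i] + 2.0 * k3h[i] + k4h[i])
            n[i] += dt / 6.0 * (k1n[i] + 2.0 * k2n[i] + 2.0 * k3n[i] + k4n[i])
            s[i] += dt / 6.0 * (k1s[i] + 2.0 * k2s[i] + 2.0 * k3s[i] + k4s[i])
            # gates leave [0,1] only by integration round-off
            if h[i] < 0.0:
                h[i] = 0.0
            elif h[i] > 1.0:
                h[i] = 1.0
            if n[i] < 0.0:
                n[i] = 0.0
            elif n[i] > 1.0:
                n[i] = 1.0
            if s[i] < 0.0:
                s[i] = 0.0
            elif s[i] > 1.0:
                s[i] = 1.0

        # spike detection on the completed step
        for i in range(nc):
            if Vold[i] < vthresh and V[i] >= vthresh:
                if t1 - last_detect[i] >= lockout:
                    if nsp >= cap:
                        return nsp, -2, t1
                    spike_cells[nsp] = i
                    spike_times[nsp] = t1
                    nsp += 1
                    last_detect[i] = t1
                    last_spike[i] = t1

        if nrec > 0 and (k + 1) % rec_stride == 0:
            row = (k + 1) // rec_stride
            for r in range(nrec):
                V_rec[row, r] = V[record_idx[r]]

        if (k + 1) % 200 == 0 or k == nsteps - 1:
            for i in range(nc):
                if not np.isfinite(V[i]):
                    return nsp, i, t1

    return nsp, -1, 0.0


def pack_neuron_params(p) -> np.ndarray:
    """Pack a NeuronParams into the flat ``pv`` vector used by the kernels."""
    return np.array([
        p.cm, p.gNa_max, p.gKdr_max, p.gKs_max, p.gl, p.ENa, p.EK, p.El,
        p.I_tune,
        p.m.alpha, p.m.beta,
        p.h.alpha, p.h.beta, p.h.gamma, p.h.eps, p.h.D,
        p.n.alpha, p.n.beta, p.n.gamma, p.n.eps, p.n.D,
        p.s.alpha, p.s.beta, p.s.tau_fixed,
    ], dtype=np.float64)


def pack_synapse_params(sp, cutoff_factor: float = 15.0) -> np.ndarray:
    """Pack SynapseParams into ``sv``; the kernel is truncated at
    ``cutoff_factor * tau_S`` past the delay (relative error < 1e-6)."""
    return np.array([
        sp.tau_F, sp.tau_S, sp.tau_D, sp.K, sp.E_exc, sp.E_inh,
        cutoff_factor * sp.tau_S,
    ], dtype=np.float64)
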