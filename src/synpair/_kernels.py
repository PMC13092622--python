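"""Compiled inner loops (numba) for cable integration and transfer entropy.

Everything here operates on plain arrays in the package's internal units
(mV, ms, uS, nF, nA).  The public API lives in :mod:`synpair.model_core`,
:mod:`synpair.simulator` and :mod:`synpair.infotheory`; these kernels are
implementation detail and carry no validation.
"""

import numpy as np
from numba import njit

# ----------------------------------------------------------------------
# cable step: Rush-Larsen gating + Crank-Nicolson tridiagonal voltage solve
# ----------------------------------------------------------------------


@njit(cache=True)
def cable_step_kernel(V, m, h, n, capdt, gax, gna, gk, gl,
                      ena, ek, el, gsyn, esyn, iext,
                      tv0, tinv, tn,
                      minf, mexp, hinf, hexp, ninf, nexp):
    """One dt step, in place.  Returns -1 on success, else the first
    segment index whose potential went non-finite."""
    ns = V.size
    # gating: exponential update using tables evaluated at the pre-step V
    for i in range(ns):
        u = (V[i] - tv0) * tinv
        if u < 0.0:
            u = 0.0
        elif u > tn - 1.001:
            u = tn - 1.001
        j = int(u)
        f = u - j
        xi = minf[j] + (minf[j + 1] - minf[j]) * f
        xe = mexp[j] + (mexp[j + 1] - mexp[j]) * f
        m[i] = xi + (m[i] - xi) * xe
        xi = hinf[j] + (hinf[j + 1] - hinf[j]) * f
        xe = hexp[j] + (hexp[j + 1] - hexp[j]) * f
        h[i] = xi + (h[i] - xi) * xe
        xi = ninf[j] + (ninf[j + 1] - ninf[j]) * f
        xe = nexp[j] + (nexp[j + 1] - nexp[j]) * f
        n[i] = xi + (n[i] - xi) * xe
    # Crank-Nicolson: (C/dt - M/2) V+ = (C/dt + M/2) V + b,
    # M = axial Laplacian - diag(g_ion + g_syn), all in uS / nA
    lo = np.empty(ns)
    di = np.empty(ns)
    up = np.empty(ns)
    rhs = np.empty(ns)
    for i in range(ns):
        m3h = m[i] * m[i] * m[i] * h[i]
        n4 = n[i] * n[i]
        n4 = n4 * n4
        gm = gna[i] * m3h + gk[i] * n4 + gl[i] + gsyn[i]
        b = (gna[i] * m3h * ena + gk[i] * n4 * ek + gl[i] * el
             + gsyn[i] * esyn + iext[i])
        gl_ax = gax[i - 1] if i > 0 else 0.0
        gr_ax = gax[i] if i < ns - 1 else 0.0
        mdiag = -(gm + gl_ax + gr_ax)
        di[i] = capdt[i] - 0.5 * mdiag
        r = (capdt[i] + 0.5 * mdiag) * V[i] + b
        if i > 0:
            r += 0.5 * gax[i - 1] * V[i - 1]
            lo[i] = -0.5 * gax[i - 1]
        else:
            lo[i] = 0.0
        if i < ns - 1:
            r += 0.5 * gax[i] * V[i + 1]
            up[i] = -0.5 * gax[i]
        else:
            up[i] = 0.0
        rhs[i] = r
    # Thomas solve
    for i in range(1, ns):
        w = lo[i] / di[i - 1]
        di[i] -= w * up[i - 1]
        rhs[i] -= w * rhs[i - 1]
    V[ns - 1] = rhs[ns - 1] / di[ns - 1]
    for i in range(ns - 2, -1, -1):
        V[i] = (rhs[i] - up[i] * V[i + 1]) / di[i]
    for i in range(ns):
        if not np.isfinite(V[i]):
            return i
    return -1


# ----------------------------------------------------------------------
# full two-neuron run
# ----------------------------------------------------------------------


@njit(cache=True)
def run_pair_kernel(dt, n_settle, n_steps,
                    capdt_a, gax_a, gna_a, gk_a, gl_a, V_a, m_a, h_a, n_a,
                    capdt_b, gax_b, gna_b, gk_b, gl_b, V_b, m_b, h_b, n_b,
                    ena, ek, el,
                    tv0, tinv, tn, minf, mexp, hinf, hexp, ninf, nexp,
                    spont_step_a, spont_time_a, spont_w_a,
                    spont_step_b, spont_time_b, spont_w_b,
                    sp_d1, sp_d2, sp_ninv, e_spont, spont_seg,
                    pre_trig_seg, post_seg,
                    ampa_w, nmda_w,
                    am_d1, am_d2, am_ninv, nm_d1, nm_d2, nm_ninv, e_syn,
                    threshold, refr,
                    mon_a, mon_b,
                    spikes_a, counts_a, spikes_b, counts_b,
                    syn_times,
                    rec_flag, rec_Va, rec_Vb):
    """Integrate a coupled pair.  Spike times are written into
    ``spikes_a/spikes_b`` (rows follow ``mon_a``/``mon_b``), presynaptic
    activation times into ``syn_times``.  Returns
    (status, step, neuron, segment, n_syn): status 0 = ok, 1 = blow-up."""
    ns_a = V_a.size
    ns_b = V_b.size
    gsyn_a = np.zeros(ns_a)
    gsyn_b = np.zeros(ns_b)
    iext_a = np.zeros(ns_a)
    iext_b = np.zeros(ns_b)

    # silent settling: no inputs, nothing recorded
    for t_idx in range(n_settle):
        err = cable_step_kernel(V_a, m_a, h_a, n_a, capdt_a, gax_a, gna_a,
                                gk_a, gl_a, ena, ek, el, gsyn_a, e_syn,
                                iext_a, tv0, tinv, tn, minf, mexp, hinf,
                                hexp, ninf, nexp)
        if err >= 0:
            return 1, t_idx, 0, err, 0
        err = cable_step_kernel(V_b, m_b, h_b, n_b, capdt_b, gax_b, gna_b,
                                gk_b, gl_b, ena, ek, el, gsyn_b, e_syn,
                                iext_b, tv0, tinv, tn, minf, mexp, hinf,
                                hexp, ninf, nexp)
        if err >= 0:
            return 1, t_idx, 1, err, 0

    # conductance accumulators: beta kernel as difference of two exponentials
    sa1 = 0.0
    sa2 = 0.0
    sb1 = 0.0
    sb2 = 0.0
    am1 = 0.0
    am2 = 0.0
    nm1 = 0.0
    nm2 = 0.0
    ia = 0
    ib = 0
    iw = 0
    n_syn = 0
    n_pool = ampa_w.size

    nm_a = mon_a.size
    nm_b = mon_b.size
    last_a = np.full(nm_a, -1e12)
    last_b = np.full(nm_b, -1e12)
    prev_a = np.empty(nm_a)
    prev_b = np.empty(nm_b)
    # Schmitt-trigger detection: after a crossing the detector re-arms only
    # once V falls below threshold - rearm, suppressing the 2-step
    # Crank-Nicolson micro-oscillation around the slow repolarization
    # plateau of these broad spikes.
    rearm = 10.0
    armed_a = np.ones(nm_a, np.int64)
    armed_b = np.ones(nm_b, np.int64)
    for q in range(nm_a):
        prev_a[q] = V_a[mon_a[q]]
    for q in range(nm_b):
        prev_b[q] = V_b[mon_b[q]]
    prev_trig = V_a[pre_trig_seg]
    armed_trig = 1
    last_trig = -1e12
    max_spk = spikes_a.shape[1]
    max_syn = syn_times.size

    sp_tau1 = -dt / np.log(sp_d1)
    sp_tau2 = -dt / np.log(sp_d2)
    am_tau1 = -dt / np.log(am_d1)
    am_tau2 = -dt / np.log(am_d2)
    nm_tau1 = -dt / np.log(nm_d1)
    nm_tau2 = -dt / np.log(nm_d2)

    for t_idx in range(n_steps):
        t = t_idx * dt
        t_end = t + dt
        # decay all conductance states over this step, then deliver the
        # events of this step pre-decayed by their exact residual time so
        # the sampled conductance is independent of dt
        sa1 *= sp_d1
        sa2 *= sp_d2
        sb1 *= sp_d1
        sb2 *= sp_d2
        am1 *= am_d1
        am2 *= am_d2
        nm1 *= nm_d1
        nm2 *= nm_d2
        while ia < spont_step_a.size and spont_step_a[ia] == t_idx:
            wn = spont_w_a[ia] * sp_ninv
            resid = t_end - spont_time_a[ia]
            sa1 += wn * np.exp(-resid / sp_tau1)
            sa2 += wn * np.exp(-resid / sp_tau2)
            ia += 1
        while ib < spont_step_b.size and spont_step_b[ib] == t_idx:
            wn = spont_w_b[ib] * sp_ninv
            resid = t_end - spont_time_b[ib]
            sb1 += wn * np.exp(-resid / sp_tau1)
            sb2 += wn * np.exp(-resid / sp_tau2)
            ib += 1
        gsyn_a[spont_seg] = sa1 - sa2
        gsyn_b[spont_seg] = sb1 - sb2
        g_conn = (am1 - am2) + (nm1 - nm2)
        if post_seg == spont_seg:
            gsyn_b[post_seg] += g_conn
        else:
            gsyn_b[post_seg] = g_conn

        err = cable_step_kernel(V_a, m_a, h_a, n_a, capdt_a, gax_a, gna_a,
                                gk_a, gl_a, ena, ek, el, gsyn_a, e_spont,
                                iext_a, tv0, tinv, tn, minf, mexp, hinf,
                                hexp, ninf, nexp)
        if err >= 0:
            return 1, n_settle + t_idx, 0, err, n_syn
        err = cable_step_kernel(V_b, m_b, h_b, n_b, capdt_b, gax_b, gna_b,
                                gk_b, gl_b, ena, ek, el, gsyn_b, e_spont,
                                iext_b, tv0, tinv, tn, minf, mexp, hinf,
                                hexp, ninf, nexp)
        if err >= 0:
            return 1, n_settle + t_idx, 1, err, n_syn

        # spike monitors: upward threshold crossing, linear interpolation,
        # refractory suppression
        for q in range(nm_a):
            v = V_a[mon_a[q]]
            if armed_a[q] == 1 and prev_a[q] < threshold <= v:
                ts = t + dt * (threshold - prev_a[q]) / (v - prev_a[q])
                if ts - last_a[q] >= refr:
                    if counts_a[q] < max_spk:
                        spikes_a[q, counts_a[q]] = ts
                        counts_a[q] += 1
                    last_a[q] = ts
                armed_a[q] = 0
            elif armed_a[q] == 0 and v < threshold - rearm:
                armed_a[q] = 1
            prev_a[q] = v
        for q in range(nm_b):
            v = V_b[mon_b[q]]
            if armed_b[q] == 1 and prev_b[q] < threshold <= v:
                ts = t + dt * (threshold - prev_b[q]) / (v - prev_b[q])
                if ts - last_b[q] >= refr:
                    if counts_b[q] < max_spk:
                        spikes_b[q, counts_b[q]] = ts
                        counts_b[q] += 1
                    last_b[q] = ts
                armed_b[q] = 0
            elif armed_b[q] == 0 and v < threshold - rearm:
                armed_b[q] = 1
            prev_b[q] = v
        # synaptic transmission trigger at the presynaptic segment nearest
        # z_syn: fresh AMPA + NMDA weights per activation
        v = V_a[pre_trig_seg]
        if armed_trig == 1 and prev_trig < threshold <= v:
            ts = t + dt * (threshold - prev_trig) / (v - prev_trig)
            armed_trig = 0
            if ts - last_trig >= refr:
                wa = ampa_w[iw % n_pool] * am_ninv
                wn = nmda_w[iw % n_pool] * nm_ninv
                iw += 1
                resid = t_end - ts
                am1 += wa * np.exp(-resid / am_tau1)
                am2 += wa * np.exp(-resid / am_tau2)
                nm1 += wn * np.exp(-resid / nm_tau1)
                nm2 += wn * np.exp(-resid / nm_tau2)
                if n_syn < max_syn:
                    syn_times[n_syn] = ts
                    n_syn += 1
                last_trig = ts
        elif armed_trig == 0 and v < threshold - rearm:
            armed_trig = 1
        prev_trig = v

        if rec_flag == 1:
            for i in range(ns_a):
                rec_Va[t_idx, i] = V_a[i]
            for i in range(ns_b):
                rec_Vb[t_idx, i] = V_b[i]

    return 0, n_steps, -1, -1, n_syn


# ----------------------------------------------------------------------
# transfer entropy (binary plug-in estimator)
# ----------------------------------------------------------------------


@njit(cache=True)
def past_codes(x, k):
    """Integer code of the k-bin past x_{t-1..t-k} for every t (0 for t<k)."""
    N = x.size
    p = np.zeros(N, np.int64)
    for t in range(k, N):
        c = 0
        for i in range(1, k + 1):
            c |= x[t - i] << (i - 1)
        p[t] = c
    return p


@njit(cache=True)
def binary_cmi(x, cond, ncond, y, d, shift, t0):
    """Plug-in I(X_t ; Y_{t-d+shift mod N} | cond_t) in bits.

    ``cond`` holds integer conditioning codes in [0, ncond); the source is
    read circularly so the same routine serves surrogate shifts.
    """
    N = x.size
    cj = np.zeros(ncond * 4, np.int64)
    for t in range(t0, N):
        yi = y[(t - d + shift) % N]
        cj[(cond[t] << 2) | (yi << 1) | x[t]] += 1
    total = N - t0
    te = 0.0
    for c in range(ncond):
        b = c << 2
        n00 = cj[b]       # y=0, x=0
        n01 = cj[b + 1]   # y=0, x=1
        n10 = cj[b + 2]   # y=1, x=0
        n11 = cj[b + 3]   # y=1, x=1
        nc = n00 + n01 + n10 + n11
        if nc == 0:
            continue
        nx0 = n00 + n10
        nx1 = n01 + n11
        ny0 = n00 + n01
        ny1 = n10 + n11
        if n00 > 0:
            te += n00 * np.log2(n00 * nc / (nx0 * ny0))
        if n01 > 0:
            te += n01 * np.log2(n01 * nc / (nx1 * ny0))
        if n10 > 0:
            te += n10 * np.log2(n10 * nc / (nx0 * ny1))
        if n11 > 0:
            te += n11 * np.log2(n11 * nc / (nx1 * ny1))
    te /= total
    if te < 0.0:
        te = 0.0
    return te


@njit(cache=True)
def te_grid(x, y, kmax, d_lo, d_hi, shift, extra_cond, n_extra):
    """TE over the (k, delta) grid at one source shift.

    Returns a (kmax, d_hi-d_lo+1) array.  ``extra_cond`` carries combined
    past codes of any conditioning processes (all zeros and n_extra=1 for
    the bivariate case); the target past code is combined with it.
    """
    nd = d_hi - d_lo + 1
    out = np.empty((kmax, nd))
    t0 = kmax + d_hi
    for k in range(1, kmax + 1):
        p = past_codes(x, k)
        if n_extra > 1:
            cond = p * n_extra + extra_cond
            ncond = (1 << k) * n_extra
        else:
            cond = p
            ncond = 1 << k
        for di in range(nd):
            out[k - 1, di] = binary_cmi(x, cond, ncond, y, d_lo + di,
                                        shift, t0)
    return out


@njit(cache=True)
def te_grid_max(x, y, kmax, d_lo, d_hi, shift, extra_cond, n_extra):
    """Maximum TE over the grid; ties broken toward the smallest delta,
    then the smallest k.  Returns (te, k_star, delta_star)."""
    g = te_grid(x, y, kmax, d_lo, d_hi, shift, extra_cond, n_extra)
    best = -1.0
    bk = 1
    bd = d_lo
    nd = d_hi - d_lo + 1
    for di in range(nd):
        for k in range(1, kmax + 1):
            v = g[k - 1, di]
            if v > best + 1e-13:
                best = v
                bk = k
                bd = d_lo + di
    return best, bk, bd


@njit(cache=True)
def te_perm_counts(x, y, kmax, d_lo, d_hi, shifts, extra_cond, n_extra):
    """Observed max-TE plus the count of surrogate maxima >= observed.

    Surrogates are circular shifts of the source; the surrogate statistic
    is the same grid maximum as the observed one (matched selection)."""
    obs, bk, bd = te_grid_max(x, y, kmax, d_lo, d_hi, 0, extra_cond, n_extra)
    cnt = 0
    for si in range(shifts.size):
        tes, _, _ = te_grid_max(x, y, kmax, d_lo, d_hi, shifts[si],
                                extra_cond, n_extra)
        if tes >= obs - 1e-12:
            cnt += 1
    return obs, bk, bd, cnt


# ----------------------------------------------------------------------
# spike matching across axial sites
# ----------------------------------------------------------------------


@njit(cache=True)
def match_spikes_kernel(a, b, max_lat):
    """Order-preserving one-to-one matching of a -> b with latency in
    (0, max_lat]; maximum cardinality, then minimum total latency.
    Returns (n_matched, 2) index pairs into a and b."""
    n = a.size
    m = b.size
    M = np.zeros((n + 1, m + 1), np.int64)
    L = np.zeros((n + 1, m + 1))
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            bm = M[i + 1, j]
            bl = L[i + 1, j]
            if M[i, j + 1] > bm or (M[i, j + 1] == bm and L[i, j + 1] < bl):
                bm = M[i, j + 1]
                bl = L[i, j + 1]
            d = b[j] - a[i]
            if 0.0 < d <= max_lat:
                cm = M[i + 1, j + 1] + 1
                cl = L[i + 1, j + 1] + d
                if cm > bm or (cm == bm and cl < bl):
                    bm = cm
                    bl = cl
            M[i, j] = bm
            L[i, j] = bl
    pairs = np.empty((M[0, 0], 2), np.int64)
    i = 0
    j = 0
    kk = 0
    while i < n and j < m:
        bm = M[i + 1, j]
        bl = L[i + 1, j]
        choice = 0
        if M[i, j + 1] > bm or (M[i, j + 1] == bm and L[i, j + 1] < bl):
            bm = M[i, j + 1]
            bl = L[i, j + 1]
            choice = 1
        d = b[j] - a[i]
        if 0.0 < d <= max_lat:
            cm = M[i + 1, j + 1] + 1
            cl = L[i + 1, j + 1] + d
            if cm > bm or (cm == bm and cl < bl):
                choice = 2
        if choice == 2:
            pairs[kk, 0] = i
            pairs[kk, 1] = j
            kk += 1
            i += 1
            j += 1
        elif choice == 0:
            i += 1
        else:
            j += 1
    return pairs[:kk]
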