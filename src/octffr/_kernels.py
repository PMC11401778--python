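"""Tight inner time loops, compiled with numba when available.

Both kernels are plain scalar state-steppers; the surrounding modules do all
unit handling, network reduction and convergence bookkeeping. The pure-Python
fallbacks are the same functions undecorated, so numerical behaviour is
identical either way.
"""
from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def driver_loop(shape, dt, n_warm_cycles, n_store_cycles, stride,
                e_max, e_min, v0, r_mv, p_ven, r_c, l_av,
                c_prox, r_prox, l_prox, c_a, r_p, v_init, p_init):
    """Open-loop LV + aortic-root stepper (forward Euler at substep dt).

    ``shape`` is the normalized elastance activation over one cycle, sampled
    at the substep grid. Returns the aortic (proximal-root) and LV pressure
    traces of the last ``n_store_cycles`` cycles at ``stride`` decimation,
    plus the final state for warm restarts.
    """
    n_sub = shape.shape[0]
    n_total = (n_warm_cycles + n_store_cycles) * n_sub
    n_out = (n_store_cycles * n_sub) // stride
    pa_out = np.empty(n_out)
    plv_out = np.empty(n_out)

    v = v_init
    q_av = 0.0
    q_pa = 0.0
    p_pr = p_init
    p_ao = p_init
    k = 0
    start_store = n_warm_cycles * n_sub
    for i in range(n_total):
        e = e_min + (e_max - e_min) * shape[i % n_sub]
        plv = e * (v - v0)
        q_mv = (p_ven - plv) / r_mv if plv < p_ven else 0.0
        if q_av > 0.0 or plv > p_pr:
            dq = (plv - p_pr - r_c * q_av) / l_av
        else:
            q_av = 0.0
            dq = 0.0
        dq_pa = (p_pr - p_ao - r_prox * q_pa) / l_prox
        if i >= start_store and (i - start_store) % stride == 0 and k < n_out:
            pa_out[k] = p_pr
            plv_out[k] = plv
            k += 1
        v += dt * (q_mv - q_av)
        q_av += dt * dq
        if q_av < 0.0:
            q_av = 0.0
        p_pr += dt * (q_av - q_pa) / c_prox
        q_pa += dt * dq_pa
        p_ao += dt * (q_pa - p_ao / r_p) / c_a
    return pa_out, plv_out, v, p_pr


@njit(cache=True)
def coronary_loop(pa, plv, dt,
                  ka, kd, kv, kdd, k_conv,
                  na, nd, nv, ndd,
                  la, ld, lv, ldd,
                  ia, id_, iv, idd,
                  g_pdv, g_vout, cd, cv, coupling, p_ra, p_im_out,
                  max_cycles, conv_tol, d_tol, pd0, pv0):
    """Advance the coronary R-C network to its periodic steady state.

    ``pa``/``plv`` hold one cardiac cycle on the solver grid and are reused
    cyclically. The quasi-steady epicardial chain has been reduced to affine
    output maps in (Pa, Pd, Pv, d) with d the quadratic expansion drop; the
    two compliance states are advanced by implicit Euler with a fixed-point
    iteration on d. The venous outlet is a vascular waterfall: outflow is
    g_vout * max(Pv - max(p_ra, p_im_out*P_LV), 0). Returns the last cycle's
    traces, the cycle count, the worst chain flow-balance residual and a
    convergence flag.
    """
    n = pa.shape[0]
    beta = -kdd * k_conv
    # constant implicit-Euler matrices (outlet open / collapsed), inverted once
    m11 = 1.0 - (dt / cd) * (nd - g_pdv)
    m12 = -(dt / cd) * (nv + g_pdv)
    m21 = -(dt / cv) * (ld + g_pdv)
    m22 = 1.0 - (dt / cv) * (lv - g_pdv - g_vout)
    det = m11 * m22 - m12 * m21
    i11 = m22 / det
    i12 = -m12 / det
    i21 = -m21 / det
    i22 = m11 / det
    m22b = 1.0 - (dt / cv) * (lv - g_pdv)
    detb = m11 * m22b - m12 * m21
    b11 = m22b / detb
    b12 = -m12 / detb
    b21 = -m21 / detb
    b22 = m11 / detb

    pd_tr = np.empty(n)
    pv_tr = np.empty(n)
    qin_tr = np.empty(n)
    qout_tr = np.empty(n)
    leak_tr = np.empty(n)
    d_tr = np.empty(n)

    pd = pd0
    pv = pv0
    d = 0.0
    plv_prev = plv[n - 1]
    mean_prev = -1.0
    max_res = 0.0
    cycles = 0
    converged = False
    for cyc in range(max_cycles):
        acc_pd = 0.0
        for j in range(n):
            pa_j = pa[j]
            dplv = coupling * (plv[j] - plv_prev)
            plv_prev = plv[j]
            p_out = p_im_out * plv[j]
            if p_out < p_ra:
                p_out = p_ra
            pd_n = pd
            pv_n = pv
            for _ in range(60):
                r1 = pd + (dt / cd) * (na * pa_j + ndd * d)
                r2 = pv + dplv + (dt / cv) * (la * pa_j + ldd * d + g_vout * p_out)
                pd_n = i11 * r1 + i12 * r2
                pv_n = i21 * r1 + i22 * r2
                if pv_n <= p_out:
                    # outlet collapsed: re-solve without the outflow branch
                    r2b = pv + dplv + (dt / cv) * (la * pa_j + ldd * d)
                    pd_n = b11 * r1 + b12 * r2b
                    pv_n = b21 * r1 + b22 * r2b
                a0 = ka * pa_j + kd * pd_n + kv * pv_n
                if beta > 0.0:
                    s = 1.0 if a0 >= 0.0 else -1.0
                    qm = s * (math.sqrt(1.0 + 4.0 * beta * abs(a0)) - 1.0) / (2.0 * beta)
                else:
                    qm = a0
                d_new = k_conv * qm * abs(qm)
                if abs(d_new - d) < d_tol:
                    d = d_new
                    break
                d = d_new
            pd = pd_n
            pv = pv_n
            q_in = ia * pa_j + id_ * pd + iv * pv + idd * d
            q_out = na * pa_j + nd * pd + nv * pv + ndd * d
            leak = la * pa_j + ld * pd + lv * pv + ldd * d
            res = abs(q_in - leak - q_out)
            if res > max_res:
                max_res = res
            pd_tr[j] = pd
            pv_tr[j] = pv
            qin_tr[j] = q_in
            qout_tr[j] = q_out
            leak_tr[j] = leak
            d_tr[j] = d
            acc_pd += pd
        cycles = cyc + 1
        mean_pd = acc_pd / n
        if mean_prev >= 0.0 and abs(mean_pd - mean_prev) <= conv_tol * max(abs(mean_pd), 1e-9):
            converged = True
            break
        mean_prev = mean_pd
    return pd_tr, pv_tr, qin_tr, qout_tr, leak_tr, d_tr, cycles, max_res, converged
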