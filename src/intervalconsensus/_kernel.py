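"""Numba-compiled twin of the ICM log-posterior gradient.

``ICMPosterior.logp_and_grad`` (pure numpy) is the reference implementation;
this module provides a numerically identical compiled kernel used for speed
during sampling.  The test-suite asserts agreement between the two routes to
tight tolerance.  Configuration-dependent normalising constants are
precomputed by the caller and added to the kernel's output.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


_LOG_2PI = np.log(2.0 * np.pi)


@njit(cache=False, error_model="numpy")
def _h_expand(theta, off, m, out):
    """Helmert expansion: m free coords at theta[off:] -> (m+1) sum-zero out."""
    acc = 0.0
    for k in range(m - 1, -1, -1):
        c = 1.0 / np.sqrt((k + 1.0) * (k + 2.0))
        tk = theta[off + k] * c
        out[k + 1] = acc - (k + 1.0) * tk
        acc += tk
    out[0] = acc


@njit(cache=False, error_model="numpy")
def _h_contract_into(gfull, m, grad, goff, theta, zoff):
    """grad[goff+k] = (Helmert adjoint of gfull)[k] - theta[zoff+k]."""
    prefix = 0.0
    for k in range(m):
        prefix += gfull[k]
        c = 1.0 / np.sqrt((k + 1.0) * (k + 2.0))
        grad[goff + k] = c * (prefix - (k + 1.0) * gfull[k + 1]) - theta[zoff + k]


@njit(cache=False, error_model="numpy")
def logp_grad_kernel(
    theta, y, oi, oj, N, J,
    alpha_w, beta_w, alpha_l, beta_l, s_rho, s_om, hs,
    inc_a, inc_bl, inc_bw, est_corr, om_E_fix, om_L_fix,
    k1, k2,
    o_xi, o_zeta, o_zll, o_zlw, o_rr, o_zel, o_zew,
    o_za, o_zbl, o_zbw, o_mu, o_lsE, o_lsL, o_lsa, o_lsbl, o_lsbw, o_tE, o_tL,
    grad,
):
    lp = 0.0
    grad[:] = 0.0

    # --- consensus blocks ---
    w = np.empty(J)
    lamstar = np.empty(J)
    T_loc = np.empty(J)
    T_wid = np.empty(J)
    rho = np.empty(J)
    for j in range(J):
        xi = theta[o_xi + j]
        zeta = theta[o_zeta + j]
        wj = 1.0 / (1.0 + np.exp(-xi))
        lj = 1.0 / (1.0 + np.exp(-zeta))
        w[j] = wj
        lamstar[j] = lj
        T_loc[j] = k1 * zeta
        T_wid[j] = k2 * (xi - 0.5 * (np.log(lj) + np.log1p(-lj)))
        rho[j] = np.tanh(theta[o_rr + j])

    sE0 = np.exp(theta[o_lsE])
    sE1 = np.exp(theta[o_lsE + 1])
    sL0 = np.exp(theta[o_lsL])
    sL1 = np.exp(theta[o_lsL + 1])
    if est_corr:
        om_E = np.tanh(theta[o_tE])
        om_L = np.tanh(theta[o_tL])
    else:
        om_E = om_E_fix
        om_L = om_L_fix
    sqE = np.sqrt(1.0 - om_E * om_E)
    sqL = np.sqrt(1.0 - om_L * om_L)

    # sum-to-zero discernibility innovations (Helmert basis)
    zfl = np.empty(J)
    zfw = np.empty(J)
    _h_expand(theta, o_zll, J - 1, zfl)
    _h_expand(theta, o_zlw, J - 1, zfw)
    v_loc = np.empty(J)
    v_wid = np.empty(J)
    for j in range(J):
        v_loc[j] = sL0 * zfl[j]
        v_wid[j] = sL1 * (om_L * zfl[j] + sqL * zfw[j])

    # proficiencies
    mu0 = theta[o_mu]
    mu1 = theta[o_mu + 1]
    el = np.empty(N)
    ew = np.empty(N)
    for i in range(N):
        z1 = theta[o_zel + i]
        z2 = theta[o_zew + i]
        el[i] = mu0 + sE0 * z1
        ew[i] = mu1 + sE1 * (om_E * z1 + sqE * z2)

    # scaling biases: a = N * softmax(sigma_a * zf)
    loga = np.zeros(N)
    a = np.ones(N)
    prob = np.empty(N)
    zfa = np.zeros(N)
    ua = np.zeros(N)
    sigma_a = 1.0
    if inc_a:
        sigma_a = np.exp(theta[o_lsa])
        _h_expand(theta, o_za, N - 1, zfa)
        m_ = -1e300
        for i in range(N):
            ua[i] = sigma_a * zfa[i]
            if ua[i] > m_:
                m_ = ua[i]
        lse = 0.0
        for i in range(N):
            lse += np.exp(ua[i] - m_)
        lse = m_ + np.log(lse)
        for i in range(N):
            loga[i] = np.log(N) + ua[i] - lse
            a[i] = np.exp(loga[i])
            prob[i] = a[i] / N

    # shifting biases
    bl = np.zeros(N)
    bw = np.zeros(N)
    zfbl = np.zeros(N)
    zfbw = np.zeros(N)
    sigma_bl = 1.0
    sigma_bw = 1.0
    if inc_bl:
        sigma_bl = np.exp(theta[o_lsbl])
        _h_expand(theta, o_zbl, N - 1, zfbl)
        for i in range(N):
            bl[i] = sigma_bl * zfbl[i]
    if inc_bw:
        sigma_bw = np.exp(theta[o_lsbw])
        _h_expand(theta, o_zbw, N - 1, zfbw)
        for i in range(N):
            bw[i] = sigma_bw * zfbw[i]

    # --- likelihood ---
    g_el = np.zeros(N)
    g_ew = np.zeros(N)
    g_bl = np.zeros(N)
    g_bw = np.zeros(N)
    g_loga = np.zeros(N)
    g_vl = np.zeros(J)
    g_vw = np.zeros(J)
    g_Tl = np.zeros(J)
    g_Tw = np.zeros(J)
    g_rho = np.zeros(J)

    n_obs = oi.shape[0]
    for k in range(n_obs):
        i = oi[k]
        j = oj[k]
        log_sl = loga[i] - el[i] - v_loc[j]
        log_sw = -ew[i] - v_wid[j]
        sl = np.exp(log_sl)
        sw = np.exp(log_sw)
        R = rho[j]
        q = 1.0 / (1.0 - R * R)
        mu_l = a[i] * T_loc[j] + bl[i]
        mu_w = T_wid[j] + bw[i]
        dl = (y[k, 0] - mu_l) / sl
        dw = (y[k, 1] - mu_w) / sw
        S = dl * dl - 2.0 * R * dl * dw + dw * dw
        lp += -_LOG_2PI - log_sl - log_sw + 0.5 * np.log(q) - 0.5 * q * S

        gm_l = q * (dl - R * dw) / sl
        gm_w = q * (dw - R * dl) / sw
        gls_l = -1.0 + q * dl * (dl - R * dw)
        gls_w = -1.0 + q * dw * (dw - R * dl)
        g_el[i] -= gls_l
        g_ew[i] -= gls_w
        g_bl[i] += gm_l
        g_bw[i] += gm_w
        g_loga[i] += a[i] * T_loc[j] * gm_l + gls_l
        g_vl[j] -= gls_l
        g_vw[j] -= gls_w
        g_Tl[j] += a[i] * gm_l
        g_Tw[j] += gm_w
        g_rho[j] += R * q - R * q * q * S + q * dl * dw

    # --- consensus priors + chain rule into xi/zeta ---
    for j in range(J):
        lp += alpha_w * np.log(w[j]) + beta_w * np.log1p(-w[j])
        lp += alpha_l * np.log(lamstar[j]) + beta_l * np.log1p(-lamstar[j])
        grad[o_xi + j] = k2 * g_Tw[j] + alpha_w - (alpha_w + beta_w) * w[j]
        grad[o_zeta + j] = (
            k1 * g_Tl[j]
            - 0.5 * k2 * (1.0 - 2.0 * lamstar[j]) * g_Tw[j]
            + alpha_l
            - (alpha_l + beta_l) * lamstar[j]
        )
        lp += s_rho * np.log1p(-rho[j] * rho[j])
        grad[o_rr + j] = (1.0 - rho[j] * rho[j]) * g_rho[j] - 2.0 * s_rho * rho[j]

    # --- discernibilities ---
    g_lsL0 = 0.0
    g_lsL1 = 0.0
    gl_full = np.empty(J)
    gw_full = np.empty(J)
    for j in range(J):
        g_lsL0 += g_vl[j] * v_loc[j]
        g_lsL1 += g_vw[j] * v_wid[j]
        gl_full[j] = sL0 * g_vl[j] + sL1 * om_L * g_vw[j]
        gw_full[j] = sL1 * sqL * g_vw[j]
    for j in range(J - 1):
        zj = theta[o_zll + j]
        zw = theta[o_zlw + j]
        lp += -0.5 * (zj * zj + zw * zw)
    _h_contract_into(gl_full, J - 1, grad, o_zll, theta, o_zll)
    _h_contract_into(gw_full, J - 1, grad, o_zlw, theta, o_zlw)
    grad[o_lsL] = g_lsL0
    grad[o_lsL + 1] = g_lsL1

    # --- proficiencies ---
    sum_gel = 0.0
    sum_gew = 0.0
    g_lsE0 = 0.0
    g_lsE1 = 0.0
    for i in range(N):
        z1 = theta[o_zel + i]
        z2 = theta[o_zew + i]
        lp += -0.5 * (z1 * z1 + z2 * z2)
        grad[o_zel + i] = sE0 * g_el[i] + sE1 * om_E * g_ew[i] - z1
        grad[o_zew + i] = sE1 * sqE * g_ew[i] - z2
        sum_gel += g_el[i]
        sum_gew += g_ew[i]
        g_lsE0 += g_el[i] * z1
        g_lsE1 += g_ew[i] * (om_E * z1 + sqE * z2)
    lp += -0.5 * (mu0 * mu0 + mu1 * mu1)
    grad[o_mu] = sum_gel - mu0
    grad[o_mu + 1] = sum_gew - mu1
    grad[o_lsE] = sE0 * g_lsE0
    grad[o_lsE + 1] = sE1 * g_lsE1

    # --- scaling biases ---
    if inc_a:
        sum_gloga = 0.0
        for i in range(N):
            sum_gloga += g_loga[i]
        g_lsa = 0.0
        gu_full = np.empty(N)
        for i in range(N):
            gu = g_loga[i] - prob[i] * sum_gloga
            gu_full[i] = sigma_a * gu
            g_lsa += gu * ua[i]
        for i in range(N - 1):
            zi = theta[o_za + i]
            lp += -0.5 * zi * zi
        _h_contract_into(gu_full, N - 1, grad, o_za, theta, o_za)
        grad[o_lsa] = g_lsa

    # --- shifting biases ---
    if inc_bl:
        g_lsbl = 0.0
        gb_full = np.empty(N)
        for i in range(N):
            g_lsbl += g_bl[i] * zfbl[i]
            gb_full[i] = sigma_bl * g_bl[i]
        for i in range(N - 1):
            zi = theta[o_zbl + i]
            lp += -0.5 * zi * zi
        _h_contract_into(gb_full, N - 1, grad, o_zbl, theta, o_zbl)
        grad[o_lsbl] = sigma_bl * g_lsbl
    if inc_bw:
        g_lsbw = 0.0
        gb_full = np.empty(N)
        for i in range(N):
            g_lsbw += g_bw[i] * zfbw[i]
            gb_full[i] = sigma_bw * g_bw[i]
        for i in range(N - 1):
            zi = theta[o_zbw + i]
            lp += -0.5 * zi * zi
        _h_contract_into(gb_full, N - 1, grad, o_zbw, theta, o_zbw)
        grad[o_lsbw] = sigma_bw * g_lsbw

    # --- half-normal hyperpriors on scales ---
    lp += theta[o_lsE] - 0.5 * (sE0 / hs) ** 2
    grad[o_lsE] += 1.0 - (sE0 / hs) ** 2
    lp += theta[o_lsE + 1] - 0.5 * (sE1 / hs) ** 2
    grad[o_lsE + 1] += 1.0 - (sE1 / hs) ** 2
    lp += theta[o_lsL] - 0.5 * (sL0 / hs) ** 2
    grad[o_lsL] += 1.0 - (sL0 / hs) ** 2
    lp += theta[o_lsL + 1] - 0.5 * (sL1 / hs) ** 2
    grad[o_lsL + 1] += 1.0 - (sL1 / hs) ** 2
    if inc_a:
        lp += theta[o_lsa] - 0.5 * (sigma_a / hs) ** 2
        grad[o_lsa] += 1.0 - (sigma_a / hs) ** 2
    if inc_bl:
        lp += theta[o_lsbl] - 0.5 * (sigma_bl / hs) ** 2
        grad[o_lsbl] += 1.0 - (sigma_bl / hs) ** 2
    if inc_bw:
        lp += theta[o_lsbw] - 0.5 * (sigma_bw / hs) ** 2
        grad[o_lsbw] += 1.0 - (sigma_bw / hs) ** 2

    # --- estimated correlations ---
    if est_corr:
        acc = 0.0
        for i in range(N):
            z1 = theta[o_zel + i]
            z2 = theta[o_zew + i]
            acc += g_ew[i] * (z1 - (om_E / sqE) * z2)
        lp += s_om * np.log1p(-om_E * om_E)
        grad[o_tE] = (1.0 - om_E * om_E) * sE1 * acc - 2.0 * s_om * om_E
        acc = 0.0
        for j in range(J):
            acc += g_vw[j] * (zfl[j] - (om_L / sqL) * zfw[j])
        lp += s_om * np.log1p(-om_L * om_L)
        grad[o_tL] = (1.0 - om_L * om_L) * sL1 * acc - 2.0 * s_om * om_L

    return lp
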