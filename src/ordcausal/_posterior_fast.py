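"""Numba-compiled kernel for the log posterior and its gradient.

This mirrors ``_posterior.OrdinalPosterior._value_and_grad`` exactly — the
test suite asserts bitwise-level agreement between the two — but fuses the
per-row likelihood work into one loop, which makes NUTS roughly an order
of magnitude faster.  If numba is unavailable the pure-numpy path is used
instead.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]

J = 6
NEG_INF = float("-inf")


@njit(cache=False, fastmath=False)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=False, fastmath=False)
def _simplex_fwd(y, d, alpha, zeta, z, cp):
    """Stick-breaking forward pass; returns the log prior+Jacobian term."""
    logp = 0.0
    run = 1.0
    for t in range(d - 1):
        zt = _sigmoid(y[t] - math.log(d - 1.0 - t))
        if zt < 1e-15:
            zt = 1e-15
        elif zt > 1.0 - 1e-15:
            zt = 1.0 - 1e-15
        z[t] = zt
        zeta[t] = zt * run
        run *= 1.0 - zt
        cp[t] = run
        logp += math.log(zt) + (d - 1.0 - t) * math.log(1.0 - zt)
    zeta[d - 1] = run
    for t in range(d):
        logp += (alpha - 1.0) * math.log(zeta[t])
    return logp


@njit(cache=False, fastmath=False)
def _simplex_bwd(g_zeta_in, zeta, z, cp, d, alpha, g_y):
    tail = 0.0
    # accumulate from the top so tail holds sum_{t>u} g_zeta[t]*zeta[t]
    g_zeta_top = g_zeta_in[d - 1] + (alpha - 1.0) / zeta[d - 1]
    tail = g_zeta_top * zeta[d - 1]
    for u in range(d - 2, -1, -1):
        g_z = (g_zeta_in[u] + (alpha - 1.0) / zeta[u])
        cp_prev = 1.0 if u == 0 else cp[u - 1]
        onemz = 1.0 - z[u]
        val = g_z * cp_prev - tail / onemz
        val += 1.0 / z[u] - (d - 1.0 - u) / onemz
        g_y[u] = val * z[u] * onemz
        tail += (g_zeta_in[u] + (alpha - 1.0) / zeta[u]) * zeta[u]
    return


@njit(cache=False, fastmath=False)
def logp_grad_kernel(
    theta, grad,
    site_idx, sex, food, edu, age_idx, child, y,
    S, K, DE, DA, DC,
    ts2, cs2, alpha, sd_rate, lkj_a,
):
    """Compute (log posterior, gradient) in one fused pass.

    ``grad`` is overwritten in place; the return value is the log density.
    Layout of ``theta`` matches ``OrdinalPosterior.slices``.
    """
    n = site_idx.shape[0]
    n_corr = J * (J - 1) // 2

    o_c = 0
    o_b = o_c + K - 1
    o_ye = o_b + 5
    o_ya = o_ye + DE - 1
    o_yc = o_ya + DA - 1
    o_s = o_yc + DC - 1
    o_w = o_s + J
    o_z = o_w + n_corr
    dim = o_z + J * S

    for i in range(dim):
        grad[i] = 0.0

    logp = 0.0

    # cutpoints
    kappa = np.empty(K - 1)
    kappa[0] = theta[o_c]
    for j in range(1, K - 1):
        kappa[j] = kappa[j - 1] + math.exp(theta[o_c + j])
    for j in range(K - 1):
        logp -= 0.5 * kappa[j] * kappa[j] / ts2
    for j in range(1, K - 1):
        logp += theta[o_c + j]

    beta = theta[o_b: o_b + 5]
    for j in range(5):
        logp -= 0.5 * beta[j] * beta[j] / cs2

    zetaE = np.empty(DE)
    zE = np.empty(max(DE - 1, 1))
    cpE = np.empty(max(DE - 1, 1))
    if DE > 1:
        logp += _simplex_fwd(theta[o_ye: o_ye + DE - 1], DE, alpha, zetaE, zE, cpE)
    else:
        zetaE[0] = 1.0
    zetaA = np.empty(DA)
    zA = np.empty(max(DA - 1, 1))
    cpA = np.empty(max(DA - 1, 1))
    if DA > 1:
        logp += _simplex_fwd(theta[o_ya: o_ya + DA - 1], DA, alpha, zetaA, zA, cpA)
    else:
        zetaA[0] = 1.0
    zetaC = np.empty(DC)
    zC = np.empty(max(DC - 1, 1))
    cpC = np.empty(max(DC - 1, 1))
    if DC > 1:
        logp += _simplex_fwd(theta[o_yc: o_yc + DC - 1], DC, alpha, zetaC, zC, cpC)
    else:
        zetaC[0] = 1.0

    sigma = np.empty(J)
    for j in range(J):
        sigma[j] = math.exp(theta[o_s + j])
        logp += -sd_rate * sigma[j] + theta[o_s + j]

    # correlation CPCs -> Cholesky
    zc = np.empty(n_corr)
    for t in range(n_corr):
        zc[t] = math.tanh(theta[o_w + t])
        one_m = 1.0 - zc[t] * zc[t]
        if one_m <= 0.0:
            return NEG_INF
        logp += lkj_a[t] * math.log(one_m)

    L = np.zeros((J, J))
    L[0, 0] = 1.0
    rems = np.zeros((J, J + 1))
    idx = 0
    for i in range(1, J):
        rem = 1.0
        rems[i, 0] = 1.0
        for col in range(i):
            L[i, col] = zc[idx] * math.sqrt(rem)
            rem *= 1.0 - zc[idx] * zc[idx]
            rems[i, col + 1] = rem
            idx += 1
        L[i, i] = math.sqrt(rem)

    # site effects U = diag(sigma) L Z, Z standard normal
    U = np.zeros((J, S))
    for j in range(J):
        for jj in range(j + 1):
            a_jjj = sigma[j] * L[j, jj]
            for s_ in range(S):
                U[j, s_] += a_jjj * theta[o_z + jj * S + s_]
    for t in range(J * S):
        zv = theta[o_z + t]
        logp += -0.5 * zv * zv

    # mo lookup tables
    moE = np.empty(DE + 1)
    moE[0] = 0.0
    for t in range(DE):
        moE[t + 1] = moE[t] + DE * zetaE[t]
    moA = np.empty(DA + 1)
    moA[0] = 0.0
    for t in range(DA):
        moA[t + 1] = moA[t] + DA * zetaA[t]
    moC = np.empty(DC + 1)
    moC[0] = 0.0
    for t in range(DC):
        moC[t + 1] = moC[t] + DC * zetaC[t]

    if not math.isfinite(logp):
        return NEG_INF

    # fused likelihood + per-row gradient accumulation
    g_kappa = np.zeros(K - 1)
    g_B = np.zeros((J, S))
    g_moE = np.zeros(DE + 1)
    g_moA = np.zeros(DA + 1)
    g_moC = np.zeros(DC + 1)

    for i in range(n):
        s_ = site_idx[i]
        x3 = moE[edu[i]]
        x4 = moA[age_idx[i]]
        x5 = moC[child[i]]
        c3 = beta[2] + U[3, s_]
        c4 = beta[3] + U[4, s_]
        c5 = beta[4] + U[5, s_]
        xi = (
            U[0, s_]
            + (beta[0] + U[1, s_]) * sex[i]
            + (beta[1] + U[2, s_]) * food[i]
            + c3 * x3 + c4 * x4 + c5 * x5
        )
        k = y[i]
        if k <= K - 1:
            e_hi = _sigmoid(kappa[k - 1] - xi)
            phi_hi = e_hi * (1.0 - e_hi)
        else:
            e_hi = 1.0
            phi_hi = 0.0
        if k >= 2:
            e_lo = _sigmoid(kappa[k - 2] - xi)
            phi_lo = e_lo * (1.0 - e_lo)
        else:
            e_lo = 0.0
            phi_lo = 0.0
        P = e_hi - e_lo
        if P < 1e-300:
            P = 1e-300
        logp += math.log(P)
        invP = 1.0 / P
        g_xi = (phi_lo - phi_hi) * invP
        if k <= K - 1:
            g_kappa[k - 1] += phi_hi * invP
        if k >= 2:
            g_kappa[k - 2] -= phi_lo * invP
        g_B[0, s_] += g_xi
        g_B[1, s_] += g_xi * sex[i]
        g_B[2, s_] += g_xi * food[i]
        g_B[3, s_] += g_xi * x3
        g_B[4, s_] += g_xi * x4
        g_B[5, s_] += g_xi * x5
        g_moE[edu[i]] += g_xi * c3
        g_moA[age_idx[i]] += g_xi * c4
        g_moC[child[i]] += g_xi * c5

    if not math.isfinite(logp):
        return NEG_INF

    # ---- backward ----
    for j in range(K - 1):
        g_kappa[j] -= kappa[j] / ts2
    rc = 0.0
    for j in range(K - 2, 0, -1):
        rc += g_kappa[j]
        grad[o_c + j] = math.exp(theta[o_c + j]) * rc + 1.0
    grad[o_c] = rc + g_kappa[0]

    for j in range(5):
        gb = -beta[j] / cs2
        for s_ in range(S):
            gb += g_B[j + 1, s_]
        grad[o_b + j] = gb

    # mo gradients -> simplex coordinates
    if DE > 1:
        g_zeta = np.empty(DE)
        acc = 0.0
        for v in range(DE, 0, -1):
            acc += g_moE[v]
            g_zeta[v - 1] = DE * acc
        _simplex_bwd(g_zeta, zetaE, zE, cpE, DE, alpha,
                     grad[o_ye: o_ye + DE - 1])
    if DA > 1:
        g_zeta = np.empty(DA)
        acc = 0.0
        for v in range(DA, 0, -1):
            acc += g_moA[v]
            g_zeta[v - 1] = DA * acc
        _simplex_bwd(g_zeta, zetaA, zA, cpA, DA, alpha,
                     grad[o_ya: o_ya + DA - 1])
    if DC > 1:
        g_zeta = np.empty(DC)
        acc = 0.0
        for v in range(DC, 0, -1):
            acc += g_moC[v]
            g_zeta[v - 1] = DC * acc
        _simplex_bwd(g_zeta, zetaC, zC, cpC, DC, alpha,
                     grad[o_yc: o_yc + DC - 1])

    # site-effect chain: U = A Z with A = diag(sigma) L
    g_A = np.zeros((J, J))
    for j in range(J):
        for jj in range(j + 1):
            acc = 0.0
            for s_ in range(S):
                acc += g_B[j, s_] * theta[o_z + jj * S + s_]
            g_A[j, jj] = acc
    # g_Z = A^T g_U - Z
    for jj in range(J):
        for s_ in range(S):
            acc = -theta[o_z + jj * S + s_]
            for j in range(jj, J):
                acc += sigma[j] * L[j, jj] * g_B[j, s_]
            grad[o_z + jj * S + s_] = acc
    for j in range(J):
        g_sig = 0.0
        for jj in range(j + 1):
            g_sig += g_A[j, jj] * L[j, jj]
        grad[o_s + j] = g_sig * sigma[j] + (-sd_rate * sigma[j] + 1.0)

    # Cholesky backward to the partial correlations
    idx = n_corr
    for i in range(J - 1, 0, -1):
        base = idx - i
        g_rem_next = sigma[i] * g_A[i, i] * 0.5 / math.sqrt(rems[i, i])
        for col in range(i - 1, -1, -1):
            zv = zc[base + col]
            sq = math.sqrt(rems[i, col])
            gL = sigma[i] * g_A[i, col]
            g_zc = gL * sq - 2.0 * zv * rems[i, col] * g_rem_next
            g_rem_next = gL * zv * 0.5 / sq + g_rem_next * (1.0 - zv * zv)
            grad[o_w + base + col] = (
                g_zc * (1.0 - zv * zv) - 2.0 * lkj_a[base + col] * zv
            )
        idx = base

    return logp
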