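"""Compiled inner loop of the MGRLMM log posterior.

A numba translation of :meth:`mgrlmm._posterior.MgrlmmPosterior.logp_grad`,
looping over subject-wave rows and items instead of allocating masked
arrays.  The numpy implementation remains the reference; the test suite
asserts the two agree to close to machine precision.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["logp_grad_kernel"]


@njit(cache=True)
def _expit(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _softplus(x: float) -> float:
    if x > 30.0:
        return x
    if x < -30.0:
        return math.exp(x)
    return math.log1p(math.exp(x))


@njit(cache=True)
def logp_grad_kernel(
    z,
    y,  # (R, J) int64, -1 = missing
    X,  # (R, P)
    subj_idx,  # (R,) int64
    n_subjects,
    A0,  # (J, D) anchor rows, zeros in free slots
    free_j,  # free-loading item indices
    free_d,  # free-loading dimension indices
    offsets,  # (8,) int64 packing offsets
    t_scale,
    c_scale,
    s_scale,
    free_thr,  # bool
    thr_fixed,  # (J, 2) used when not free_thr
    free_sd,  # bool
    sd_fixed,  # (D,) used when not free_sd
    n_corr,  # 0 => identity correlation
):
    R, J = y.shape
    P = X.shape[1]
    D = A0.shape[1]
    N = n_subjects
    nf = free_j.size
    tiny = 1e-12

    la = z[offsets[0] : offsets[1]]
    zb1 = z[offsets[1] : offsets[2]]
    zb2 = z[offsets[2] : offsets[3]]
    zg = z[offsets[3] : offsets[4]]
    zls = z[offsets[4] : offsets[5]]
    zcw = z[offsets[5] : offsets[6]]
    zeps = z[offsets[6] : offsets[7]]

    A = A0.copy()
    a_free = np.empty(nf)
    for m in range(nf):
        a_free[m] = math.tanh(la[m])
        A[free_j[m], free_d[m]] = a_free[m]

    b1 = np.empty(J)
    b2 = np.empty(J)
    gap = np.empty(J)
    if free_thr:
        for j in range(J):
            b1[j] = zb1[j]
            gap[j] = math.exp(zb2[j])
            b2[j] = b1[j] + gap[j]
    else:
        for j in range(J):
            b1[j] = thr_fixed[j, 0]
            b2[j] = thr_fixed[j, 1]

    gamma = np.empty((D, P))
    for d in range(D):
        for p in range(P):
            gamma[d, p] = zg[d * P + p]

    sd = np.empty(D)
    if free_sd:
        for d in range(D):
            sd[d] = math.exp(zls[d])
    else:
        for d in range(D):
            sd[d] = sd_fixed[d]

    zc = np.empty(n_corr)
    L = np.zeros((D, D))
    L[0, 0] = 1.0
    if n_corr > 0:
        for m in range(n_corr):
            zc[m] = math.tanh(zcw[m])
        m = 0
        for i in range(1, D):
            rem = 1.0
            for j in range(i):
                root = math.sqrt(rem if rem > tiny else tiny)
                L[i, j] = zc[m] * root
                rem -= L[i, j] * L[i, j]
                m += 1
            L[i, i] = math.sqrt(rem if rem > tiny else tiny)
    else:
        for d in range(D):
            L[d, d] = 1.0

    eps = np.empty((N, D))
    for i in range(N):
        for d in range(D):
            eps[i, d] = zeps[i * D + d]
    U = np.zeros((N, D))
    for i in range(N):
        for d in range(D):
            acc = 0.0
            for k in range(d + 1):
                acc += L[d, k] * eps[i, k]
            U[i, d] = sd[d] * acc

    lp = 0.0
    grad = np.zeros(z.size)
    g_A = np.zeros((J, D))
    gb1 = np.zeros(J)
    gb2 = np.zeros(J)
    g_gamma = np.zeros((D, P))
    g_U = np.zeros((N, D))
    theta_r = np.empty(D)
    g_theta = np.empty(D)

    for r in range(R):
        i = subj_idx[r]
        for d in range(D):
            acc = U[i, d]
            for p in range(P):
                acc += X[r, p] * gamma[d, p]
            theta_r[d] = acc
            g_theta[d] = 0.0
        for j in range(J):
            yv = y[r, j]
            if yv < 0:
                continue
            eta = 0.0
            for d in range(D):
                eta += A[j, d] * theta_r[d]
            x1 = eta - b1[j]
            x2 = eta - b2[j]
            c1 = _expit(x1)
            c2 = _expit(x2)
            if yv == 0:
                lp -= _softplus(x1)
                ge = -c1
                gb1[j] += c1
            elif yv == 2:
                lp -= _softplus(-x2)
                ge = 1.0 - c2
                gb2[j] -= 1.0 - c2
            else:
                d1 = c1 * (1.0 - c1)
                d2 = c2 * (1.0 - c2)
                diff = c1 - c2
                if diff < tiny:
                    diff = tiny
                lp += math.log(diff)
                ge = (d1 - d2) / diff
                gb1[j] -= d1 / diff
                gb2[j] += d2 / diff
            for d in range(D):
                g_A[j, d] += ge * theta_r[d]
                g_theta[d] += ge * A[j, d]
        for d in range(D):
            g_U[i, d] += g_theta[d]
            gd = g_theta[d]
            for p in range(P):
                g_gamma[d, p] += gd * X[r, p]

    # loadings: uniform prior on (-1, 1) via tanh
    for m in range(nf):
        a = a_free[m]
        lp += math.log1p(-a * a)
        grad[offsets[0] + m] = g_A[free_j[m], free_d[m]] * (1.0 - a * a) - 2.0 * a

    if free_thr:
        t2 = t_scale * t_scale
        for j in range(J):
            lp += -0.5 * (b1[j] * b1[j] + b2[j] * b2[j]) / t2 + zb2[j]
            pb1 = -b1[j] / t2
            pb2 = -b2[j] / t2
            grad[offsets[1] + j] = gb1[j] + gb2[j] + pb1 + pb2
            grad[offsets[2] + j] = (gb2[j] + pb2) * gap[j] + 1.0

    c2s = c_scale * c_scale
    for d in range(D):
        for p in range(P):
            g = gamma[d, p]
            lp += -0.5 * g * g / c2s
            grad[offsets[3] + d * P + p] = g_gamma[d, p] - g / c2s

    # subject effects (non-centred)
    for i in range(N):
        for k in range(D):
            acc = 0.0
            for d in range(k, D):
                acc += g_U[i, d] * sd[d] * L[d, k]
            e = eps[i, k]
            lp += -0.5 * e * e
            grad[offsets[6] + i * D + k] = acc - e

    if free_sd:
        s2 = s_scale * s_scale
        for d in range(D):
            acc = 0.0
            for i in range(N):
                acc += g_U[i, d] * U[i, d]
            lp += -0.5 * sd[d] * sd[d] / s2 + zls[d]
            grad[offsets[4] + d] = acc - sd[d] * sd[d] / s2 + 1.0

    if n_corr > 0:
        # g_L[d, k] = sum_i g_U[i, d] * sd[d] * eps[i, k]
        g_L = np.zeros((D, D))
        for d in range(D):
            for k in range(d + 1):
                acc = 0.0
                for i in range(N):
                    acc += g_U[i, d] * eps[i, k]
                g_L[d, k] = acc * sd[d]
        # forward-mode dL/dz through the partial-correlation recursion
        m0 = 0
        for ti in range(1, D):
            for tj in range(ti):
                rem = 1.0
                drem = 0.0
                gsum = 0.0
                mrow = m0
                for j in range(ti):
                    zm = zc[mrow]
                    root = math.sqrt(rem if rem > tiny else tiny)
                    Lij = zm * root
                    ind = 1.0 if j == tj else 0.0
                    dLij = ind * root + zm * 0.5 * drem / root
                    gsum += g_L[ti, j] * dLij
                    drem -= 2.0 * Lij * dLij
                    rem -= Lij * Lij
                    mrow += 1
                dLii = 0.5 * drem / math.sqrt(rem if rem > tiny else tiny)
                gsum += g_L[ti, ti] * dLii
                k = m0 + tj
                zm = zc[k]
                grad[offsets[5] + k] = gsum * (1.0 - zm * zm) - 2.0 * zm
            m0 += ti
        for m in range(n_corr):
            lp += math.log1p(-zc[m] * zc[m])

    return lp, grad
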