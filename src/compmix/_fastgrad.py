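"""Numba-accelerated joint log-posterior gradient.

Mirrors ``UnconstrainedPosterior._logp_grad_inner`` exactly; the pure-numpy
implementation remains the reference and a unit test asserts agreement on
random states for every variant/family combination.  Import of this module
must never fail the package: if numba is unavailable the caller falls back
to numpy.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    NUMBA_AVAILABLE = True
except Exception:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

_LOG_2PI = math.log(2.0 * math.pi)


@njit(cache=True, fastmath=False)
def _logp_grad_jit(
    q,
    y,
    Z,
    ZT,
    lap,
    L,
    use_iar,
    has_u,
    is_gaussian,
    local_half_t,
    global_half_t,
    sum_var,
    slab_a,
    slab_b,
    slab_const,
    ht3_const,
    global_scale,
    intercept_scale,
    dispersion_scale,
    re_variance_scale,
):
    n = y.shape[0]
    m = Z.shape[1]
    dim = q.shape[0]
    grad = np.zeros(dim)

    b0 = q[0]
    zb = q[1 : 1 + m]
    lt = q[1 + m]
    psi = q[2 + m : 2 + 2 * m]
    lc = q[2 + 2 * m]
    pos = 3 + 2 * m

    tau2 = math.exp(2.0 * lt)
    c2 = math.exp(lc)

    s = np.empty(m)
    r = np.empty(m)
    beta = np.empty(m)
    for j in range(m):
        l2 = math.exp(2.0 * psi[j])
        A = tau2 * l2
        denom = c2 + A
        s[j] = math.sqrt(c2 * A / denom)
        r[j] = c2 / denom
        beta[j] = zb[j] * s[j]

    eta = np.dot(Z, beta)
    for i in range(n):
        eta[i] += b0

    u = np.zeros(0)
    zu = np.zeros(0)
    v = 0.0
    if has_u:
        zu = q[pos : pos + n]
        v = math.exp(q[pos + n])
        sqrt_v = math.sqrt(v)
        u = np.dot(L, zu)
        for i in range(n):
            u[i] *= sqrt_v
            eta[i] += u[i]

    logp = 0.0
    g_eta = np.empty(n)
    if is_gaussian:
        lphi = q[dim - 1]
        phi = math.exp(lphi)
        phi2 = phi * phi
        rss = 0.0
        for i in range(n):
            resid = y[i] - eta[i]
            rss += resid * resid
            g_eta[i] = resid / phi2
        logp += -0.5 * n * _LOG_2PI - n * lphi - 0.5 * rss / phi2
        ps2 = 3.0 * dispersion_scale * dispersion_scale
        logp += (
            ht3_const
            - math.log(dispersion_scale)
            - 2.0 * math.log1p(phi2 / ps2)
            + lphi
        )
        grad[dim - 1] = -n + rss / phi2 - 4.0 * phi2 / (ps2 + phi2) + 1.0
    else:
        for i in range(n):
            e = eta[i]
            if e > 0.0:
                logp += y[i] * e - (e + math.log1p(math.exp(-e)))
                p = 1.0 / (1.0 + math.exp(-e))
            else:
                logp += y[i] * e - math.log1p(math.exp(e))
                ex = math.exp(e)
                p = ex / (1.0 + ex)
            g_eta[i] = y[i] - p

    # soft sum-to-zero on beta*
    S = 0.0
    for j in range(m):
        S += beta[j]
    logp += -0.5 * _LOG_2PI - 0.5 * math.log(sum_var) - 0.5 * S * S / sum_var
    gS = -S / sum_var

    gbeta = np.dot(ZT, g_eta)
    for j in range(m):
        gbeta[j] += gS

    # intercept t(3, 0, scale)
    is2 = 3.0 * intercept_scale * intercept_scale
    logp += (
        ht3_const
        - math.log(2.0)
        - math.log(intercept_scale)
        - 2.0 * math.log1p(b0 * b0 / is2)
    )
    ge_sum = 0.0
    for i in range(n):
        ge_sum += g_eta[i]
    grad[0] = ge_sum - 4.0 * b0 / (is2 + b0 * b0)

    # zb ~ N(0,1); chain rule pieces
    zb2 = 0.0
    dot_gbzs_r = 0.0
    dot_gbzs_1mr = 0.0
    for j in range(m):
        zb2 += zb[j] * zb[j]
        grad[1 + j] = gbeta[j] * s[j] - zb[j]
        gbzs = gbeta[j] * zb[j] * s[j]
        dot_gbzs_r += gbzs * r[j]
        dot_gbzs_1mr += gbzs * (1.0 - r[j])
    logp += -0.5 * m * _LOG_2PI - 0.5 * zb2

    # tau prior (+ Jacobian)
    gs2 = global_scale * global_scale
    if global_half_t:
        logp += (
            ht3_const
            - math.log(global_scale)
            - 2.0 * math.log1p(tau2 / (3.0 * gs2))
            + lt
        )
        gtau = -4.0 * tau2 / (3.0 * gs2 + tau2) + 1.0
    else:
        logp += (
            math.log(2.0 / math.pi)
            - math.log(global_scale)
            - math.log1p(tau2 / gs2)
            + lt
        )
        gtau = -2.0 * tau2 / (gs2 + tau2) + 1.0
    grad[1 + m] = dot_gbzs_r + gtau

    # local scales
    if use_iar:
        lap_psi = np.dot(lap, psi)
        Sp = 0.0
        qlp = 0.0
        for j in range(m):
            Sp += psi[j]
            qlp += psi[j] * lap_psi[j]
        logp += -0.5 * qlp
        logp += -0.5 * _LOG_2PI - 0.5 * math.log(sum_var) - 0.5 * Sp * Sp / sum_var
        for j in range(m):
            grad[2 + m + j] = (
                gbeta[j] * zb[j] * s[j] * r[j] - lap_psi[j] - Sp / sum_var
            )
    else:
        if local_half_t:
            for j in range(m):
                l2 = math.exp(2.0 * psi[j])
                logp += ht3_const - 2.0 * math.log1p(l2 / 3.0) + psi[j]
                grad[2 + m + j] = (
                    gbeta[j] * zb[j] * s[j] * r[j] - 4.0 * l2 / (3.0 + l2) + 1.0
                )
        else:
            for j in range(m):
                l2 = math.exp(2.0 * psi[j])
                logp += math.log(2.0 / math.pi) - math.log1p(l2) + psi[j]
                grad[2 + m + j] = (
                    gbeta[j] * zb[j] * s[j] * r[j] - 2.0 * l2 / (1.0 + l2) + 1.0
                )

    # slab c2 ~ Inv-Gamma (+ Jacobian)
    logp += slab_const - (slab_a + 1.0) * lc - slab_b / c2 + lc
    grad[2 + 2 * m] = 0.5 * dot_gbzs_1mr - slab_a + slab_b / c2

    # random effect
    if has_u:
        sqrt_v = math.sqrt(v)
        Lg = np.dot(L, g_eta)  # L symmetric
        zu2 = 0.0
        g_dot_u = 0.0
        for i in range(n):
            grad[pos + i] = sqrt_v * Lg[i] - zu[i]
            zu2 += zu[i] * zu[i]
            g_dot_u += g_eta[i] * u[i]
        logp += -0.5 * n * _LOG_2PI - 0.5 * zu2
        vs2 = 3.0 * re_variance_scale * re_variance_scale
        logp += (
            ht3_const
            - math.log(re_variance_scale)
            - 2.0 * math.log1p(v * v / vs2)
            + q[pos + n]
        )
        grad[pos + n] = 0.5 * g_dot_u - 4.0 * v * v / (vs2 + v * v) + 1.0

    return logp, grad
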