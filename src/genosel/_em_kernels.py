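"""Numba kernels for the EM coordinate sweeps.

``UT`` is the transposed genotype matrix (N x n, float64, C-contiguous) so each
SNP's column is a contiguous row.  The weighted residual
``r = y - X b - sum_j xi_j g_j u_j`` is maintained incrementally; every update
touches it in O(n).

Two noise scales enter a sweep: ``s2e_ridge`` is the variance in the ridge
denominators of the effect updates (by default the fixed null-model residual
variance) and ``s2e_lam`` the current residual variance used in the
inclusion-weight likelihood ratios.
"""

import numpy as np
from numba import njit

_LAM_CLAMP = 700.0  # exp() overflow guard for the inclusion-odds exponent


@njit(cache=True)
def _dot(u, r):
    s = 0.0
    for i in range(u.shape[0]):
        s += u[i] * r[i]
    return s


@njit(cache=True)
def _axpy(alpha, u, r):
    for i in range(u.shape[0]):
        r[i] += alpha * u[i]


@njit(cache=True)
def em_sweep(UT, u2, r, g, xi, sigma2_g, s2e_ridge, s2e_lam, nu, s, p,
             weighted, precision_form):
    """One E+M sweep over all SNPs (variances, weights, then effects).

    Updates ``r``, ``g``, ``xi`` and ``sigma2_g`` in place and returns the
    accumulated squared change of the SNP effects.  The fixed effects and the
    residual variance are updated by the caller.

    ``precision_form=False`` replaces each effect variance by its conditional
    posterior expectation ``(nu*s + g^2)/(nu - 1)``; ``True`` uses the
    reciprocal of the conditional expectation of the precision,
    ``(nu*s + g^2)/(nu + 1)``.
    """
    N = UT.shape[0]
    denom_df = (nu + 1.0) if precision_form else (nu - 1.0)
    for l in range(N):
        sigma2_g[l] = (nu * s + g[l] * g[l]) / denom_df

    if weighted:
        for l in range(N):
            if u2[l] == 0.0:
                continue
            a = _dot(UT[l], r) + xi[l] * g[l] * u2[l]
            lam = (2.0 * g[l] * a - g[l] * g[l] * u2[l]) / (2.0 * s2e_lam)
            if lam > _LAM_CLAMP:
                lam = _LAM_CLAMP
            elif lam < -_LAM_CLAMP:
                lam = -_LAM_CLAMP
            xin = p / (p + (1.0 - p) * np.exp(-lam))
            if xin != xi[l]:
                _axpy((xi[l] - xin) * g[l], UT[l], r)
                xi[l] = xin

    delta2 = 0.0
    for l in range(N):
        if u2[l] == 0.0:
            continue
        a = _dot(UT[l], r) + xi[l] * g[l] * u2[l]
        gn = a / (u2[l] + s2e_ridge / sigma2_g[l])
        d = gn - g[l]
        delta2 += d * d
        if d != 0.0:
            _axpy(xi[l] * (-d), UT[l], r)
            g[l] = gn
    return delta2
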