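"""Numba kernels: one MCMC cycle of the Gibbs (BayesA) and SSVS (BayesB) samplers.

All random variates are drawn outside with a seeded numpy Generator and passed
in, so a chain is a deterministic function of its seed.  The residual
``r = y - X b - U g`` is maintained incrementally; correctness against a
from-scratch recomputation is asserted in the test suite.
"""

import numpy as np
from numba import njit


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
def gibbs_cycle(UT, u2, r, g, sigma2_g, sigma2_e, nu_s, z, chi):
    """One Gibbs cycle over all SNPs: draw g_l then its variance.

    ``g_l | rest ~ N(u'r_l / (u'u + s2e/s2g), s2e / (u'u + s2e/s2g))`` with
    ``r_l`` the partial residual excluding SNP l, and
    ``sigma_gl^2 | g_l ~ (nu S + g_l^2) / chi2_{nu+1}``.
    ``z`` are standard normals, ``chi`` chi-square(nu+1) draws.
    """
    N = UT.shape[0]
    for l in range(N):
        a = _dot(UT[l], r) + g[l] * u2[l]
        denom = u2[l] + sigma2_e / sigma2_g[l]
        mean = a / denom
        gn = mean + np.sqrt(sigma2_e / denom) * z[l]
        _axpy(g[l] - gn, UT[l], r)
        g[l] = gn
        sigma2_g[l] = (nu_s + gn * gn) / chi[l]


@njit(cache=True)
def _log_marginal(s2, a, q, sigma2_e):
    """Log marginal likelihood of the partial residual with g integrated out,
    relative to the exclusion model (s2 = 0)."""
    if s2 == 0.0:
        return 0.0
    t = s2 * q / sigma2_e
    return -0.5 * np.log1p(t) + 0.5 * s2 * a * a / (sigma2_e * (sigma2_e + s2 * q))


@njit(cache=True)
def ssvs_cycle(UT, u2, r, g, sigma2_g, sigma2_e, nu_s, p,
               u_incl, chi_prop, u_acc, z):
    """One SSVS cycle: per SNP, a block of Metropolis-Hastings proposals on
    (sigma_gl^2, gamma_l) drawn from the prior, accepted by the marginal
    likelihood ratio with g_l integrated out; then g_l is refreshed from its
    conditional (0 when excluded).

    ``u_incl, chi_prop, u_acc`` have shape (N, T) for T proposals per locus;
    ``chi_prop`` holds chi-square(nu) draws.  Returns the number of accepted
    proposals.
    """
    N, T = u_incl.shape
    accepted = 0
    for l in range(N):
        a = _dot(UT[l], r) + g[l] * u2[l]
        q = u2[l]
        cur = sigma2_g[l]
        cur_ml = _log_marginal(cur, a, q, sigma2_e)
        for t in range(T):
            prop = nu_s / chi_prop[l, t] if u_incl[l, t] < p else 0.0
            prop_ml = _log_marginal(prop, a, q, sigma2_e)
            if np.log(u_acc[l, t]) < prop_ml - cur_ml:
                cur = prop
                cur_ml = prop_ml
                accepted += 1
        sigma2_g[l] = cur
        if cur > 0.0:
            denom = q + sigma2_e / cur
            gn = a / denom + np.sqrt(sigma2_e / denom) * z[l]
        else:
            gn = 0.0
        _axpy(g[l] - gn, UT[l], r)
        g[l] = gn
    return accepted
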