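"""MCMC samplers for Bayesian shrinkage regression (BayesA) and SSVS (BayesB).

Both samplers share the linear model and priors of :mod:`genosel.em` and
return posterior *means* of the SNP effects (the EM methods return posterior
modes).  The BayesA sampler draws every effect and its variance from closed
conditionals; the BayesB sampler updates each SNP's (variance, inclusion) pair
with a block of Metropolis-Hastings proposals from the prior, accepting on the
marginal likelihood with the effect integrated out analytically, which keeps
excluded effects at exactly zero.

Chain defaults mirror the benchmark protocol: 11000 cycles, 1000 burn-in,
thinning 10, so 1000 samples are retained.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._mcmc_kernels import gibbs_cycle, ssvs_cycle

__all__ = ["GibbsBSRRegressor", "SSVSRegressor", "sample_g_conditional"]


def sample_g_conditional(u, r_partial, sigma2_e: float, sigma2_g: float,
                         rng: np.random.Generator) -> float:
    """Draw one SNP effect from its full conditional normal.

    Mean ``u'r / (u'u + s2e/s2g)`` and variance ``s2e / (u'u + s2e/s2g)``,
    where ``r`` is the partial residual excluding this SNP.
    """
    u = np.asarray(u, dtype=float)
    denom = float(u @ u) + sigma2_e / sigma2_g
    mean = float(u @ np.asarray(r_partial, dtype=float)) / denom
    return rng.normal(mean, np.sqrt(sigma2_e / denom))


class _McmcBase(BaseEstimator):
    def _validate(self, X, y, covariates):
        U = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if U.ndim != 2 or y.shape != (U.shape[0],):
            raise ValueError("X must be (n, N) and y length n")
        if not np.isin(U, (-1.0, 0.0, 1.0)).all():
            raise ValueError("genotype codes must be signed (-1/0/+1)")
        u2 = (U * U).sum(axis=0)
        mono = np.flatnonzero(u2 == 0)
        if mono.size:
            raise ValueError(
                f"{mono.size} monomorphic SNP columns (e.g. indices {mono[:5].tolist()}); "
                "filter them out first"
            )
        if self.burn_in >= self.total_cycles:
            raise ValueError("burn_in must be smaller than total_cycles")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        n = U.shape[0]
        if covariates is None:
            Xf = np.ones((n, 1))
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            Xf = np.column_stack([np.ones(n), cov])
        if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        return U, y, Xf, u2

    def _draw_b(self, Xf, y_work, sigma2_e, rng, XtX_inv_chol, XtX_inv):
        bhat = XtX_inv @ (Xf.T @ y_work)
        return bhat + np.sqrt(sigma2_e) * (XtX_inv_chol @ rng.standard_normal(Xf.shape[1]))

    def predict(self, X) -> np.ndarray:
        """Predict genomic breeding values from posterior-mean effects."""
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted")
        U = np.asarray(X, dtype=float)
        if U.ndim != 2 or U.shape[1] != self.n_features_in_:
            raise ValueError("X SNP count does not match the fitted model")
        return U @ self.coef_


class GibbsBSRRegressor(_McmcBase):
    """BayesA: Gibbs sampler for Bayesian shrinkage regression.

    Every SNP effect carries its own variance with a scaled inverse chi-square
    prior ``chi^-2(nu, S)``; ``b`` and ``sigma_e^2`` have flat priors.  The
    point estimate ``coef_`` is the posterior mean of ``g`` over the retained
    (post burn-in, thinned) samples.
    """

    def __init__(self, nu: float = 4.012, s: float = 0.002,
                 total_cycles: int = 11000, burn_in: int = 1000, thinning: int = 10,
                 store_samples: bool = True, random_state=None):
        self.nu = nu
        self.s = s
        self.total_cycles = total_cycles
        self.burn_in = burn_in
        self.thinning = thinning
        self.store_samples = store_samples
        self.random_state = random_state

    def fit(self, X, y, covariates=None):
        U, y, Xf, u2 = self._validate(X, y, covariates)
        n, N = U.shape
        UT = np.ascontiguousarray(U.T)
        rng = np.random.default_rng(self.random_state)

        XtX = Xf.T @ Xf
        XtX_inv = np.linalg.inv(XtX)
        XtX_inv_chol = np.linalg.cholesky(XtX_inv)

        b = XtX_inv @ (Xf.T @ y)
        r = y - Xf @ b
        sigma2_e = max(float(r @ r) / n, 1e-12)
        g = np.zeros(N)
        sigma2_g = np.full(N, self.nu * self.s / (self.nu + 2.0) if self.s > 0 else 0.01)
        nu_s = self.nu * self.s

        n_keep = (self.total_cycles - self.burn_in) // self.thinning
        g_sum = np.zeros(N)
        kept = 0
        b_samples = np.empty((n_keep, Xf.shape[1]))
        s2e_samples = np.empty(n_keep)
        g_samples = np.empty((n_keep, N)) if self.store_samples else None

        for cycle in range(1, self.total_cycles + 1):
            z = rng.standard_normal(N)
            chi = rng.chisquare(self.nu + 1.0, N)
            gibbs_cycle(UT, u2, r, g, sigma2_g, sigma2_e, nu_s, z, chi)
            y_work = r + Xf @ b
            b_new = self._draw_b(Xf, y_work, sigma2_e, rng, XtX_inv_chol, XtX_inv)
            r = y_work - Xf @ b_new
            b = b_new
            rss = float(r @ r)
            sigma2_e = rss / rng.chisquare(n - 2.0)
            if cycle > self.burn_in and (cycle - self.burn_in) % self.thinning == 0:
                g_sum += g
                b_samples[kept] = b
                s2e_samples[kept] = sigma2_e
                if g_samples is not None:
                    g_samples[kept] = g
                kept += 1

        self.n_features_in_ = N
        self.n_retained_ = kept
        self.coef_ = g_sum / kept
        self.effects_ = self.coef_
        self.fixed_effects_ = b_samples[:kept].mean(axis=0)
        self.sigma2_e_ = float(s2e_samples[:kept].mean())
        self.b_samples_ = b_samples[:kept]
        self.sigma2_e_samples_ = s2e_samples[:kept]
        self.g_samples_ = g_samples[:kept] if g_samples is not None else None
        return self


class SSVSRegressor(_McmcBase):
    """BayesB: stochastic search variable selection by Metropolis-within-Gibbs.

    Each SNP's effect variance has the mixture prior
    ``(1 - p) delta_0 + p chi^-2(nu, S)``; the (variance, inclusion) pair is
    updated jointly with ``mh_proposals_per_locus`` independence proposals from
    the prior, accepted by the marginal likelihood ratio with the effect
    integrated out.  ``coef_`` is the posterior mean of ``gamma_l g_l``;
    ``inclusion_frequencies_`` the retained-sample frequency of inclusion.
    """

    def __init__(self, p: float = 0.5, nu: float = 4.234, s: float = 0.0429,
                 total_cycles: int = 11000, burn_in: int = 1000, thinning: int = 10,
                 mh_proposals_per_locus: int = 10,
                 store_samples: bool = True, random_state=None):
        self.p = p
        self.nu = nu
        self.s = s
        self.total_cycles = total_cycles
        self.burn_in = burn_in
        self.thinning = thinning
        self.mh_proposals_per_locus = mh_proposals_per_locus
        self.store_samples = store_samples
        self.random_state = random_state

    def fit(self, X, y, covariates=None):
        if not (0 < self.p < 1):
            raise ValueError(
                f"p must be in (0, 1) for SSVS, got {self.p}; use GibbsBSRRegressor for p = 1"
            )
        U, y, Xf, u2 = self._validate(X, y, covariates)
        n, N = U.shape
        UT = np.ascontiguousarray(U.T)
        T = self.mh_proposals_per_locus
        rng = np.random.default_rng(self.random_state)

        XtX = Xf.T @ Xf
        XtX_inv = np.linalg.inv(XtX)
        XtX_inv_chol = np.linalg.cholesky(XtX_inv)

        b = XtX_inv @ (Xf.T @ y)
        r = y - Xf @ b
        sigma2_e = max(float(r @ r) / n, 1e-12)
        g = np.zeros(N)
        sigma2_g = np.zeros(N)  # all SNPs start excluded
        nu_s = self.nu * self.s

        n_keep = (self.total_cycles - self.burn_in) // self.thinning
        g_sum = np.zeros(N)
        incl_sum = np.zeros(N)
        kept = 0
        accepted = 0
        b_samples = np.empty((n_keep, Xf.shape[1]))
        s2e_samples = np.empty(n_keep)
        g_samples = np.empty((n_keep, N)) if self.store_samples else None

        for cycle in range(1, self.total_cycles + 1):
            u_incl = rng.random((N, T))
            chi_prop = rng.chisquare(self.nu, (N, T))
            u_acc = rng.random((N, T))
            z = rng.standard_normal(N)
            accepted += ssvs_cycle(UT, u2, r, g, sigma2_g, sigma2_e, nu_s,
                                   float(self.p), u_incl, chi_prop, u_acc, z)
            y_work = r + Xf @ b
            b_new = self._draw_b(Xf, y_work, sigma2_e, rng, XtX_inv_chol, XtX_inv)
            r = y_work - Xf @ b_new
            b = b_new
            rss = float(r @ r)
            sigma2_e = rss / rng.chisquare(n - 2.0)
            if cycle > self.burn_in and (cycle - self.burn_in) % self.thinning == 0:
                g_sum += g
                incl_sum += sigma2_g > 0
                b_samples[kept] = b
                s2e_samples[kept] = sigma2_e
                if g_samples is not None:
                    g_samples[kept] = g
                kept += 1

        self.n_features_in_ = N
        self.n_retained_ = kept
        self.coef_ = g_sum / kept
        self.effects_ = self.coef_
        self.inclusion_frequencies_ = incl_sum / kept
        self.acceptance_rate_ = accepted / (self.total_cycles * N * T)
        self.fixed_effects_ = b_samples[:kept].mean(axis=0)
        self.sigma2_e_ = float(s2e_samples[:kept].mean())
        self.b_samples_ = b_samples[:kept]
        self.sigma2_e_samples_ = s2e_samples[:kept]
        self.g_samples_ = g_samples[:kept] if g_samples is not None else None
        return self
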