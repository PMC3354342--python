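"""Comparison estimators: GBLUP (SNP-BLUP / ridge) and a BayesB-style
Gibbs sampler.

GBLUP assumes one common normal prior variance ``Vg / M`` for all marker
effects.  The direct solver solves the mixed-model equations jointly for the
mean and all effects; the iterative solver is per-SNP Gauss-Seidel with the
same relative squared-change stopping rule as MixP.

BayesB here follows the "small effects are small, not zero" variant: with
probability ``pi`` a SNP effect comes from a big-variance normal and
otherwise from a small-variance normal.  Component indicators are sampled
from the integrated (effect-marginalized) likelihood ratio, effects from
their Gaussian full conditionals, and variances from conjugate scaled
inverse-chi-squared full conditionals with 4.2 prior degrees of freedom;
big-component variances are locus-specific, the small-component variance is
shared.  The inverse-chi-squared scales are anchored so the prior means equal
the Pareto-principle component variances.  The chain length defaults to
10000 iterations with 3000 burn-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .data_model import GenotypeMatrix, PhenotypeVector

logger = logging.getLogger(__name__)

__all__ = ["GBLUPResult", "BayesBResult", "fit_gblup", "fit_bayesb", "GBLUP", "BayesB"]


# ---------------------------------------------------------------------------
# GBLUP


@dataclass
class GBLUPResult:
    g_hat: np.ndarray
    mu: float
    solver: str
    iterations: int | None = None
    converged: bool = True


def _gblup_direct(B: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Joint dense solve of [[n, 1'B], [B'1, B'B + lam I]] [mu; g] = [1'y; B'y]."""
    n, M = B.shape
    A = np.empty((M + 1, M + 1))
    A[0, 0] = n
    colsum = B.sum(axis=0)
    A[0, 1:] = colsum
    A[1:, 0] = colsum
    A[1:, 1:] = B.T @ B + lam * np.eye(M)
    rhs = np.concatenate(([y.sum()], B.T @ y))
    sol = np.linalg.solve(A, rhs)
    return sol[1:], float(sol[0])


def _gblup_gauss_seidel(
    B: np.ndarray, y: np.ndarray, lam: float, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int, bool]:
    n, M = B.shape
    cols = [np.ascontiguousarray(B[:, i]) for i in range(M)]
    bb = np.array([float(c @ c) for c in cols])
    g = np.zeros(M)
    mu = float(np.mean(y))
    r = y - mu
    converged = False
    sweep = 0
    for sweep in range(1, max_iter + 1):
        shift = float(np.mean(r))
        mu += shift
        r -= shift
        change_sq = 0.0
        for i in range(M):
            if bb[i] == 0.0:
                continue
            g_new = float(cols[i] @ r + bb[i] * g[i]) / (bb[i] + lam)
            r -= cols[i] * (g_new - g[i])
            change_sq += (g_new - g[i]) ** 2
            g[i] = g_new
        sol_sq = float(g @ g)
        if sweep % 25 == 0:
            r = y - mu - B @ g
        if sol_sq > 0.0 and change_sq < tol * sol_sq:
            converged = True
            break
    return g, mu, sweep, converged


def fit_gblup(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotypes: PhenotypeVector | np.ndarray,
    genetic_variance: float,
    resid_var: float,
    solver: str = "auto",
    tol: float = 1e-7,
    max_iter: int = 5000,
) -> GBLUPResult:
    """Fit SNP-BLUP with per-SNP prior variance ``Vg / M``.

    ``solver='auto'`` uses the dense direct solve for M <= 5000 and
    Gauss-Seidel above that.
    """
    B = genotypes.standardized if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    y = phenotypes.values if isinstance(phenotypes, PhenotypeVector) else np.asarray(phenotypes, float)
    if not np.all(np.isfinite(B)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in input")
    if genetic_variance <= 0 or resid_var <= 0:
        raise ValueError("variances must be positive")
    n, M = B.shape
    lam = resid_var * M / genetic_variance
    if solver == "auto":
        solver = "direct" if M <= 5000 else "iterative"
    if solver == "direct":
        g, mu = _gblup_direct(B, y, lam)
        return GBLUPResult(g, mu, "direct")
    if solver == "iterative":
        g, mu, sweeps, converged = _gblup_gauss_seidel(B, y, lam, tol, max_iter)
        return GBLUPResult(g, mu, "iterative", iterations=sweeps, converged=converged)
    raise ValueError(f"unknown solver {solver!r}")


class GBLUP(RegressorMixin, BaseEstimator):
    """Genome-wide BLUP (ridge regression on standardized genotypes).

    Attributes after :meth:`fit`: ``coef_``, ``intercept_``, ``solver_``,
    ``n_iter_`` (iterative solver only).
    """

    def __init__(
        self,
        genetic_variance: float = 1.0,
        resid_var: float = 1.0,
        solver: str = "auto",
        tol: float = 1e-7,
        max_iter: int = 5000,
    ):
        self.genetic_variance = genetic_variance
        self.resid_var = resid_var
        self.solver = solver
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        res = fit_gblup(X, y, self.genetic_variance, self.resid_var,
                        solver=self.solver, tol=self.tol, max_iter=self.max_iter)
        self.n_features_in_ = X.shape[1]
        self.coef_ = res.g_hat
        self.intercept_ = res.mu
        self.solver_ = res.solver
        self.n_iter_ = res.iterations
        self.converged_ = res.converged
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def breeding_values(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_


# ---------------------------------------------------------------------------
# BayesB


@njit(cache=False)
def _bayesb_kernel(
    B, y, pi, df, s1_scale, s2_scale, resid_var,
    n_iter, n_burnin, thin, sample_variances, seed,
):  # pragma: no cover - exercised through fit_bayesb
    np.random.seed(seed)
    n, M = B.shape
    bb = np.empty(M)
    for i in range(M):
        s = 0.0
        for j in range(n):
            s += B[j, i] * B[j, i]
        bb[i] = s
    g = np.zeros(M)
    delta = np.zeros(M, np.int64)  # 1 = big component
    s1 = np.empty(M)
    for i in range(M):  # start locus variances at their prior draws
        if sample_variances:
            s1[i] = df * s1_scale / (2.0 * np.random.standard_gamma(df / 2.0))
        else:
            s1[i] = df * s1_scale / (df - 2.0)
    if sample_variances:
        s2 = df * s2_scale / (2.0 * np.random.standard_gamma(df / 2.0))
    else:
        s2 = df * s2_scale / (df - 2.0)
    mu = y.mean()
    r = y - mu
    n_keep = n_iter - n_burnin
    g_sum = np.zeros(M)
    p_sum = np.zeros(M)
    mu_sum = 0.0
    n_thin = n_iter // thin
    thin_iter = np.empty(n_thin, np.int64)
    thin_mu = np.empty(n_thin)
    thin_gsq = np.empty(n_thin)
    thin_nbig = np.empty(n_thin, np.int64)
    thin_s2 = np.empty(n_thin)
    n_sample_rows = n_keep // thin
    g_samples = np.empty((n_sample_rows, M))
    row = 0
    t = 0
    log_odds0 = np.log(1.0 - pi) - np.log(pi)
    for it in range(n_iter):
        # overall mean
        mean_now = mu + r.mean()
        mu_new = mean_now + np.random.normal() * np.sqrt(resid_var / n)
        for j in range(n):
            r[j] += mu - mu_new
        mu = mu_new
        # marker effects and indicators
        for i in range(M):
            if bb[i] == 0.0:
                g[i] = 0.0
                continue
            by = 0.0
            for j in range(n):
                by += B[j, i] * r[j]
            by += bb[i] * g[i]
            d1 = bb[i] + resid_var / s1[i]
            d2 = bb[i] + resid_var / s2
            g1 = by / d1
            g2 = by / d2
            ll1 = -0.5 * np.log1p(bb[i] * s1[i] / resid_var) + 0.5 * by * g1 / resid_var
            ll2 = -0.5 * np.log1p(bb[i] * s2 / resid_var) + 0.5 * by * g2 / resid_var
            z = log_odds0 + ll2 - ll1
            if z > 700.0:
                z = 700.0
            elif z < -700.0:
                z = -700.0
            p1 = 1.0 / (1.0 + np.exp(z))
            if np.random.random() < p1:
                delta[i] = 1
                denom = d1
                g_mean = g1
            else:
                delta[i] = 0
                denom = d2
                g_mean = g2
            g_new = g_mean + np.random.normal() * np.sqrt(resid_var / denom)
            diff = g_new - g[i]
            for j in range(n):
                r[j] -= B[j, i] * diff
            g[i] = g_new
            if it >= n_burnin:
                p_sum[i] += p1
        # component variances
        if sample_variances:
            ssq_small = 0.0
            k_small = 0
            for i in range(M):
                if delta[i] == 1:
                    chi = 2.0 * np.random.standard_gamma((df + 1.0) / 2.0)
                    s1[i] = (df * s1_scale + g[i] * g[i]) / chi
                else:
                    chi = 2.0 * np.random.standard_gamma(df / 2.0)
                    s1[i] = df * s1_scale / chi
                    ssq_small += g[i] * g[i]
                    k_small += 1
            chi = 2.0 * np.random.standard_gamma((df + k_small) / 2.0)
            s2 = (df * s2_scale + ssq_small) / chi
        if it >= n_burnin:
            g_sum += g
            mu_sum += mu
            if (it - n_burnin) % thin == 0 and row < n_sample_rows:
                g_samples[row] = g
                row += 1
        if it % thin == 0 and t < n_thin:
            thin_iter[t] = it
            thin_mu[t] = mu
            gsq = 0.0
            nbig = 0
            for i in range(M):
                gsq += g[i] * g[i]
                nbig += delta[i]
            thin_gsq[t] = gsq
            thin_nbig[t] = nbig
            thin_s2[t] = s2
            t += 1
    g_hat = g_sum / n_keep
    prob_big = p_sum / n_keep
    mu_hat = mu_sum / n_keep
    return (g_hat, prob_big, mu_hat, g_samples[:row],
            thin_iter[:t], thin_mu[:t], thin_gsq[:t], thin_nbig[:t], thin_s2[:t])


@dataclass
class BayesBResult:
    g_hat: np.ndarray
    prob_big: np.ndarray
    mu: float
    n_iter: int
    n_burnin: int
    chain_seed: int
    effect_samples: np.ndarray  # thinned post-burn-in draws, (n_samples, M)
    chain_summary: pd.DataFrame  # thinned (iteration, mu, sum_g_sq, n_big)


def fit_bayesb(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotypes: PhenotypeVector | np.ndarray,
    pi: float,
    genetic_variance: float,
    resid_var: float,
    n_iter: int = 10000,
    n_burnin: int = 3000,
    df: float = 4.2,
    seed: int | None = None,
    thin: int = 10,
    sample_variances: bool = True,
    sigma1_sq: float | None = None,
    sigma2_sq: float | None = None,
) -> BayesBResult:
    """Gibbs sampling of the two-component mixture model.

    The scaled inverse-chi-squared scales are set so the prior mean of the
    big (small) component variance equals the Pareto value sigma1^2
    (sigma2^2) for the given ``pi`` and ``genetic_variance``; pass
    ``sigma1_sq`` / ``sigma2_sq`` to anchor them elsewhere.  The residual
    variance is held fixed at its known value.  ``sample_variances=False``
    freezes both component variances at those prior means (useful to compare
    against a fully Gaussian model).
    """
    if seed is None:
        raise ValueError("a seed is required for BayesB (stored in the result)")
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi must lie in (0, 1), got {pi}")
    if n_burnin >= n_iter:
        raise ValueError("n_burnin must be smaller than n_iter")
    if df <= 2.0:
        raise ValueError("df must exceed 2 for the prior mean to exist")
    B = genotypes.standardized if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    y = phenotypes.values if isinstance(phenotypes, PhenotypeVector) else np.asarray(phenotypes, float)
    M = B.shape[1]
    # anchor prior means to the Pareto component variances unless overridden;
    # M (pi s1 + (1-pi) s2) = Vg holds for any pi in (0, 1)
    if sigma1_sq is None:
        sigma1_sq = (1.0 - pi) * genetic_variance / (pi * M)
    if sigma2_sq is None:
        sigma2_sq = pi * genetic_variance / ((1.0 - pi) * M)
    factor = (df - 2.0) / df
    out = _bayesb_kernel(
        np.ascontiguousarray(B, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        float(pi), float(df),
        float(sigma1_sq * factor), float(sigma2_sq * factor),
        float(resid_var), int(n_iter), int(n_burnin), int(thin),
        bool(sample_variances), int(seed) % (2**32),
    )
    g_hat, prob_big, mu_hat, g_samples, t_it, t_mu, t_gsq, t_nbig, t_s2 = out
    summary = pd.DataFrame({
        "iteration": t_it, "mu": t_mu, "sum_g_sq": t_gsq, "n_big": t_nbig,
        "small_variance": t_s2,
    })
    return BayesBResult(g_hat, prob_big, mu_hat, n_iter, n_burnin, int(seed),
                        g_samples, summary)


class BayesB(RegressorMixin, BaseEstimator):
    """BayesB-style Gibbs sampler (small effects drawn from a small-variance
    normal rather than fixed at zero).

    ``random_state`` must be set explicitly; it is stored with the result so
    chains are reproducible.
    """

    def __init__(
        self,
        pi: float = 0.1,
        genetic_variance: float = 1.0,
        resid_var: float = 1.0,
        n_iter: int = 10000,
        n_burnin: int = 3000,
        df: float = 4.2,
        thin: int = 10,
        sample_variances: bool = True,
        random_state: int | None = None,
    ):
        self.pi = pi
        self.genetic_variance = genetic_variance
        self.resid_var = resid_var
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.df = df
        self.thin = thin
        self.sample_variances = sample_variances
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        res = fit_bayesb(
            X, y, self.pi, self.genetic_variance, self.resid_var,
            n_iter=self.n_iter, n_burnin=self.n_burnin, df=self.df,
            seed=self.random_state, thin=self.thin,
            sample_variances=self.sample_variances,
        )
        self.n_features_in_ = X.shape[1]
        self.coef_ = res.g_hat
        self.intercept_ = res.mu
        self.prob_big_ = res.prob_big
        self.effect_samples_ = res.effect_samples
        self.chain_summary_ = res.chain_summary
        self.result_ = res
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def breeding_values(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_
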