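"""MixP: mixture-of-normals marker-effect estimation by iterative
conditional expectation (ICE).

Model
-----
Records follow the SNP-regression model

    y = 1 mu + sum_i b_i g_i + e,        Var(e) = I sigma_e^2

with ``b_i`` the standardized genotype column of SNP ``i``.  The prior on each
SNP effect is a mixture of two zero-mean normals,

    p(g_i) = pi N(0, sigma1^2) + (1 - pi) N(0, sigma2^2),

whose variances are fixed by the Pareto principle: the fraction ``pi`` of
markers with the biggest effects is assumed to explain the fraction
``1 - pi`` of the total genetic variance Vg, giving

    sigma1^2 = (1 - pi) Vg / (pi M),     sigma2^2 = pi Vg / ((1 - pi) M)

so that M (pi sigma1^2 + (1 - pi) sigma2^2) = Vg.  With pi = 0.5 both
variances collapse to Vg / M and the method reduces to GBLUP / ridge
regression.

The ICE solver visits every SNP in turn and replaces its effect by its exact
posterior mean given the current estimates of all other effects: a weighted
average of the two single-variance BLUP estimates, weighted by the posterior
probability that the SNP belongs to the big-variance component.  The
component marginal likelihoods need |V| and y'V^-1 y for
V = b b' sigma^2 + I sigma_e^2, which rank-one (Sherman-Morrison) identities
reduce to scalar work:

    |V|        = (sigma_e^2)^n (b'b sigma^2 / sigma_e^2 + 1)
    g_blup     = b'y / (b'b + sigma_e^2 / sigma^2)
    y'V^-1 y   = (y'y - y'b g_blup) / sigma_e^2

Iteration stops when the sum of squared changes of the effect estimates drops
below ``tol`` times the sum of squared estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .data_model import GenotypeMatrix, PhenotypeVector

logger = logging.getLogger(__name__)

__all__ = [
    "MixturePrior",
    "ICEState",
    "SNPUpdateResult",
    "pareto_prior",
    "scalar_loglik",
    "ice_update_snp",
    "fit_mixp",
    "predict",
    "MixP",
]

_EXP_CLAMP = 700.0  # exp() overflow guard for the log likelihood-ratio


@dataclass(frozen=True)
class MixturePrior:
    """Two-component normal mixture prior with Pareto-principle variances."""

    pi: float
    genetic_variance: float
    n_markers: int
    sigma1_sq: float
    sigma2_sq: float


def pareto_prior(pi: float, genetic_variance: float, n_markers: int) -> MixturePrior:
    """Build the mixture prior from (pi, Vg, M).

    ``pi`` is the proportion of markers in the big-variance component and must
    lie in (0, 0.5]: values above 0.5 would make the "big" component the
    smaller one and invert the Pareto semantics.
    """
    if not 0.0 < pi <= 0.5:
        raise ValueError(f"pi must lie in (0, 0.5], got {pi}")
    if genetic_variance <= 0.0:
        raise ValueError("genetic_variance must be positive")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    sigma1_sq = (1.0 - pi) * genetic_variance / (pi * n_markers)
    sigma2_sq = pi * genetic_variance / ((1.0 - pi) * n_markers)
    return MixturePrior(pi, genetic_variance, n_markers, sigma1_sq, sigma2_sq)


def scalar_loglik(
    y_tilde: np.ndarray, b: np.ndarray, sigma_sq: float, resid_var: float
) -> tuple[float, float]:
    """Marginal log-likelihood of a single-SNP model and the BLUP estimate.

    Evaluates, up to a constant shared by any two prior variances,
    ``log N(y_tilde | 0, b b' sigma_sq + I resid_var)`` together with the BLUP
    solution ``g = b'y / (b'b + resid_var / sigma_sq)`` using the scalar
    determinant and quadratic-form identities (no n x n matrix is formed).

    ``sigma_sq = 0`` is handled as its continuous limit: ``g = 0`` and the
    plain Gaussian log density under ``I resid_var``.
    """
    if resid_var <= 0.0:
        raise ValueError("resid_var must be positive")
    if sigma_sq < 0.0:
        raise ValueError("sigma_sq must be non-negative")
    y_tilde = np.asarray(y_tilde, dtype=float)
    b = np.asarray(b, dtype=float)
    n = y_tilde.shape[0]
    yy = float(y_tilde @ y_tilde)
    bb = float(b @ b)
    base = -0.5 * n * np.log(resid_var)
    if sigma_sq == 0.0 or bb == 0.0:
        return base - 0.5 * yy / resid_var, 0.0
    by = float(b @ y_tilde)
    g = by / (bb + resid_var / sigma_sq)
    loglik = base - 0.5 * np.log1p(bb * sigma_sq / resid_var) \
        - 0.5 * (yy - by * g) / resid_var
    return loglik, g


@dataclass
class ICEState:
    """Mutable solver state: effect estimates, mean, residual, bookkeeping."""

    g_hat: np.ndarray
    mu: float
    residual: np.ndarray
    prob_big: np.ndarray
    iteration: int = 0
    converged: bool = False
    change_sq_sum: float = 0.0
    solution_sq_sum: float = 0.0

    @classmethod
    def initial(cls, y: np.ndarray, n_markers: int) -> "ICEState":
        mu = float(np.mean(y))
        return cls(
            g_hat=np.zeros(n_markers),
            mu=mu,
            residual=np.asarray(y, dtype=float) - mu,
            prob_big=np.zeros(n_markers),
        )


@dataclass(frozen=True)
class SNPUpdateResult:
    """One conditional-expectation update of a single SNP."""

    g_hat_big: float
    g_hat_small: float
    loglik_big: float
    loglik_small: float
    posterior_big: float
    g_hat: float


def ice_update_snp(
    state: ICEState,
    b_i: np.ndarray,
    prior: MixturePrior,
    resid_var: float,
    snp_index: int,
) -> SNPUpdateResult:
    """Replace SNP ``snp_index``'s effect by its conditional posterior mean.

    Forms the corrected records ``y_tilde = residual + b_i g_i(old)`` (records
    adjusted for the mean and all *other* SNP effects), computes both
    single-component BLUP estimates and marginal likelihoods through
    :func:`scalar_loglik`, weights them by the posterior component
    probability, and updates the state (effects, residual, probabilities,
    squared-change accumulator) in place.
    """
    g_old = float(state.g_hat[snp_index])
    y_tilde = state.residual + b_i * g_old
    ll1, g1 = scalar_loglik(y_tilde, b_i, prior.sigma1_sq, resid_var)
    ll2, g2 = scalar_loglik(y_tilde, b_i, prior.sigma2_sq, resid_var)
    # posterior of the big component, in log space with an overflow clamp
    z = np.clip(np.log1p(-prior.pi) - np.log(prior.pi) + ll2 - ll1,
                -_EXP_CLAMP, _EXP_CLAMP)
    p1 = 1.0 / (1.0 + np.exp(z))
    g_new = p1 * g1 + (1.0 - p1) * g2
    if not np.isfinite(g_new):
        raise FloatingPointError(
            f"non-finite effect update at SNP index {snp_index}; "
            "check input scaling"
        )
    state.residual -= b_i * (g_new - g_old)
    state.g_hat[snp_index] = g_new
    state.prob_big[snp_index] = p1
    state.change_sq_sum += (g_new - g_old) ** 2
    return SNPUpdateResult(g1, g2, ll1, ll2, p1, g_new)


class ConvergenceWarning(UserWarning):
    pass


def fit_mixp(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotypes: PhenotypeVector | np.ndarray,
    prior: MixturePrior,
    resid_var: float,
    tol: float = 1e-5,
    max_iter: int = 1000,
    resid_recompute_every: int = 25,
) -> ICEState:
    """Run ICE sweeps until the relative squared-change criterion is met.

    Each sweep first updates the overall mean ``mu = 1'(y - B g) / n``, then
    applies :func:`ice_update_snp` to every SNP in ascending column order.
    Convergence is declared when ``sum((delta g)^2) < tol * sum(g^2)`` with a
    non-zero denominator.  The residual is recomputed from scratch every
    ``resid_recompute_every`` sweeps (and at convergence) to bound
    floating-point drift.  If ``max_iter`` sweeps pass without convergence a
    warning is issued and the state returned with ``converged=False``.
    """
    B = genotypes.standardized if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    y = phenotypes.values if isinstance(phenotypes, PhenotypeVector) else np.asarray(phenotypes, float)
    if B.ndim != 2 or B.shape[0] != y.shape[0]:
        raise ValueError("genotypes and phenotypes are not aligned")
    n, M = B.shape
    if M < 1:
        raise ValueError("need at least one marker")
    if M != prior.n_markers:
        raise ValueError(f"prior built for {prior.n_markers} markers, data has {M}")
    cols = [np.ascontiguousarray(B[:, i]) for i in range(M)]
    active = [i for i in range(M) if float(cols[i] @ cols[i]) > 0.0]
    if len(active) < M:
        logger.info("%d constant column(s) skipped (effect fixed at 0)", M - len(active))
    state = ICEState.initial(y, M)
    for sweep in range(1, max_iter + 1):
        # mean update: mu = 1'(y - B g)/n, equivalently mu += mean(residual)
        shift = float(np.mean(state.residual))
        state.mu += shift
        state.residual -= shift
        state.change_sq_sum = 0.0
        for i in active:
            ice_update_snp(state, cols[i], prior, resid_var, i)
        state.iteration = sweep
        state.solution_sq_sum = float(state.g_hat @ state.g_hat)
        if sweep % resid_recompute_every == 0:
            state.residual = y - state.mu - B @ state.g_hat
        # zero denominator counts as not converged, except at an exact fixed
        # point (nothing changed at all, e.g. a constant phenotype)
        if state.change_sq_sum == 0.0 or (
                state.solution_sq_sum > 0.0
                and state.change_sq_sum < tol * state.solution_sq_sum):
            state.converged = True
            state.residual = y - state.mu - B @ state.g_hat
            break
    if not state.converged:
        warnings.warn(
            f"MixP did not converge in {max_iter} sweeps "
            f"(relative change {state.change_sq_sum / max(state.solution_sq_sum, 1e-300):.3g})",
            ConvergenceWarning,
        )
    return state


def predict(genotypes: GenotypeMatrix | np.ndarray, state: ICEState) -> PhenotypeVector | np.ndarray:
    """Genome-wide estimated breeding values ``GWEBV_j = sum_i b_ji g_i``.

    The overall mean is deliberately excluded: breeding values are used for
    ranking and correlation with true genetic merit, both invariant to mu.
    """
    if isinstance(genotypes, GenotypeMatrix):
        B = genotypes.standardized
        ids = genotypes.individual_ids
    else:
        B = np.asarray(genotypes, float)
        ids = None
    if B.shape[1] != state.g_hat.shape[0]:
        raise ValueError(
            f"marker mismatch: state has {state.g_hat.shape[0]} effects, "
            f"genotypes have {B.shape[1]} markers"
        )
    gwebv = B @ state.g_hat
    if ids is not None:
        return PhenotypeVector(gwebv, ids)
    return gwebv


class MixP(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the MixP method.

    Parameters
    ----------
    pi : float, default=0.1
        Proportion of markers in the big-variance component, in (0, 0.5].
    genetic_variance : float, default=1.0
        Known total genetic variance Vg (trait units squared).
    resid_var : float, default=1.0
        Known residual variance sigma_e^2.
    tol : float, default=1e-5
        Relative squared-change convergence threshold.
    max_iter : int, default=1000
        Maximum number of ICE sweeps.

    Attributes
    ----------
    coef_ : ndarray of shape (n_markers,)
        Posterior-mean marker effects.
    intercept_ : float
        Estimated overall mean.
    prob_big_ : ndarray of shape (n_markers,)
        Posterior probability of each marker belonging to the big component.
    prior_ : MixturePrior
    n_iter_ : int
        Number of ICE sweeps performed.
    converged_ : bool

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> B = rng.standard_normal((50, 20))
    >>> y = B[:, 0] * 0.8 + rng.standard_normal(50)
    >>> model = MixP(pi=0.1, genetic_variance=0.7, resid_var=1.0).fit(B, y)
    >>> model.coef_.shape
    (20,)
    """

    def __init__(
        self,
        pi: float = 0.1,
        genetic_variance: float = 1.0,
        resid_var: float = 1.0,
        tol: float = 1e-5,
        max_iter: int = 1000,
        resid_recompute_every: int = 25,
    ):
        self.pi = pi
        self.genetic_variance = genetic_variance
        self.resid_var = resid_var
        self.tol = tol
        self.max_iter = max_iter
        self.resid_recompute_every = resid_recompute_every

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        prior = pareto_prior(self.pi, self.genetic_variance, X.shape[1])
        state = fit_mixp(
            X, y, prior, self.resid_var,
            tol=self.tol, max_iter=self.max_iter,
            resid_recompute_every=self.resid_recompute_every,
        )
        self.n_features_in_ = X.shape[1]
        self.prior_ = prior
        self.coef_ = state.g_hat
        self.intercept_ = state.mu
        self.prob_big_ = state.prob_big
        self.n_iter_ = state.iteration
        self.converged_ = state.converged
        self.state_ = state
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def breeding_values(self, X):
        """GWEBV (mean excluded): ``X @ coef_``."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_
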