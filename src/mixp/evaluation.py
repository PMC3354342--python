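"""Accuracy metrics, replicate scenario runner, and cross-validated
grid search for the mixture proportion pi.

Prediction accuracy is the Pearson correlation between estimated
(GWEBV) and true breeding values of evaluation individuals.  The scenario
runner repeats simulate -> fit -> predict -> correlate over replicates with
deterministically derived seeds and reports per-method means and standard
errors.  ``cv_grid_search`` mirrors a real-data protocol: repeated k-fold
cross-validation where the held-out criterion is the correlation between
GWEBV and *phenotypes* (true breeding values being unavailable in real
data), scanned over a grid of pi values.

``expected_accuracy`` implements the deterministic population-genetic
prediction r = sqrt(N h^2 / (N h^2 + 4 Ne L v)), where 4 Ne L v is the
effective number of independent chromosome segments.  It is invariant to
scaling h^2 and L down by the same factor, which is what justifies
simulating a single chromosome with a small per-chromosome heritability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .baselines import fit_bayesb, fit_gblup
from .engine import fit_mixp, pareto_prior
from .popsim import PedigreeSpec, SimConfig, SimulatedDataset, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "AccuracyReport",
    "CVGrid",
    "accuracy",
    "pooled_se",
    "run_scenario",
    "cv_grid_search",
    "expected_accuracy",
    "default_pi_grid",
]

METHODS = ("mixp", "gblup", "bayesb")


def accuracy(gwebv: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation between predicted and true breeding values.

    Raises on constant or too-short input instead of silently returning 0.
    """
    gwebv = np.asarray(gwebv, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if gwebv.shape != truth.shape or gwebv.ndim != 1 or gwebv.size < 3:
        raise ValueError("need two aligned 1-d vectors of length >= 3")
    if np.ptp(gwebv) == 0.0 or np.ptp(truth) == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(gwebv, truth).statistic)


@dataclass
class AccuracyReport:
    method: str
    scenario: dict
    replicate_accuracies: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_accuracies))

    @property
    def std_error(self) -> float:
        a = np.asarray(self.replicate_accuracies)
        return float(a.std(ddof=1) / np.sqrt(len(a)))


def pooled_se(a: AccuracyReport, b: AccuracyReport) -> float:
    return float(np.hypot(a.std_error, b.std_error))


def _fit_and_score(method: str, dataset: SimulatedDataset, seed: int,
                   bayesb_kwargs: dict | None = None) -> float:
    B_train, y_train = dataset.training_data()
    B_eval, truth = dataset.evaluation_data()
    vg = dataset.trait.realized_vg
    ve = dataset.trait.resid_var
    if method == "mixp":
        pi = min(dataset.pi_ratio, 0.5)
        state = fit_mixp(B_train, y_train,
                         pareto_prior(pi, vg, B_train.shape[1]), ve)
        gwebv = B_eval @ state.g_hat
    elif method == "gblup":
        res = fit_gblup(B_train, y_train, vg, ve)
        gwebv = B_eval @ res.g_hat
    elif method == "bayesb":
        kwargs = dict(n_iter=10000, n_burnin=3000, df=4.2)
        if bayesb_kwargs:
            kwargs.update(bayesb_kwargs)
        pi = min(max(dataset.pi_ratio, 1e-3), 0.999)
        res = fit_bayesb(B_train, y_train, pi, vg, ve, seed=seed, **kwargs)
        gwebv = B_eval @ res.g_hat
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return accuracy(gwebv, truth)


def run_scenario(
    config: SimConfig,
    methods: tuple[str, ...] = ("mixp", "gblup"),
    n_replicates: int = 20,
    seed: int = 0,
    pedigree: PedigreeSpec | None = None,
    bayesb_kwargs: dict | None = None,
) -> dict[str, AccuracyReport]:
    """Replicate simulate/fit/predict/score runs for each method.

    The simulated (realized) genetic and residual variances of each replicate
    are passed to the estimators as known parameters, and MixP uses
    pi = N_QTL / N_mkr.  Per-replicate seeds derive from the master seed, so
    two scenarios run with the same seed share identical replicate histories
    (only loci sampling and the trait differ with the scenario parameters).
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if pedigree is None:
        pedigree = PedigreeSpec()
    scenario = {"h2_chr": config.h2_chr, "n_markers": config.n_markers,
                "n_qtl": config.n_qtl}
    results: dict[str, list[float]] = {m: [] for m in methods}
    for rep in range(n_replicates):
        dataset = simulate_dataset(config, pedigree,
                                   seed=int(np.random.SeedSequence([seed, rep])
                                            .generate_state(1)[0] % (2**31)))
        for m in methods:
            results[m].append(_fit_and_score(m, dataset, seed=seed * 1000 + rep,
                                             bayesb_kwargs=bayesb_kwargs))
    return {m: AccuracyReport(m, dict(scenario), accs)
            for m, accs in results.items()}


def default_pi_grid() -> np.ndarray:
    """pi from 0.01 to 0.50 in steps of 0.01."""
    return np.round(np.arange(1, 51) * 0.01, 2)


@dataclass
class CVGrid:
    pi_grid: np.ndarray
    mean_correlation: np.ndarray
    fold_assignments: list[np.ndarray] = field(repr=False)

    @property
    def best_pi(self) -> float:
        return float(self.pi_grid[int(np.argmax(self.mean_correlation))])


def cv_grid_search(
    genotypes,
    phenotypes,
    heritability: float,
    pi_grid: np.ndarray | None = None,
    n_folds: int = 10,
    n_replicates: int = 10,
    seed: int = 0,
    tol: float = 1e-5,
) -> CVGrid:
    """Repeated k-fold cross-validation over a grid of pi values.

    Individuals are partitioned randomly and evenly (fold sizes differ by at
    most one).  Within each training split, Vg = h^2 var(y_train) and
    sigma_e^2 = (1 - h^2) var(y_train); MixP is fitted for every pi on the
    grid and the correlation between held-out GWEBV and held-out phenotypes
    is averaged across folds and replicates.  Folds with a constant held-out
    phenotype are skipped with a warning.
    """
    from .data_model import GenotypeMatrix, PhenotypeVector

    if isinstance(genotypes, GenotypeMatrix):
        B = genotypes.standardized
    else:
        B = np.asarray(genotypes, dtype=float)
    if isinstance(phenotypes, PhenotypeVector):
        y = phenotypes.values
    else:
        y = np.asarray(phenotypes, dtype=float)
    if B.shape[0] != y.shape[0]:
        raise ValueError("genotypes and phenotypes are not aligned")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if pi_grid is None:
        pi_grid = default_pi_grid()
    pi_grid = np.asarray(pi_grid, dtype=float)
    if np.any(np.diff(pi_grid) <= 0):
        raise ValueError("pi_grid must be strictly increasing")
    n = B.shape[0]
    rng = np.random.default_rng(seed)
    fold_assignments: list[np.ndarray] = []
    corr_sums = np.zeros(len(pi_grid))
    corr_counts = np.zeros(len(pi_grid))
    for _ in range(n_replicates):
        labels = np.empty(n, dtype=int)
        labels[rng.permutation(n)] = np.arange(n) % n_folds
        fold_assignments.append(labels)
        for fold in range(n_folds):
            held = labels == fold
            y_out = y[held]
            if np.ptp(y_out) == 0.0:
                logger.warning("fold %d has constant phenotype; skipped", fold)
                continue
            B_in, y_in = B[~held], y[~held]
            var_y = float(np.var(y_in, ddof=1))
            vg = heritability * var_y
            ve = (1.0 - heritability) * var_y
            for k, pi in enumerate(pi_grid):
                state = fit_mixp(B_in, y_in,
                                 pareto_prior(pi, vg, B_in.shape[1]), ve, tol=tol)
                gwebv = B[held] @ state.g_hat
                corr_sums[k] += accuracy(gwebv, y_out)
                corr_counts[k] += 1
    mean_corr = corr_sums / np.maximum(corr_counts, 1)
    return CVGrid(pi_grid, mean_corr, fold_assignments)


@dataclass(frozen=True)
class AccuracyFormulaInputs:
    n_training: int
    heritability: float
    effective_size: float
    genome_length: float  # Morgan
    segment_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.n_training <= 0 or self.effective_size <= 0 \
                or self.genome_length <= 0 or self.segment_ratio <= 0:
            raise ValueError("all inputs must be positive")
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")


def expected_accuracy(
    n_training: int,
    heritability: float,
    effective_size: float,
    genome_length: float,
    segment_ratio: float = 1.0,
) -> float:
    """Deterministic accuracy prediction r = sqrt(N h^2 / (N h^2 + 4 Ne L v))."""
    inp = AccuracyFormulaInputs(n_training, heritability, effective_size,
                                genome_length, segment_ratio)
    nh2 = inp.n_training * inp.heritability
    segments = 4.0 * inp.effective_size * inp.genome_length * inp.segment_ratio
    return float(np.sqrt(nh2 / (nh2 + segments)))
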