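"""Synthetic genotype/phenotype data via forward-in-time simulation and
gene-dropping.

The generator emulates a livestock genomic-selection study design:

1. an ideal random-mating population of effective size ``Ne`` is simulated
   forward in time under the infinite-sites model until mutation-drift
   balance, building up linkage disequilibrium on a single chromosome of
   ``L`` Morgan / ``L_bp`` base pairs (Haldane crossover model, Poisson
   crossover counts, no interference);
2. QTL and then marker loci are sampled uniformly, without replacement and
   disjointly, from the segregating sites with minor allele frequency at or
   above a threshold (default 0.05);
3. final-generation haplotypes are dropped through a pedigree (synthetic or
   user supplied): founders draw pool haplotypes, offspring receive one
   recombinant gamete per parent, and no new mutation occurs;
4. QTL effects are Laplace(0, scale) draws; true breeding values are summed
   dosage-weighted effects; phenotypes (training individuals only) add
   normal noise calibrated so the realized per-chromosome heritability among
   training individuals equals ``h2_chr``.

Default parameters mirror a historical population of Ne = 200 run for 10000
generations at mutation rate 1e-8/bp on a 1 Morgan / 1e8 bp chromosome.
:meth:`SimConfig.desk` provides a cheaper configuration (Ne = 100 for 800
generations with the mutation rate doubled) that preserves the population
mutation parameter theta = 4 Ne mu L_bp and therefore the equilibrium level
of polymorphism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .data_model import (
    GenotypeMatrix,
    Pedigree,
    PedigreeRecord,
    PhenotypeVector,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "PedigreeSpec",
    "HaplotypePool",
    "SimulatedTrait",
    "SimulatedDataset",
    "InsufficientSitesError",
    "DegenerateTraitError",
    "simulate_ideal_population",
    "sample_loci",
    "generate_pedigree",
    "gene_drop",
    "make_trait",
    "simulate_dataset",
]


class InsufficientSitesError(RuntimeError):
    """Too few segregating sites pass the MAF filter; simulate a longer
    history or lower the threshold."""


class DegenerateTraitError(RuntimeError):
    """Realized genetic variance is zero (all QTL monomorphic in the
    pedigree); re-simulate with a different seed."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the historical population and trait architecture."""

    effective_size: int = 200
    n_generations_history: int = 10000
    genome_length_bp: int = 100_000_000
    genome_length_morgan: float = 1.0
    mutation_rate: float = 1e-8  # per bp per meiosis
    maf_threshold: float = 0.05
    n_qtl: int = 30
    n_markers: int = 1500
    h2_chr: float = 0.03
    laplace_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.effective_size, self.n_generations_history,
               self.genome_length_bp, self.n_qtl, self.n_markers) <= 0:
            raise ValueError("sizes and counts must be positive")
        if self.genome_length_morgan < 0 or self.mutation_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 < self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in (0, 0.5)")
        if not 0.0 < self.h2_chr < 1.0:
            raise ValueError("h2_chr must lie in (0, 1)")

    @property
    def theta(self) -> float:
        """Population mutation parameter 4 Ne mu L_bp."""
        return 4.0 * self.effective_size * self.mutation_rate * self.genome_length_bp

    @classmethod
    def desk(cls, **overrides) -> "SimConfig":
        """Desk-scale history: Ne = 100 for 800 generations with theta
        preserved by doubling the mutation rate."""
        base = dict(effective_size=100, n_generations_history=800,
                    mutation_rate=2e-8)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class PedigreeSpec:
    """Shape of the synthetic layered pedigree.

    Defaults emulate a dairy-cattle pedigree of 19523 individuals over eight
    generations with 2165 genotyped bulls, the oldest 1915 of which form the
    training set and the youngest 250 the evaluation set.
    """

    n_total: int = 19523
    n_generations: int = 8
    n_genotyped: int = 2165
    n_training: int = 1915
    n_evaluation: int = 250

    def __post_init__(self) -> None:
        if not (self.n_training + self.n_evaluation <= self.n_genotyped
                <= self.n_total):
            raise ValueError("need n_training + n_evaluation <= n_genotyped <= n_total")
        if self.n_generations < 1 or self.n_total < self.n_generations:
            raise ValueError("infeasible generation layout")


@dataclass
class HaplotypePool:
    """2 Ne haplotypes as sorted arrays of mutant (derived-allele) positions."""

    haplotypes: list[np.ndarray]
    genome_length_bp: int
    positions: np.ndarray = field(default=None, repr=False)
    frequencies: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.positions is None:
            if self.haplotypes and any(len(h) for h in self.haplotypes):
                allpos = np.concatenate(self.haplotypes)
                self.positions, counts = np.unique(allpos, return_counts=True)
                self.frequencies = counts / len(self.haplotypes)
            else:
                self.positions = np.empty(0, dtype=np.int64)
                self.frequencies = np.empty(0)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_segregating(self) -> int:
        return len(self.positions)

    def allele_matrix(self, loci: np.ndarray) -> np.ndarray:
        """(n_haplotypes, len(loci)) 0/1 matrix of derived alleles at loci."""
        loci = np.asarray(loci, dtype=np.int64)
        out = np.zeros((self.n_haplotypes, len(loci)), dtype=np.int8)
        for k, hap in enumerate(self.haplotypes):
            if len(hap):
                out[k] = np.isin(loci, hap, assume_unique=True)
        return out


@njit(cache=False)
def _history_kernel(ne, n_gen, lbp, lm, mut_mean, seed):  # pragma: no cover
    """Forward neutral simulation over segregating sites only.

    Haplotypes are rows of a 0/1 matrix whose columns are the currently
    segregating sites (column order is arbitrary during evolution; the caller
    sorts by position at the end).  Fixed and lost columns are pruned every
    generation, which keeps the matrix at its equilibrium width.
    """
    np.random.seed(seed)
    n_hap = 2 * ne
    H = np.zeros((n_hap, 0), dtype=np.uint8)
    positions = np.empty(0, dtype=np.int64)
    for _ in range(n_gen):
        S = positions.shape[0]
        n_mut = np.empty(n_hap, dtype=np.int64)
        total_new = 0
        for r in range(n_hap):
            n_mut[r] = np.random.poisson(mut_mean)
            total_new += n_mut[r]
        H2 = np.zeros((n_hap, S + total_new), dtype=np.uint8)
        new_pos = np.empty(total_new, dtype=np.int64)
        col = S
        for off in range(ne):
            for side in range(2):
                row = 2 * off + side
                p = np.random.randint(0, ne)
                k = np.random.poisson(lm)
                start = np.random.randint(0, 2)
                if k == 0 or S == 0:
                    src = 2 * p + start
                    for j in range(S):
                        H2[row, j] = H[src, j]
                else:
                    cx = np.sort(np.random.randint(1, lbp, k))
                    for j in range(S):
                        # segment index = number of crossovers left of the site
                        lo, hi = 0, k
                        pos_j = positions[j]
                        while lo < hi:
                            mid = (lo + hi) // 2
                            if cx[mid] < pos_j:
                                lo = mid + 1
                            else:
                                hi = mid
                        H2[row, j] = H[2 * p + ((start + lo) % 2), j]
                for _m in range(n_mut[row]):
                    new_pos[col - S] = np.random.randint(1, lbp + 1)
                    H2[row, col] = 1
                    col += 1
        # prune fixed and lost sites
        S2 = S + total_new
        counts = np.zeros(S2, dtype=np.int64)
        for r in range(n_hap):
            for j in range(S2):
                counts[j] += H2[r, j]
        keep = np.empty(S2, dtype=np.int64)
        nk = 0
        for j in range(S2):
            if 0 < counts[j] < n_hap:
                keep[nk] = j
                nk += 1
        all_pos = np.empty(S2, dtype=np.int64)
        for j in range(S):
            all_pos[j] = positions[j]
        for m in range(total_new):
            all_pos[S + m] = new_pos[m]
        positions = np.empty(nk, dtype=np.int64)
        Hn = np.empty((n_hap, nk), dtype=np.uint8)
        for jj in range(nk):
            positions[jj] = all_pos[keep[jj]]
            for r in range(n_hap):
                Hn[r, jj] = H2[r, keep[jj]]
        H = Hn
    return H, positions


def simulate_ideal_population(config: SimConfig,
                              rng: np.random.Generator | None = None) -> HaplotypePool:
    """Forward simulation of 2 Ne haplotypes to mutation-drift balance.

    Each generation, Ne offspring are formed by random mating (parents drawn
    uniformly with replacement); each transmitted gamete recombines with a
    Poisson(L_morgan) number of crossovers at uniform positions and gains a
    Poisson(mu * L_bp) number of new mutations at uniform positions
    (infinite sites: with a base-pair genome the chance of a repeat position
    is vanishing; the rare collision is resolved by keeping the first site).
    Fixed and lost sites are pruned every generation.  Deterministic given
    the seed (or generator) supplied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    kernel_seed = int(rng.integers(2**32))
    H, positions = _history_kernel(
        config.effective_size, config.n_generations_history,
        config.genome_length_bp, config.genome_length_morgan,
        config.mutation_rate * config.genome_length_bp, kernel_seed)
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    H = H[:, order]
    uniq, first = np.unique(positions, return_index=True)
    if len(uniq) < len(positions):  # positional collision: keep first site
        positions = positions[first]
        H = H[:, first]
    haps = [positions[H[r].astype(bool)] for r in range(H.shape[0])]
    return HaplotypePool(haps, config.genome_length_bp)


def sample_loci(pool: HaplotypePool, config: SimConfig,
                rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sample disjoint QTL and marker position sets from MAF-passing sites.

    QTL are drawn first, uniformly without replacement, from the sites whose
    folded (minor) allele frequency is at least ``maf_threshold``; markers
    are then drawn from the remaining qualifying sites.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    maf = np.minimum(pool.frequencies, 1.0 - pool.frequencies)
    qualifying = pool.positions[maf >= config.maf_threshold]
    need = config.n_qtl + config.n_markers
    if len(qualifying) < need:
        raise InsufficientSitesError(
            f"only {len(qualifying)} sites with MAF >= {config.maf_threshold}, "
            f"need {need}; simulate a longer history or lower the threshold"
        )
    pick = rng.choice(len(qualifying), size=need, replace=False)
    qtl = np.sort(qualifying[pick[:config.n_qtl]])
    markers = np.sort(qualifying[pick[config.n_qtl:]])
    return markers, qtl


def generate_pedigree(
    n_total: int = 19523,
    n_generations: int = 8,
    n_genotyped: int = 2165,
    n_training: int = 1915,
    n_evaluation: int = 250,
    seed: int | np.random.Generator = 0,
) -> Pedigree:
    """Layered synthetic pedigree emulating a multi-generation bull pedigree.

    Generation 0 individuals are founders with unknown parents; each later
    generation draws sire and dam uniformly from the previous generation.
    ``n_genotyped`` individuals are sampled from the younger half of the
    pedigree; the oldest ``n_training`` of them are the training set and the
    youngest ``n_evaluation`` the evaluation set (any in between are
    genotyped but unused).
    """
    spec = PedigreeSpec(n_total, n_generations, n_genotyped, n_training, n_evaluation)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base, rem = divmod(n_total, n_generations)
    sizes = [base + (1 if g < rem else 0) for g in range(n_generations)]
    width = len(str(n_total))
    ids = [f"I{k:0{width}d}" for k in range(1, n_total + 1)]
    # genotyped individuals come from the younger half (all gens if tiny)
    half_start = 0 if n_generations == 1 else sum(sizes[: n_generations // 2])
    candidates = np.arange(half_start, n_total)
    if len(candidates) < n_genotyped:
        candidates = np.arange(n_total)
    genotyped_idx = np.sort(rng.choice(candidates, size=n_genotyped, replace=False))
    roles = {}
    for j, idx in enumerate(genotyped_idx):
        if j < n_training:
            roles[idx] = "training"
        elif j >= n_genotyped - n_evaluation:
            roles[idx] = "evaluation"
        else:
            roles[idx] = "none"
    genotyped = set(genotyped_idx.tolist())
    records: list[PedigreeRecord] = []
    k = 0
    prev_range: tuple[int, int] | None = None
    for g, size in enumerate(sizes):
        start = k
        for _ in range(size):
            if g == 0:
                sire = dam = None
            else:
                lo, hi = prev_range
                sire = ids[int(rng.integers(lo, hi))]
                dam = ids[int(rng.integers(lo, hi))]
            records.append(PedigreeRecord(
                ids[k], sire, dam, k in genotyped, roles.get(k, "none")))
            k += 1
        prev_range = (start, k)
    return Pedigree(records)


def gene_drop(
    pool: HaplotypePool,
    pedigree: Pedigree,
    marker_positions: np.ndarray,
    qtl_positions: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop final-generation haplotypes through the pedigree.

    Founder gametes are drawn uniformly without replacement from the pool
    (falling back to with-replacement once the pool is exhausted, logged);
    every other gamete is a Haldane-recombinant copy of its parent's two
    haplotypes.  No mutation occurs.  A non-founder with one unknown parent
    draws a fresh founder gamete for the unknown slot.

    Returns the marker GenotypeMatrix for genotyped individuals (allele
    frequencies re-estimated from those individuals; markers monomorphic in
    the sample are dropped) and the QTL dosage matrix for *all* pedigree
    individuals (for true breeding values).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    marker_positions = np.asarray(marker_positions, dtype=np.int64)
    qtl_positions = np.asarray(qtl_positions, dtype=np.int64)
    loci = np.union1d(marker_positions, qtl_positions)
    if len(loci) != len(marker_positions) + len(qtl_positions):
        raise ValueError("marker and QTL position sets must be disjoint")
    pool_alleles = pool.allele_matrix(loci)
    n_pool = pool.n_haplotypes
    n_ind = len(pedigree)
    n_loci = len(loci)
    H = np.zeros((n_ind, 2, n_loci), dtype=np.int8)
    index = {pid: i for i, pid in enumerate(pedigree.ids())}
    founder_order = rng.permutation(n_pool)
    founder_ptr = 0
    warned = False
    lbp = config.genome_length_bp
    lm = config.genome_length_morgan

    def founder_gamete() -> np.ndarray:
        nonlocal founder_ptr, warned
        if founder_ptr < n_pool:
            h = pool_alleles[founder_order[founder_ptr]]
            founder_ptr += 1
            return h
        if not warned:
            logger.info("haplotype pool exhausted; founder gametes now drawn "
                        "with replacement")
            warned = True
        return pool_alleles[int(rng.integers(n_pool))]

    def parental_gamete(parent_row: int) -> np.ndarray:
        k = rng.poisson(lm)
        start = int(rng.integers(2))
        if k == 0:
            return H[parent_row, start]
        cx = np.sort(rng.integers(1, lbp, size=k))
        seg = np.searchsorted(cx, loci)
        use_first = (seg + start) % 2 == 0
        return np.where(use_first, H[parent_row, 0], H[parent_row, 1])

    for i, rec in enumerate(pedigree.records):
        for side, parent in enumerate((rec.sire, rec.dam)):
            if parent is None:
                H[i, side] = founder_gamete()
            else:
                H[i, side] = parental_gamete(index[parent])

    dosages = H.sum(axis=1, dtype=np.int8)
    marker_cols = np.searchsorted(loci, marker_positions)
    qtl_cols = np.searchsorted(loci, qtl_positions)
    genotyped_idx = [index[g] for g in pedigree.genotyped_ids]
    gm = GenotypeMatrix.from_dosages(
        dosages[np.ix_(genotyped_idx, marker_cols)].astype(float),
        marker_ids=[f"M{p}" for p in marker_positions],
        individual_ids=pedigree.genotyped_ids,
    )
    return gm, dosages[:, qtl_cols]


@dataclass
class SimulatedTrait:
    qtl_positions: np.ndarray
    qtl_effects: np.ndarray
    true_bv: PhenotypeVector  # all pedigree individuals
    phenotypes: PhenotypeVector  # training individuals only
    realized_vg: float
    resid_var: float


def make_trait(
    qtl_dosages: np.ndarray,
    pedigree: Pedigree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    qtl_positions: np.ndarray | None = None,
) -> SimulatedTrait:
    """Laplace QTL effects, true breeding values and training phenotypes.

    The residual variance is set from the *realized* genetic variance among
    training individuals, ``sigma_e^2 = vg (1 - h2) / h2``, so the simulated
    variances can be handed to the estimators as known parameters.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if qtl_dosages.shape[0] != len(pedigree):
        raise ValueError("QTL dosages must cover every pedigree individual")
    effects = rng.laplace(0.0, config.laplace_scale, size=qtl_dosages.shape[1])
    tbv = qtl_dosages.astype(float) @ effects
    ids = pedigree.ids()
    idx = {pid: i for i, pid in enumerate(ids)}
    training = pedigree.training_ids
    tbv_train = tbv[[idx[t] for t in training]]
    realized_vg = float(np.var(tbv_train, ddof=1)) if len(training) > 1 else 0.0
    if realized_vg <= 0.0:
        raise DegenerateTraitError("realized genetic variance is zero; re-simulate")
    resid_var = realized_vg * (1.0 - config.h2_chr) / config.h2_chr
    noise = rng.normal(0.0, np.sqrt(resid_var), size=len(training))
    phenos = PhenotypeVector(tbv_train + noise, training)
    if qtl_positions is None:
        qtl_positions = np.arange(qtl_dosages.shape[1])
    return SimulatedTrait(
        qtl_positions=np.asarray(qtl_positions),
        qtl_effects=effects,
        true_bv=PhenotypeVector(tbv, ids),
        phenotypes=phenos,
        realized_vg=realized_vg,
        resid_var=resid_var,
    )


@dataclass
class SimulatedDataset:
    """Everything one replicate produces, aligned and ready for fitting."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # genotyped individuals x retained markers
    trait: SimulatedTrait
    marker_positions: np.ndarray
    qtl_positions: np.ndarray

    @property
    def pi_ratio(self) -> float:
        """N_QTL / N_mkr over the markers actually retained."""
        return self.qtl_positions.size / self.genotypes.n_markers

    def training_data(self) -> tuple[np.ndarray, np.ndarray]:
        gm = self.genotypes.subset(self.trait.phenotypes.individual_ids)
        return gm.standardized, self.trait.phenotypes.values

    def evaluation_data(self) -> tuple[np.ndarray, np.ndarray]:
        eval_ids = self.pedigree.evaluation_ids
        gm = self.genotypes.subset(eval_ids)
        truth = self.trait.true_bv.reindex(eval_ids)
        return gm.standardized, truth.values


# simple in-process cache of historical pools: a pool is a pure function of
# the history parameters and seed, so reuse across scenarios is safe
_POOL_CACHE: dict[tuple, HaplotypePool] = {}
_POOL_CACHE_MAX = 64


def _cached_pool(config: SimConfig, seed: int) -> HaplotypePool:
    key = (config.effective_size, config.n_generations_history,
           config.genome_length_bp, config.genome_length_morgan,
           config.mutation_rate, int(seed))
    pool = _POOL_CACHE.get(key)
    if pool is None:
        pool = simulate_ideal_population(config, np.random.default_rng(int(seed)))
        if len(_POOL_CACHE) >= _POOL_CACHE_MAX:
            _POOL_CACHE.pop(next(iter(_POOL_CACHE)))
        _POOL_CACHE[key] = pool
    return pool


def _stage_seed(*entropy: int) -> int:
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


def simulate_dataset(
    config: SimConfig,
    pedigree: Pedigree | PedigreeSpec | None = None,
    seed: int = 0,
    max_redraws: int = 5,
    cache_pool: bool = True,
) -> SimulatedDataset:
    """Full pipeline: history -> loci -> pedigree -> gene drop -> trait.

    Deterministic given ``seed``; stage-specific streams are derived from it.
    If loci sampling or the trait degenerates, the replicate is redrawn with
    a derived seed, up to ``max_redraws`` times.
    """
    if pedigree is None:
        pedigree = PedigreeSpec()
    if isinstance(pedigree, PedigreeSpec):
        pedigree = generate_pedigree(
            pedigree.n_total, pedigree.n_generations, pedigree.n_genotyped,
            pedigree.n_training, pedigree.n_evaluation,
            seed=np.random.default_rng(_stage_seed(seed, 9)),
        )
    last_err: Exception | None = None
    for attempt in range(max_redraws + 1):
        pool_seed = _stage_seed(seed, attempt, 0)
        try:
            if cache_pool:
                pool = _cached_pool(config, pool_seed)
            else:
                pool = simulate_ideal_population(
                    config, np.random.default_rng(pool_seed))
            markers, qtl = sample_loci(
                pool, config, np.random.default_rng(_stage_seed(seed, attempt, 1)))
            gm, qtl_dosages = gene_drop(
                pool, pedigree, markers, qtl, config,
                np.random.default_rng(_stage_seed(seed, attempt, 2)))
            trait = make_trait(
                qtl_dosages, pedigree, config,
                np.random.default_rng(_stage_seed(seed, attempt, 3)),
                qtl_positions=qtl)
            return SimulatedDataset(config, pedigree, gm, trait, markers, qtl)
        except (InsufficientSitesError, DegenerateTraitError) as err:
            logger.warning("replicate redraw (attempt %d): %s", attempt + 1, err)
            last_err = err
    raise RuntimeError(f"simulation failed after {max_redraws} redraws") from last_err
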