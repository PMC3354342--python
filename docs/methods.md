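# Methods

## The model

Phenotypic records of genotyped individuals follow the SNP-regression model

    y = 1 mu + sum_i b_i g_i + e,        Var(e) = I sigma_e^2,

where `b_i` is the standardized genotype column of SNP `i`,
`b = (dosage - 2p) / sqrt(2 p (1 - p))`, `g_i` is the additive effect of the
SNP, and the total genetic variance `Vg` and residual variance `sigma_e^2`
are treated as known (in practice a REML/GBLUP variance-component estimate;
in simulation the realized values).

MixP places a two-component normal mixture prior on each effect,

    p(g_i) = pi N(0, sigma1^2) + (1 - pi) N(0, sigma2^2),

and fixes both component variances by the Pareto principle: the `pi` fraction
of markers with the biggest effects is assumed to explain the `1 - pi`
fraction of `Vg`,

    sigma1^2 = (1 - pi) Vg / (pi M),     sigma2^2 = pi Vg / ((1 - pi) M),

so that `M (pi sigma1^2 + (1 - pi) sigma2^2) = Vg` holds identically.  This
collapses the prior's free hyper-parameters to the single proportion `pi`,
constrained to (0, 0.5]: at `pi = 0.5` both variances equal `Vg / M` and the
method *is* GBLUP.  Values above 0.5 would make the "big" component the
smaller one and are rejected.

## The ICE solver

Effects are estimated by iterative conditional expectation: each SNP in turn
is replaced by its exact posterior mean given the current estimates of all
other effects and the mean.  For corrected records
`y~ = y - 1 mu - sum_{j != i} b_j g_j`, the update is the
posterior-probability-weighted average of the two single-variance BLUP
estimates,

    g_i = (pi L1 g1 + (1 - pi) L2 g2) / (pi L1 + (1 - pi) L2),
    gk  = b'y~ / (b'b + sigma_e^2 / sigmak^2),

with `Lk` the marginal likelihood of `y~` under component `k`.  The mean is
the posterior mean (not the mode) because the mixture posterior can be
bimodal, in which case a mode is an arbitrary representative.  Each `Lk`
nominally needs the determinant and inverse of the n-by-n matrix
`V = b b' sigmak^2 + I sigma_e^2`; rank-one (Sherman-Morrison) identities
reduce both to scalars:

    log|V|   = n log sigma_e^2 + log(b'b sigmak^2 / sigma_e^2 + 1)
    y~'V^-1y~ = (y~'y~ - y~'b gk) / sigma_e^2

The shared additive constant of the two component log-likelihoods is set to
zero; only the ratio enters the update, computed in log space with the
exponent clamped to +-700 to avoid overflow at realistic n.

Numerical and scheduling choices (the description of the algorithm leaves
these open; they are fixed here for reproducibility):

* SNPs are visited in ascending column order in every sweep.
* `mu = 1'(y - B g) / n` is updated once per sweep, before the SNP updates.
* The residual vector is maintained incrementally (`r <- r - b_i delta_i`)
  and recomputed from scratch every 25 sweeps and at convergence to bound
  floating-point drift.
* Convergence: `sum((delta g)^2) < tol * sum(g^2)` with `tol = 1e-5` by
  default.  A zero denominator counts as not converged (the relative rule is
  undefined there) *except* when the sweep changed nothing at all, which is
  an exact fixed point (e.g. a constant phenotype).
* Columns that are constant in the training rows (`b'b = 0`) are skipped and
  their effect fixed at 0.
* `max_iter = 1000` by default - a generous ceiling, since the solver is
  observed (and tested) to converge in well under 50 sweeps; hitting the
  ceiling warns rather than raises.

Genome-wide estimated breeding values are `GWEBV_j = sum_i b_ji g_i`; the
mean is excluded because breeding values are used for ranking and
correlation, both invariant to it.

## Baselines

**GBLUP / SNP-BLUP** gives every marker prior variance `Vg / M`.  The direct
solver solves the joint mixed-model equations for `(mu, g)` densely (used up
to M = 5000, and as the oracle in tests); the iterative solver is per-SNP
Gauss-Seidel with the same stopping rule as MixP.

**BayesB** is the "small effects are small, not zero" variant: with
probability `pi` a SNP effect comes from a big-variance normal, otherwise
from a small-variance normal, fitted by Gibbs sampling with 10000 iterations
and 3000 burn-in.  The full conditionals are conjugate: the component
indicator is sampled from the integrated (effect-marginalized) likelihood
ratio; the effect from its Gaussian full conditional; the big-component
variances (locus-specific) and the shared small-component variance from
scaled inverse-chi-squared full conditionals with 4.2 prior degrees of
freedom.  The inverse-chi-squared scale parameters are anchored so the prior
*means* of the component variances equal the Pareto values `sigma1^2` and
`sigma2^2` - a deliberate interpretation, since only the degrees of freedom
are standard.  `pi` is fixed, not sampled, and the residual variance is held
at its known value.  A seed is mandatory and stored with the result;
`sample_variances=False` freezes the component variances at their prior
means, which makes the model fully Gaussian and lets tests compare the chain
against the exact GBLUP posterior mean.

## The synthetic-data generator

The simulator emulates a dairy-cattle genomic-selection design on a single
chromosome:

1. **History.** An ideal random-mating population of effective size `Ne` is
   evolved forward under the infinite-sites model on a chromosome of
   1 Morgan / 1e8 bp, with Poisson(L Morgan) crossovers per meiosis (Haldane,
   no interference) and Poisson(mu L_bp) new mutations per gamete, until
   mutation-drift balance.  Full-scale parameters are `Ne = 200`, 10000
   generations, `mu = 1e-8`/bp.  The desk-scale preset (`SimConfig.desk()`)
   uses `Ne = 100` for 800 generations (8 Ne) with `mu = 2e-8`, preserving
   `theta = 4 Ne mu L_bp = 800` and hence the equilibrium polymorphism
   level; one history then costs seconds instead of minutes.  Internally the
   population is a 0/1 matrix over currently segregating sites (pruned of
   fixed and lost columns every generation, compiled with numba); the public
   container exposes the equivalent sparse mutant-position sets.  Positional
   collisions of new mutations are vanishingly rare (~5e-5 per draw) and are
   resolved by keeping the first site.
2. **Loci.** QTL first, then markers, are sampled uniformly without
   replacement - and disjointly - from the sites with folded (minor) allele
   frequency >= 0.05.
3. **Pedigree.** A layered pedigree: founders in generation 0, each later
   individual drawing sire and dam uniformly from the previous generation.
   Defaults emulate a real bull pedigree: 19523 individuals over 8
   generations, 2165 genotyped, the oldest 1915 genotyped individuals as
   training set and the youngest 250 as evaluation set.  Genotyped
   individuals are sampled from the younger half of the pedigree.  User
   pedigrees read from TSV are re-sorted so parents precede offspring.
4. **Gene drop.** Founder gametes are final-generation pool haplotypes drawn
   without replacement (falling back to with-replacement once the 2 Ne pool
   is exhausted, as it is for thousands of founders); every other gamete is
   a Haldane-recombinant copy of the parent's two haplotypes; no new
   mutation.
5. **Trait.** QTL effects are Laplace(0, 1) draws; `TBV_j` is the
   dosage-weighted sum; `sigma_e^2 = vg (1 - h2_chr) / h2_chr` with `vg`
   the *realized* TBV variance among training individuals, so the simulated
   variances can be handed to the estimators as known parameters.  Only
   training individuals receive phenotypes (one record each, like a
   progeny-test reliability design); `h2_chr` is a per-chromosome
   heritability, roughly the total heritability divided by the chromosome
   count.  The deterministic accuracy formula
   `r = sqrt(N h^2 / (N h^2 + 4 Ne L v))` is invariant to scaling `h^2` and
   `L` down together, which is what justifies the single-chromosome design.

What the generator does *not* emulate: multiple chromosomes, selection or
assortative mating in the history or pedigree, genotyping error and
missingness patterns of real arrays, dominance/epistasis, and non-normal
environmental effects.  Passing tests therefore demonstrate internal
consistency and the method's behaviour under its own model assumptions, not
performance on any particular real population.

## Evaluation protocol

Accuracy is the Pearson correlation between GWEBV and true breeding values
of the evaluation individuals.  The scenario runner repeats
simulate-fit-predict-score with per-replicate seeds derived from one master
seed; MixP receives `pi = N_QTL / N_mkr` (clipped to 0.5) and all methods
receive the replicate's realized variances.  Replicate histories depend only
on the master seed and replicate index, so scenarios run with the same seed
share histories (cached in-process), which both saves time and makes
cross-scenario comparisons paired.

Cross-validated grid search mirrors a real-data protocol where true breeding
values are unavailable: individuals are partitioned randomly and evenly into
k folds (sizes differ by at most one); within each training split
`Vg = h^2 var(y)` and `sigma_e^2 = (1 - h^2) var(y)`; the held-out criterion
is the correlation between GWEBV and phenotypes, averaged over folds and
replicates per grid value (per-fold correlations averaged, not pooled).

## Problem sizes used by the tests and the acceptance script

* Convergence and the acceptance script: 20 replicates of the full-size
  design (19523-individual pedigree, 1915 training / 250 evaluation, 1500
  markers, 30 QTL, `h2_chr = 0.03`) on the desk-scale history.
* Method comparisons: 20 replicates on a reduced design (700-individual
  pedigree over 5 generations, 400 training / 100 evaluation, 200 markers)
  across QTL counts {5, 100}, heritabilities {0.01, 0.03, 0.05} and marker
  densities {100, 200, 500}.  Directional claims are asserted against pooled
  standard errors over replicates.
* CV flatness: one scenario (200 markers, 10 QTL, `h2_chr = 0.3`,
  400 phenotyped individuals), 10 folds, 2 replicates, the full
  0.01-0.50 grid.
* Oracle tests: dense multivariate-normal likelihood (n <= 50) and adaptive
  quadrature of the single-SNP posterior mean, with integration breakpoints
  at the likelihood peak so the adaptive rule cannot miss it.

## Known limitations

* `Vg` and `sigma_e^2` are never estimated; they are inputs.
* The wheat-style CV criterion correlates GWEBV with phenotypes, which is
  bounded by sqrt(h^2) - it is a model-selection signal, not an accuracy
  estimate.
* BayesB's variance-scale anchoring to the Pareto variances is one
  reasonable choice among several; posterior inclusion probabilities are
  sensitive to it.
* The GBLUP dense solver forms an (M+1)-square system; beyond ~5000 markers
  the iterative solver is selected automatically.
* MCMC comparisons in the tests use block-mean Monte-Carlo standard errors,
  which understate error if autocorrelation exceeds the block length.
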