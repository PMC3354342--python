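# mixp

Genome-wide breeding value estimation with a Pareto-principle mixture prior
(**MixP**), together with GBLUP and BayesB baselines, a pedigree-based
genotype/phenotype simulator, and cross-validation tooling.

## The problem

Genomic selection predicts the additive genetic merit (GWEBV) of selection
candidates from genome-wide SNP genotypes, using a reference population with
both genotypes and phenotypes.  Methods differ in the prior placed on marker
effects: GBLUP gives every marker the same normal prior (fast, but blind to
large-effect loci), while Bayesian mixtures allow a few large effects but
traditionally need MCMC.

MixP keeps the mixture but removes both the MCMC and the extra
hyper-parameters.  Writing `y = 1μ + Σᵢ bᵢgᵢ + e` with standardized
genotypes `b = (d − 2p)/√(2p(1−p))`, each effect gets the prior

> p(gᵢ) = π N(0, σ₁²) + (1 − π) N(0, σ₂²)

with both variances fixed by the Pareto ("80:20") principle — the π fraction
of markers with the largest effects explains the (1 − π) fraction of the
genetic variance V_g:

> σ₁² = (1 − π) V_g / (π M),  σ₂² = π V_g / ((1 − π) M),

so that M(πσ₁² + (1−π)σ₂²) = V_g.  Given V_g, the prior has a single free
parameter π ∈ (0, 0.5], estimable by cross-validation; π = 0.5 recovers
GBLUP exactly.  Effects are solved by **iterative conditional expectation**:
each SNP in turn is set to its exact posterior mean given all other current
estimates — a weighted average of two ridge estimates, with scalar
(Sherman–Morrison) likelihood identities in place of any n×n algebra.  The
solver typically converges in well under 50 sweeps, putting it in GBLUP's
speed class rather than MCMC's.

## Worked example

```python
import numpy as np
from mixp import MixP, GBLUP, SimConfig, PedigreeSpec, simulate_dataset, accuracy

# simulate one replicate: forward population history, loci sampling,
# gene-dropping through a synthetic 5-generation pedigree, Laplace QTL trait
cfg = SimConfig.desk(n_markers=200, n_qtl=5, h2_chr=0.03)
ped = PedigreeSpec(n_total=700, n_generations=5, n_genotyped=500,
                   n_training=400, n_evaluation=100)
ds = simulate_dataset(cfg, ped, seed=7)
B_train, y_train = ds.training_data()
B_eval, tbv_eval = ds.evaluation_data()

model = MixP(pi=ds.pi_ratio,                      # N_QTL / N_mkr = 0.025
             genetic_variance=ds.trait.realized_vg,
             resid_var=ds.trait.resid_var).fit(B_train, y_train)
print(f"converged in {model.n_iter_} sweeps")
print(f"MixP  accuracy: {accuracy(model.breeding_values(B_eval), tbv_eval):.3f}")

gblup = GBLUP(genetic_variance=ds.trait.realized_vg,
              resid_var=ds.trait.resid_var).fit(B_train, y_train)
print(f"GBLUP accuracy: {accuracy(gblup.breeding_values(B_eval), tbv_eval):.3f}")
```

Output:

```
converged in 5 sweeps
MixP  accuracy: 0.120
GBLUP accuracy: 0.074
```

The accuracy is the Pearson correlation between predicted and true breeding
values of the 100 evaluation individuals, which carry genotypes but no
phenotypes.  Absolute accuracies are modest because this is a single
chromosome at per-chromosome heritability 0.03 with only 400 training
records; the instructive part is the comparison.  With only 5 QTL the
mixture prior concentrates evidence on the few large-effect markers and
beats uniform-shrinkage GBLUP; with many QTL the two converge (and at
π = 0.5 they coincide by construction).  The replicated version of this
comparison, with pooled standard errors, lives in
`tests/test_acceptance.py`.

The estimators follow scikit-learn conventions (`fit`/`predict`,
`get_params`, fitted attributes like `coef_`, `prob_big_`, `n_iter_`), so
they compose with sklearn model-selection tooling.  `cv_grid_search`
implements the repeated 10-fold cross-validation protocol for choosing π on
real data, and `expected_accuracy` the deterministic prediction
r = √(Nh² / (Nh² + 4NₑLv)).

There is also a command-line interface:

```bash
mixp simulate --desk --seed 1 --out-dir data/
mixp fit --method mixp --pi 0.02 --vg 14.3 --ve 463 \
     --genotypes data/genotypes.tsv --phenotypes data/phenotypes.tsv \
     --out effects.tsv
mixp predict --genotypes data/genotypes.tsv --effects effects.tsv --out gwebv.tsv
mixp evaluate --predictions gwebv.tsv --truth data/truth.tsv
```

Every command writes a JSON manifest sufficient to regenerate its output.

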