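# famimpute

Phenotype imputation for family-based association studies, using the
conditional multivariate normal distribution over pedigrees.

## The problem

Genome-wide association studies lose power whenever the analysis phenotype
is missing for part of the sample — follow-up visits are skipped, assays
are expensive, participants drop out.  The common fix, dropping every
incomplete sample, throws away information twice over: the missing person
usually *has* a correlated second phenotype (e.g. a pre-treatment
measurement of the same trait), and their relatives carry information about
their genetic make-up.  `famimpute` exploits both.  It models two
phenotypes on `n` pedigree members as one multivariate-normal vector of
length `2n` with covariance

    Σ = Σ_A ⊗ φ + Σ_E ⊗ I ,

where `Σ_A`/`Σ_E` are the 2×2 additive-genetic and environmental
covariance matrices of the phenotype pair and `φ` is the pedigree-derived
genetic relationship matrix (twice the kinship coefficient).  After
estimating `(Σ_A, Σ_E)` by maximum likelihood from the observed data, every
missing entry is replaced by its conditional expectation

    E(Y_m | Y_o) = μ_m + Σ_mo Σ_oo⁻¹ (Y_o − μ_o) ,

and association runs on the completed sample with a linear mixed model
(pedigree random effect, per-SNP 1-df score test).  The package also ships
a synthetic family-study generator and evaluation drivers that quantify
type-I error, power and imputation accuracy of the whole pipeline, so its
statistical claims can be reproduced from scratch without any restricted
data.

Intended users: statistical geneticists analyzing family cohorts with
partially missing quantitative phenotypes, and methodologists who want a
transparent reference implementation of conditional-mean phenotype
imputation with variance-component estimation.

## Worked example

```python
import numpy as np
from famimpute import (
    SimulationConfig, simulate_pedigrees, sampled_ids, compute_phi,
    simulate_phenotypes, apply_missingness, fit_bivariate_polygenic, impute_panel,
)

config = SimulationConfig(n_families=170, seed=7)          # 680 samples
ped = simulate_pedigrees(config)
phi = compute_phi(ped).subset(sampled_ids(config))

truth = simulate_phenotypes(phi, config.with_(causal_spec=[]), seed=7)
panel = apply_missingness(truth, fraction=0.17, seed=7)    # hide 17% of phenotype 2

vc = fit_bivariate_polygenic(panel, phi)
print(f"h2(pre) = {vc.heritability(1):.2f}   h2(post) = {vc.heritability(2):.2f}")
print(f"phenotypic correlation = {vc.phenotypic_correlation:.3f}")
print(f"log-likelihood = {vc.loglik:.1f} on {vc.n_obs} observed values")

imputed = impute_panel(panel, vc, phi)
hidden = panel.mask[1]
mse = np.mean((imputed.values[1, hidden] - truth.values[1, hidden]) ** 2)
print(f"imputed {hidden.sum()} hidden post-treatment values, MSE = {mse:.3f}")
```

Output:

```
h2(pre) = 0.59   h2(post) = 0.65
phenotypic correlation = 0.891
log-likelihood = -1227.0 on 1244 observed values
imputed 116 hidden post-treatment values, MSE = 0.192
```

The fitted heritabilities scatter around the generating value 0.5 (single
replicate), the phenotypic correlation recovers the generating 8/9, and the
masked-entry MSE sits at the theoretical conditional variance
`1 − 0.9² ≈ 0.19` for a visit-correlation-0.9 predictor on unit-variance
phenotypes.

## Command line

```bash
famimpute simulate --families 170 --template nuclear_4 --seed 1 --out study/
famimpute impute --phenotypes study/phenotypes.tsv --fam study/study.fam --out imp/
famimpute assoc --phenotypes imp/phenotypes_imputed.tsv \
                --genotypes study/genotypes.tsv --fam study/study.fam --out assoc/
famimpute evaluate-type1 --families 170 --replicates 50 --n-snps 2000 --out eval/
```

Every run writes a `manifest.json` (version, seed, input hashes) next to
its outputs.  See `famimpute <cmd> --help` for the full flag set and
`docs/methods.md` for the model, parameter meanings, numerical policies
and the simulator's scope.

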