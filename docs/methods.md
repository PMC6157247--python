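# Methods

## The model

`famimpute` treats a pair of quantitative phenotypes measured on `n`
pedigree members — in the motivating design, pre- and post-treatment
log-triglyceride levels — as one stacked vector

    Y = (y_{1,1} ... y_{1,n}, y_{2,1} ... y_{2,n})'   (phenotype-major)

assumed multivariate normal with mean `mu = (mu_1 1_n, mu_2 1_n)` and
covariance decomposed into additive-genetic and environmental parts:

    Sigma = Sigma_A (x) phi  +  Sigma_E (x) I_n ,

where `Sigma_A` and `Sigma_E` are 2×2 covariance matrices of the two
phenotypes, `phi` is the genetic relationship matrix, and `(x)` the
Kronecker product.  Under this model the missing coordinates `Y_m` given the
observed ones `Y_o` are again normal, and each missing entry is replaced by
its conditional expectation

    E(Y_m | Y_o) = mu_m + Sigma_mo Sigma_oo^{-1} (Y_o - mu_o).

The imputed value therefore borrows strength from two directions at once:
the same individual's other phenotype (through the off-diagonals of
`Sigma_A`, `Sigma_E`) and both phenotypes of every relative (through `phi`).
Association on the completed data uses a linear mixed model
`y = 1 b0 + g b + u + e`, `u ~ N(0, tau phi)`, `e ~ N(0, s2 I)`, with a
1-df chi-square score test per SNP.

## phi convention

`phi` is the numerator-relationship matrix: twice the kinship coefficient,
so the diagonal is 1 for non-inbred individuals, parent–offspring pairs are
0.5, half-sibs 0.25, first cousins 0.125.  With this convention `Sigma_A`
is directly the additive-genetic covariance.  Users importing kinship
matrices with diagonal ½ must double them.  The recursion supports
inbreeding (diagonal > 1); the simulator never generates inbred pedigrees.
`empirical_phi` rescales the standardized-genotype cross-product to
correlation form, forcing the diagonal to exactly 1; with few samples the
sample-allele-frequency centering biases off-diagonals by about `-1/(n-1)`,
which is why at least a few hundred samples and variants are recommended.

## Estimation choices

- **ML, not REML.**  The mean is held at the per-phenotype observed means
  and (Sigma_A, Sigma_E) maximize the observed-data likelihood — the MVN
  density of `Y_o` under the corresponding restriction of `Sigma`.  ML with
  a fixed plug-in mean is mildly biased downward in small samples; at the
  package's reference scale (170–200 families) the bias is well inside
  Monte-Carlo noise (checked by the unbiasedness test at 200 families).
- **Missing data enter through the restricted likelihood**, not EM: the
  restriction is exact and keeps the code path identical to the one the
  imputation uses.
- **Parameterization and optimizer.**  Each 2×2 component is written as
  `L L'` with log-transformed Cholesky diagonals, giving an unconstrained
  6-parameter space whose every point is positive definite.  L-BFGS-B with
  numerical gradients runs from a moment start (the complete-pairs sample
  covariance split half genetic / half environmental) plus 5 random
  restarts by default (`n_restarts`); the evaluation drivers use 1–2
  restarts since the moment start is reliably in the right basin at their
  sample sizes.  Convergence: gradient tolerance 1e-6, max 500 iterations.
- **Likelihood factorization.**  Families are the connected components of
  `phi`'s sparsity graph; the observed-data likelihood is the sum of
  per-family MVN densities, evaluated with batched Cholesky factorizations
  (missing entries padded with unit diagonal and zero residual, which
  leaves determinant and quadratic form unchanged).  This is exactly the
  dense computation — verified against `scipy.stats.multivariate_normal`
  to 1e-8 — and is what makes replicated re-fits affordable.
- **phi = I** identifies only `Sigma_A + Sigma_E`; the fit warns and the
  split is arbitrary, but imputation depends only on the total in that
  case.  Likewise the null mixed model pins the variance ratio at
  `tau = 0` when `phi` has no eigenvalue spread, where the ratio is
  unidentified.

## Numerical policies

- `Sigma_oo` is solved by Cholesky factorization, never explicit inversion.
  If the factorization fails, a diagonal jitter of `1e-8 * mean(diag)` is
  added and escalated tenfold at most 3 times before raising an error that
  names the affected individuals.  This matters at 80% missingness, where
  `Sigma_oo` can be poorly conditioned.
- The null-model variance ratio `lambda = tau/s2` is profiled on the
  eigenbasis of `phi` (one O(n^3) decomposition per sample set, O(n) per
  likelihood evaluation thereafter), located on a log-spaced grid over
  [e^-8, e^8] and refined by bounded Brent search; the `lambda -> 0`
  boundary wins ties.
- Score-test p-values are floored at the smallest positive double so that
  `p` lies in (0, 1]; monomorphic SNPs return `p = NaN` with a flag rather
  than raising.
- `apply_missingness` rounds half-up: a 50% fraction of 675 samples masks
  exactly 338 entries.

## The synthetic study and what it does (not) show

The generator emulates the structure of a two-period treatment study on
families; its defaults are the package's reference conditions:

| parameter | default | meaning |
|---|---|---|
| `n_families`, `family_template` | 170, `nuclear_4` | 680 phenotyped samples |
| `heritability` | 0.5 | per-phenotype `h^2` of the latent levels |
| `pheno_correlation_target` | 8/9 | latent pre/post correlation |
| `visit_corr_pre`, `visit_corr_cross` | 0.9, 0.8 | realized visit correlations |
| `missing_fraction` | 117/680 ≈ 0.172 | samples losing both post visits |
| `n_missing_visit1/2` | 4, 1 | early-visit gaps, carry-over filled |
| causal ladder | v = .125/.10/.075/.05/.025, MAF 0.3 | per-SNP variance explained |
| `n_replicates` | 200 | Monte-Carlo replicates |

Latent levels are drawn per family from `Sigma_A (x) phi + Sigma_E (x) I`;
the four-visit mode adds iid visit noise whose variances are solved from
the two visit-correlation targets (infeasible targets raise).  The default
latent correlation 8/9 is exactly the value that makes visit correlations
(0.9, 0.8) attainable with equal per-period noise.  Causal SNPs are
gene-dropped and sized as `beta = sqrt(v V_tot / (2 p (1-p)))` with `V_tot`
the average-difference outcome variance inflated by `1/(1 - sum v)`, so
each SNP's marginal variance explained equals its ladder value.  The
missingness is MCAR at the sample level (both post-treatment visits lost
together).

Deliberate simplifications: no linkage disequilibrium or haplotype
structure, no covariates or population stratification, no informative
missingness, no household environment, MAF fixed at 0.3 for causal SNPs.
Consequently the calibration and ordering results on this surrogate speak
to the method's statistical behaviour under its own assumptions, not to any
particular real cohort; in particular, absolute power at these effect sizes
saturates near 1 at the upper ladder rungs (a variance-explained of 0.125
at n = 680 is a very large effect for a score test), so the power study is
read for its orderings — imputed vs incomplete, average- vs
single-difference, monotonicity in v — rather than its absolute levels.
MSE is reported in the simulation's phenotype variance units (unit variance,
so the unrelated-sample benchmark is `1 - rho^2`).

## Evaluation drivers and problem sizes

`run_type1` pools p-values over replicates (per-replicate rates are kept as
diagnostics; tests within a replicate share a phenotype, so the
replicate-cluster standard error is the honest uncertainty for pooled
rates).  The packaged checks use 50 replicates × 2000 null SNPs (1e5
pooled tests), 200 replicates for power, and 50 replicates × 675 unrelated
samples for the MSE grid; `--replicates` on the CLI scales any of these.
Variance components are re-estimated inside every replicate before
imputation — the pipeline is evaluated end-to-end, estimation error
included.

## Known limitations

- Single deterministic conditional-mean imputation understates downstream
  variance (imputed entries are shrunken linear combinations of observed
  ones); the conditional standard deviation is reported as a diagnostic but
  no Rubin-style correction is applied.  The type-I calibration shows the
  score test remains calibrated under the null at the study's missingness
  levels, but standard errors of *effect estimates* on imputed data are
  optimistic.
- Two phenotypes only; the block algebra generalizes but the code does not.
- No fixed-effect covariates in either the polygenic model or the
  association model.
- The bivariate fit assumes multivariate normality; heavy-tailed phenotypes
  should be transformed first (the motivating application uses log scale).
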