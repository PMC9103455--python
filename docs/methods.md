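# Methods

## Model

Weekly feed intake of animal `i` in week `j = 1..10` follows a degree-2
Legendre random-regression model. Weeks are standardized to
`t_j = −1 + 2(j−1)/9` and the basis uses *normalized* Legendre polynomials
`φ_q(t) = sqrt((2q+1)/2) P_q(t)`, so `Ψ` (10×3) has orthogonal-ish columns
and `φ_0 = sqrt(1/2)` everywhere. The standardization and normalization are
a design choice (any full-rank reparameterization of the basis leaves
`G = Ψ K_a Ψ'` and hence the SBV unchanged); they are recorded in run
metadata.

Fixed effects: week-by-generation (absorbs the overall mean and the time
profile), batch-by-sex, birth herd, pen, and an age-at-test covariate. The
phenotypic regressions of feed intake on metabolic body weight (MBW,
kg^0.75), average daily gain (ADG, kg/d) and backfat thickness (BFT, mm)
are estimated jointly in the mixed-model equations as fixed covariates
(`β₁–β₃`); a config switch (`ModelSpec.fix_betas`) fixes them instead, for
analyses where the regression slopes are treated as known. Identifiability
is imposed by keeping all levels of the first factor and dropping the first
level of each later factor.

Genetic coefficients have covariance `A ⊗ K_a` (pedigree) or `H ⊗ K_a`
(single-step); permanent-environment coefficients `I ⊗ K_b` exist only for
animals with records; residuals are independent with heterogeneous weekly
variances `D_j`. Variance components are treated as *known inputs*
throughout the pipeline; the built-in REML exists for desk-scale recovery
checks only (below). Missing weekly records simply drop out of the
mixed-model equations — imputation happens only in the summarized-phenotype
path.

Henderson's equations are solved by direct sparse LU factorization with a
relative-residual guard of 1e-8; a failed guard reports likely confounded
fixed-effect levels. Model-based accuracies of `L'u_i` come from the
inverse coefficient matrix on the requested genetic blocks,
`acc = sqrt(1 − PEV/(L'GL))`; PEV above the prior variance (possible for
inbred animals, whose prior variance is `(1+F)·L'GL`, or numerical noise)
clamps to accuracy 0 with a warning.

## Eigen-summarization

`G` is eigendecomposed with eigenvalues in descending order; each
eigenvector's sign is fixed so its entry-sum is positive (first nonzero
entry positive on a tie), which makes SBV directions deterministic. The
eigenvectors are computed once from the whole-data `G` and reused for every
partial dataset and for the summarized phenotypes — re-estimating them per
evaluation round is deliberately out of scope. Index heritabilities are
`L'GL / L'(G+P+D)L`.

## LR evaluation design

Cut-off `i` keeps the phenotypes of the first `2+i` generations (cut-1 =
three generations, cut-5 = seven); the pedigree is never reduced. The focal
group of cut `i` is the set of genotyped dams of the first generation
without phenotypes in that partial dataset; sires are excluded because
their phenotyped-progeny counts differ systematically between partial and
whole data, and dams with own phenotypes are excluded by construction.
Statistics are computed separately per line and per SBV index. Comparisons:
(1) next cut as reference (full data for the last cut), (2) full data as
reference for cuts 1–4 (the last cut's full-data reference duplicates
comparison 1, keeping the grid at 108 phenotype-information estimates),
(3) pedigree-only versus single-step predictions from the same dataset,
for each cut (30 estimates) and for the full data. Variances and
covariances use the n−1 denominator. Focal groups smaller than 10 animals
trigger a small-sample warning. The standardized bias divides by the
variance `L'ĜL` (not its square root), as printed in the field's
formulation. The selected-reliability variant `cov(p,w)/σ²_u*` requires a
user-supplied group genetic variance; its estimation (e.g. by Gibbs
sampling) is out of scope. The downstream factor analysis (effects of line,
SBV index and relationship type on the LR statistics) is left to external
tools; the pipeline emits the full per-scenario table plus grouped means.

A note on information monotonicity: the per-cut focal groups sit at a
*stationary* information state (each group is always "dams of the first
unphenotyped generation"), so the accuracy ratio is approximately constant
across cuts by design. Monotone convergence toward the full-data reference
holds for a *fixed* focal group followed across successive cuts, and that
is the property the test suite checks.

## Summarized phenotypes

Records are corrected by the whole-data longitudinal fit (fixed effects,
covariates, trait regressions); an animal's missing weeks are imputed with
the population weekly mean of corrected values (a per-line option exists
and defaults off); each 10-vector is projected on `L_Gl`. The univariate
animal model `y = μ_l + u + e` uses derived components
`σ²_g = L'ĜL` and `σ²_e = L'(P̂+D̂)L`.

When `P + D ∝ I` (which forces `K_b = 0`), rotating the corrected records
by the eigenvectors of `G` decouples the longitudinal system into ten
independent univariate animal models, so the summarized BLUP equals
`L'(longitudinal BLUP)` exactly, for any relationship matrix — the test
suite verifies this to 1e-8. With the default (non-isotropic) components
the agreement is close but not exact: correlations ≥ 0.97 for genotyped
animals at full scale.

The variant that skips pre-correction (records corrected only by the trait
regressions, week-free fixed effects re-estimated in the univariate model)
is provided; it adds estimation noise and lowers the agreement with the
longitudinal SBV, most visibly for the third eigen-index.

## Synthetic study conditions

The generator's defaults are the package's fixed study conditions:

* **Design** — two divergent lines; eight pedigree generations (founders G0
  plus seven progeny generations); per line and generation 6 sires and 18
  dams, one litter of 11 per dam; replacement parents (6 males, 18 females
  per line) are unphenotyped, every other progeny is phenotyped. This
  yields ~2500 phenotyped animals, ~2800 pedigree records and 336 genotyped
  parents — the scale of a real divergent-selection feed-efficiency
  experiment. No genotyped animal has own phenotypes.
* **Selection** — replacement sires are truncation-selected on the *true*
  first summarized breeding value (downward in the low line, upward in the
  high line); dams are sampled one female per litter (within-family
  replacement). True-value truncation is a desk-scale stand-in for
  selection on estimated breeding values; because selection acts on the
  coefficients, they are co-generated with the pedigree so that phenotypes,
  relationships and selection history stay mutually consistent.
* **Variance components** — `K_a` and `K_b` were calibrated analytically so
  the genetic covariance function has eigen-shares ≈ 60/26/14 % and index
  heritabilities ≈ 0.36/0.20/0.15, with weekly residual variances 0.060 to
  0.080 kg² — magnitudes typical of longitudinal RFI in pigs. Trait
  regressions default to β₁ = 0.07 kg/kg^0.75, β₂ = 1.40 kg/kg,
  β₃ = 0.02 kg/mm.
* **Genotypes** — 1200 biallelic SNPs (a down-scaled panel; chip-specific
  LD structure is not emulated), founder allele frequencies uniform on
  [0.05, 0.5], gene dropping thereafter; an unknown parent's gamete draws
  from the founder frequencies.
* **Missingness** — 20 % of animals are eligible and 21 % of their weeks are
  blanked, giving ≈ 4.2 % missing records concentrated in one fifth of the
  animals; a missing record blanks all four weekly traits.
* **Production traits** — MBW/ADG/BFT are simulated as smooth animal-specific
  trajectories plus noise and treated as fixed regressors, not as
  co-modelled response traits; only their scale and smoothness matter for
  the evaluation.
* **Inbreeding** — computed by the tabular method; Mendelian-sampling
  variance uses parental inbreeding, `(1/2 − (F_s+F_d)/4)·K_a`.

What the generator does *not* emulate: real linkage disequilibrium, chip
ascertainment, genotyping error, non-genetic trends, heterogeneous litter
sizes, or the realized selection history of any particular experimental
population. Passing tests therefore demonstrate the internal consistency
and correctness of the estimation machinery under the stated model, not
performance on any real dataset.

## Relationship matrices

`A` by the vectorized tabular method (dense; intended range up to a few
thousand animals), `A⁻¹` by Henderson's rules with inbreeding, the genomic
relationship as `ZZ'/(2Σp(1−p))` with dosages centered by allele
frequencies *computed from the genotyped set itself* (recorded in output
metadata), affine rescaling to match the diagonal and off-diagonal means of
`A22`, blending `Ω_ω = 0.95 Ω* + 0.05 A22` (weight configurable), and the
single-step inverse `H⁻¹ = A⁻¹ + [[0,0],[0, Ω_ω⁻¹ − A22⁻¹]]`. A single
blend weight and no additional scaling factors of the correction block are
used. Large-scale approximations (APY), metafounders and unknown-parent
groups are out of scope.

## Desk-scale REML

`estimate_varcomp` maximizes the restricted likelihood over
Cholesky-parameterized `K_a`, `K_b` and log-`D` for balanced, complete
records with per-week-mean fixed effects, capped at 500 animals. Rotating
animals by the eigenvectors of the relationship matrix renders records
independent across animals, so each likelihood evaluation is a sum of
10-dimensional Gaussian terms and a full fit takes seconds. It exists to
verify that the generator and the likelihood agree (parameter recovery
within replicate noise; null genetic variance recovered); the pipeline
itself always treats components as known, mirroring practice where they
are estimated once and reused.

## Numerical choices and problem sizes

* Sparse LU (`scipy.sparse.linalg.splu`) for all mixed-model solves;
  relative residual tolerance 1e-8.
* Tiny ridge (1e-12) on Cholesky factorizations of possibly singular
  covariance inputs in the *generator* only; the estimation path refuses
  near-singular `K_a`/`K_b` (condition number > 1e12) and suggests an
  explicit ridge instead.
* Eigenvalues of `G` below 1e-10 are treated as zero (rank guard for the
  SBV index).
* The test suite exercises pedigrees up to 50 animals against dense
  oracles, populations of a few hundred animals for stochastic checks, and
  one full-scale run (~2500 phenotyped animals, ~16 000 equations) for the
  headline summarized-vs-longitudinal comparison; `scripts/acceptance.py`
  runs the complete grid (12 random-regression fits) at full scale in a
  few minutes.

## Known limitations

* The dense tabular `A` bounds the pedigree size to desk scale (tens of
  thousands would require a sparse-path rewrite).
* The REML is deliberately restricted (balanced data, week-mean fixed
  effects) and is not a general-purpose variance-component estimator.
* LR statistics on focal groups of ~18 dams per line are noisy; the
  pipeline warns below 10.
* Single-step results depend on the blend weight and frequency choice;
  both are configurable but only the defaults are exercised by the tests.
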