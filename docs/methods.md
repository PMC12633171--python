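# Methods

## Model

`pgifam` studies the behaviour of polygenic indices (PGIs) in
family-based regressions under a fully specified generative model.  Each
individual carries dosages `x ∈ {0,1,2}^m` at `m` unlinked biallelic
SNPs; the phenotype is

    y = x γ + x_p θ + ε,        ε ~ N(0, σ²),

with `x_p` the sum of the two parental dosage vectors.  `γ` are direct
(within-family causal) per-allele effects; `θ` collects every channel by
which parental genotype predicts the offspring phenotype other than
transmission — genetic nurture, and in richer settings stratification
and assortment.  A population regression of `y` on a single SNP has
probability limit `μ_j = γ_j + θ_j` because under random mating
`Cov(x_j, x_p,j) = Var(x_j)`.  All of the package's contrasts —
ψ versus δ, the proportional-bias factor, the heterogeneity ratios —
are exact consequences of this model, which makes the simulator the
ground truth for every downstream estimator.

## Simulator

- **Founders** are drawn under Hardy–Weinberg equilibrium: two
  independent Bernoulli(maf) alleles per SNP, maf ∈ (0, 0.5].
- **Mating** is random by default.  Assortative mating is implemented as
  noisy rank-matching on a mating phenotype: both halves of the founder
  pool are ordered by phenotype plus Gaussian noise whose scale is
  calibrated by bisection until the realized spousal phenotype
  correlation is within about ±0.03 of the requested value (defaults for
  experiments: 0, 0.2, 0.4; a discreteness ceiling triggers a warning
  and the best achievable matching).  The mechanism is a modelling
  choice — what matters downstream is the realized spousal correlation,
  which is reported.
- **Meiosis** transmits one uniformly chosen haplotype per parent per
  SNP, independently across SNPs (no linkage; an optional fixed block
  size makes the haplotype choice constant within blocks as a crude
  segment emulation).  For two-offspring families the per-SNP IBD state
  (0/1/2 shared parental haplotypes) is recorded from the haplotype
  choice identities, so trio genotypes are Mendel-consistent by
  construction and sib-pair IBD is exactly (1/4, 1/2, 1/4) in
  expectation.
- **Phenotypes**: noise is scaled so the *theoretical* random-mating
  share Var(xγ)/Var(y) equals the requested `h2_direct`; an optional
  `parental_share` rescales θ so Var(x_p θ)/Var(y) hits a target.
  Infeasible combinations (total genetic variance above Var(y)) raise.
  Binary phenotypes threshold the liability at the requested prevalence
  (realized mean/sd normal approximation).  A uniform `subgroup_scale`
  multiplies the genetic component in a random half-sample for
  heterogeneity experiments.  The realized variance decomposition is
  attached to the returned table for test use.

What the generator does **not** emulate: linkage disequilibrium,
population structure, genotyping error, phasing, X chromosome,
multi-generation pedigrees, or selection.  Tests passing here therefore
validate the estimators' statistical logic under the model's own
assumptions, not their robustness to real-data artifacts.

## GWAS weights

With unlinked SNPs, per-SNP OLS on an unrelated sample is an unbiased,
noisy estimator of μ — precisely the object whose estimation error the
attenuation parameter ρ summarizes.  LD-aware shrinkage estimators would
add nothing under this generator, so weights are the per-SNP betas times
an optional scalar (a grid search on held-out R² is provided for parity
with shrinkage workflows; a global scalar cannot change standardized
predictions).  Monomorphic SNPs are excluded and reported.

## PGI construction

Scores are weighted allele-count sums after allele alignment (sign flip
when effect/other alleles are swapped; mismatched pairs dropped with a
logged count).  Standardization uses the offspring (analysis) rows by
default and applies the same affine transform to parental scores so
proband and parental PGIs keep their Mendelian relations.  Regression
routines restandardize within the estimation sample by default;
`standardize_pgi=False` supports externally fixed scales — the right
choice when a ratio of coefficients from two samples is the estimand,
since a shared scale removes standardization noise from the ratio (the
delta-method calibration test exercises exactly this).

## Mendelian imputation

For families with missing parents, the parental genotype pair
(g_m, g_f) ∈ {0,1,2}² is enumerated with Hardy–Weinberg priors at the
cohort-estimated (or supplied) allele frequency and multiplied by the
exact transmission likelihood of the observed offspring.  For sibling
pairs the likelihood conditions on the IBD state, averaging over which
parent contributes the shared haplotype when one haplotype is shared;
without IBD information the state is marginalized.  The posterior mean
E[g_m + g_f | data] is exact for the covered designs (trio, one observed
parent + offspring, sibling pair, singleton) because the latent space is
finite.  Sibling data cannot separate maternal from paternal
expectations, so such families receive a single combined parental PGI.
Zero posterior mass (e.g. offspring dosage 2 with an observed
homozygous-reference parent) raises an explicit inconsistency error.
Unphased genotypes only; no genotyping-error model; no
assortative-mating adjustment of imputed parental PGIs (flagged in the
output metadata).

## Estimation

- ψ: OLS (or logistic, reported on the log-odds scale with an
  odds-ratio accessor) of the phenotype on the standardized PGI in a
  sample with no two members of the same family (override available).
- δ: the same regression plus parental-PGI controls.  A family random
  intercept is added whenever families contribute multiple offspring:
  linear mixed model fit by REML (statsmodels MixedLM); binary outcomes
  use a variational-Bayes logistic mixed model, with the method recorded
  in the result.  Single-offspring designs reduce exactly to OLS.
- δ/ψ: delta-method SE `sqrt(SE(δ̂)²/ψ̂² + δ̂² SE(ψ̂)²/ψ̂⁴)`, valid for
  disjoint estimation samples; a warning fires when |ψ̂|/SE(ψ̂) < 5.
- ψ − δ: two-sample z test; Benjamini–Hochberg step-up at 5% FDR across
  phenotypes; inverse-variance-weighted fixed-effect pooling across
  cohorts (single-input pass-through; mixed raw/log-odds scales
  refused).
- A sibling-difference estimator (within-pair phenotype difference on
  PGI difference) is provided as the power benchmark that
  imputed-parent control estimation dominates.

## Heterogeneity

Interaction fits include the full two-way set — PGI×covariates and
subgroup×covariates, plus parental-PGI×PGI and parental-PGI×subgroup
when parental controls are on — with mean-centered covariates and the
phenotype standardized within subgroup (raw-scale fitting is available
for generator-truth checks, where a k-fold effect scaling must return
the raw coefficient ratio k).  The subgroup ratio base/(base+interaction)
gets a delta-method SE from the joint covariance with gradient
(λ, −ψ)/(ψ+λ)²; a denominator within five combined SEs of zero refuses
the delta SE.  Incremental R² compares nested fixed-effect predictions;
confidence intervals resample whole families with replacement,
stratified by subgroup (default 1,000 replicates; percentile 2.5/97.5).
Continuous grouping variables are split at the median with ties to the
lower group.

## Attenuation theory

`expected_r2(h2, n, m)` returns `h2²/(h2 + m/n)` with the effective
number of independent SNPs defaulting to 60,000.  `rho = sqrt(h2/R²)`
carries a delta-method SE that treats R² as a known constant,
`SE(h2)/(2 ρ R²)`; full propagation through R²'s own h² dependence is
available as an alternative.  The proportional-bias factor is
`Corr(xγ, xμ)/ρ` with SE
`sqrt(SE(corr)²/ρ² + corr² SE(ρ)²/ρ⁴)` under independence of the two
estimates.  Coefficient correction divides both the estimate and its SE
by the factor, since OLS SEs attenuate by the same proportion.  The
per-SNP effective sample size `1/(2 SE² MAF(1−MAF))` backs a filter that
drops SNPs strictly below 0.8× the median (the boundary value is
retained; the convention is a package choice).

The worked-example report computes each derived column by plugging in
the previous column at 3-decimal printed precision (half-up): R² is
rounded before ρ, and ρ before the bias factor.  This "as-printed
plug-in" convention is what makes the published accounting internally
consistent; full-precision propagation is available via
`round_columns=None`.  One published row (BMI) is not exactly
reproducible from its own printed inputs — its printed R² implies an
unrounded heritability input slightly above the printed 0.247 — and the
package reports the value implied by the printed inputs (R² = 0.174,
ρ = 1.191) rather than matching the printed 0.175/1.188.

## Problem sizes and numerical conventions

Simulation-based validations use: 20 replicates of 2,000 SNPs / 40,000
GWAS individuals / 4,000 trio families for the attenuation-formula
check; 20 replicates of 400 sib-pair families × 150 SNPs for imputation
consistency; 1,000 small-sample replicates (60 SNPs, 600 + 300
families) for ratio-SE calibration; 6,000 trio families for
heterogeneity recovery.  These sizes put Monte-Carlo error comfortably
inside the 3-SE / 10% acceptance bands while keeping a full run at
desk scale.  Seeds are explicit everywhere and propagate to every
stochastic operation; reruns with the same seed and configuration are
bit-identical (TSV floats written at 10 significant digits).

## Known limitations

- The attenuation formula is derived under random mating; under
  assortative mating the true attenuation is slightly larger than
  predicted (the simulator can generate such data, and the property
  tests check the direction of the deviation).
- Binary-outcome mixed models use a variational approximation; its SEs
  are approximate and flagged by the recorded method name.
- Imputation covers at most two genotyped siblings per family and
  ignores half-sibs and multi-generation information.
- The factor correlation Corr(xγ, xμ) is treated as an input (or
  simulation truth); estimating it from real summary statistics is out
  of scope.
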