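# pgifam

Family-based polygenic-index (PGI) analysis in Python: simulate family
cohorts with direct and parental genetic effects, construct PGIs from
finite-sample GWAS weights, impute parental PGIs from relatives by
Mendelian laws, contrast population associations with within-family
direct effects, analyze subgroup heterogeneity, and correct PGI
coefficients for the two sources of measurement error that attenuate
them.

## Who this is for

Social-science and genetic-epidemiology researchers who run "causal PGI
studies" — regressions of a phenotype on a proband's PGI controlling for
the parents' PGIs — and need (a) a fully synthetic, self-contained
test-bed with known ground truth, and (b) the attenuation arithmetic to
interpret and de-bias their estimates.

## The model

Phenotypes follow the two-generation causal model

    y_i = x_i γ + x_p,i θ + ε_i,

where `x_i` is the proband's vector of effect-allele counts, `x_p,i` the
sum of the parental count vectors, `γ` the direct (within-family causal)
effects and `θ` the parental-genotype effects (genetic nurture plus any
confounding channel).  A population GWAS of `y` on `x` estimates
`μ = γ + θ` per SNP.  Three estimands follow:

- **ψ** (population association): coefficient on the standardized PGI in
  unrelated individuals, no parental controls.
- **δ** (direct effect): coefficient on the proband PGI controlling for
  paternal and maternal PGIs (or their imputed sum); identified by random
  Mendelian segregation.  δ/ψ gets a delta-method SE,
  `SE² = SE(δ̂)²/ψ̂² + δ̂²SE(ψ̂)²/ψ̂⁴`, valid because the two are
  estimated in disjoint samples.
- **Corr(xγ, xμ)/ρ** (proportional bias): with
  `ρ = sqrt(h²_μ / R²) ≥ 1` the errors-in-variables attenuation from
  finite GWAS sample size and `Corr(xγ, xμ) ≤ 1` the divergence of
  associational from causal weights, both the PGI coefficient and every
  PGI-by-environment interaction are attenuated by this single factor
  under random mating — dividing estimates and their SEs by it
  de-attenuates both.  The expected predictive power entering ρ is
  `R² = h⁴/(h² + M/N)` with `M = 60,000` effective independent SNPs.

Parental genotypes missing from a family are imputed as exact posterior
means: all parental genotype pairs are enumerated with Hardy–Weinberg
priors and Mendelian transmission likelihoods given the observed
offspring (conditioning on the sibling IBD state when known).  A sibling
pair identifies only the *sum* of parental genotypes, so such families
get a single combined parental PGI.

## Worked example

```python
from pgifam import sim, gwas, scoring, famfit
from pgifam.data import WeightSet

panel = sim.random_panel(500, seed=7, theta_mode="mixed", theta_scale=0.3)
pop, pop_phen = sim.make_population(panel, 20_000, 0.4, seed=8)
ss = gwas.run_population_gwas(pop, pop_phen, rows=pop.rows("proband"))
weights = gwas.make_weightset(ss)

# psi and delta come from disjoint samples, so the ratio SE needs no
# covariance term
assoc, assoc_phen = sim.make_population(panel, 8_000, 0.4, seed=9)
kids = assoc.subset(assoc.rows("proband"))
psi = famfit.fit_population_association(
    assoc_phen, scoring.compute_pgi(kids, weights)
)
trios, phen = sim.make_trio_cohort(panel, 3_000, 0.4, seed=10)
delta = famfit.fit_causal_effect(phen, scoring.compute_pgi(trios, weights))
ratio = famfit.ratio_with_delta_se(delta, psi)
print(f"psi   = {psi.estimate:.3f} ({psi.se:.3f})")
print(f"delta = {delta.estimate:.3f} ({delta.se:.3f})")
print(f"delta/psi = {ratio.ratio:.3f} ({ratio.se:.3f})")
```

Output:

```
psi   = 1.306 (0.010)
delta = 0.941 (0.021)
delta/psi = 0.720 (0.017)
```

(Raw phenotype scale; the generator sets Var(xγ)/Var(y) = 0.4 with a
parental component θ carrying an additional 30%-scale contribution.)

The population association overstates the direct effect because the
phenotype carries a parental-genotype component (θ ≠ 0 in this
generator) and the GWAS weights are noisy; the ratio quantifies the gap.
The attenuation accounting for published PGIs is available from the CLI:

```bash
pgifam table3
```

which prints, per phenotype, N, h², the expected R², ρ (SE), the
causal–associational factor correlation (SE), and the proportional-bias
factor Corr/ρ (SE) — e.g. 0.781 (0.027) for educational attainment and
0.938 (0.023) for height.

## Layout

- `pgifam.sim` — founders under HWE, assortative or random mating,
  Mendelian transmission with sibling IBD bookkeeping, phenotypes.
- `pgifam.gwas` — per-SNP population GWAS and weight sets.
- `pgifam.scoring` — allele alignment, PGI scoring and standardization,
  causal-vs-associational factor correlation.
- `pgifam.imputation` — exact posterior-mean parental imputation.
- `pgifam.famfit` — ψ, δ, ratio/difference inference, BH-FDR, IVW meta.
- `pgifam.hetero` — PGI-by-subgroup interactions, subgroup ratios,
  incremental R² with family bootstrap.
- `pgifam.atten` — expected R², effective N filter, ρ, bias factor,
  coefficient correction, report rendering.
- `pgifam.pipeline` / `pgifam.cli` — YAML-configured end-to-end runs
  (`pgifam simulate/gwas/pgi/impute/fit/hetero/correct/table3/run`).

See `docs/methods.md` for modeling assumptions, numerical conventions
and known limitations.
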