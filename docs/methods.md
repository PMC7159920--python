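# Methods

## The problem

Heritability, genetic correlation and polygenic-score associations
estimated from samples of nominally unrelated individuals are routinely
read as evidence that genotype causes phenotype.  Three population
phenomena can break that reading:

1. **Population stratification** — subpopulations differ both in allele
   frequencies and in phenotype means, so genotype tags ancestry rather
   than biology.
2. **Dynastic effects (genetic nurture)** — parental genotype shapes the
   rearing environment through the parental phenotype, so offspring
   inherit trait-associated alleles *and* trait-associated environments.
3. **Assortative mating** — spouses pair on phenotype, which induces
   spousal genotypic correlation, gametic-phase disequilibrium, and excess
   genetic variance in offspring.

This package provides a forward simulator that produces cohorts embodying
each mechanism (singly or combined), the estimators these mechanisms
distort, and the diagnostics that reveal them.  Everything is exercisable
without external data.

## Simulation model

**Genotypes.** `m` unlinked biallelic variants.  Ancestral frequencies are
uniform on `maf_range` (default 0.05–0.5).  With `K` subpopulations and
divergence `F`, subpopulation frequencies follow the Balding–Nichols model:
Beta draws with mean `p` and variance `F·p(1−p)`.  Founders are split
evenly across subpopulations with balanced sexes and genotypes drawn
binomially at the subpopulation frequency.

**Effects.** A configurable number of causal variants receive effects on
the standardized-genotype scale, drawn bivariate-normal across the two
study traits with correlation `rg_true` and rescaled so the genetic-value
variance equals the target heritability exactly at the founder generation
under Hardy–Weinberg at the ancestral frequencies.  Non-causal variants
carry exactly zero effect.  The negative-control trait has its own
independent causal set (default h² = 0.3, a moderate biomarker-like
value).

**Phenotypes.** `y = g + shift(subpop) + dynastic + e`.  Residuals of the
two study traits are drawn jointly with correlation `env_corr`.  The
dynastic term, present only for non-founders and only on trait A, is
`κ_m·M_mother + κ_f·M_father` where the mediator `M` is the parental
phenotype (default, as environments are built from expressed phenotypes)
or the parental genetic value (clean genetic-nurture experiments).  The
control trait receives no shift and no dynastic term under any preset.
Phenotypes have unit variance at the founder generation only; later
generations are deliberately left unscaled so that variance inflation
produced by assortment or dynastic transmission remains measurable.

**Mating.** Within generation and within subpopulation, both sexes are
ranked on `y + u` with independent Gaussian noise `u` and rank-matched.
For rank-matched Gaussians the spousal correlation is
`Var(y)/(Var(y)+Var(u))`, which provides the starting value; `Var(u)` is
then calibrated by bisection (noise draws held fixed) until the realized
correlation is within ±0.02 of the target.  A target of 0 produces
uniformly random within-subpopulation pairing.

**Transmission.** Each parent transmits one of its two alleles with
probability ½ independently across variants; the transmitted allele is
recorded per child, parent and variant, so the nontransmitted allele is
always recoverable as `parent dosage − transmitted`.  Offspring inherit
the parental subpopulation; sexes alternate within sibships.

**Randomness.** One `numpy` generator seeded from the configuration
drives every stage in a fixed order (founders, effects, then phenotypes →
pairing → transmission per generation), so a fixed seed yields a
byte-identical cohort.

### Presets

| preset | mechanisms | key values |
|---|---|---|
| `null` | none | h² = 0.6, two generations |
| `bivariate` | none | h² = 0.5/0.5, r_g = 0.7, env corr 0.3 |
| `assortment` | spousal sorting | target spousal r = 0.56, three generations |
| `dynastic` | genetic nurture | κ = 0.3 per parent, h² = 0.4 |
| `stratification` | two subpopulations | F_ST = 0.05, shifts ±0.5 SD, h² = 0.4 |
| `negative_confounding` | opposite-signed shared environment | r_g = 0.8, env corr −0.4 |
| `crp_control` | none (control trait analysed) | control h² = 0.3 |

The spousal target 0.56 matches the magnitude reported for educational
attainment in spousal-correlation studies; dynastic path sizes and
assortment persistence are not identified by any cohort study we know of,
so κ = 0.3 (a moderate path, SD per SD of mediator) is a package choice.

## Estimators

**GRM.** Mean over polymorphic variants of
`(x_ij − 2p_j)(x_ik − 2p_j) / (2p_j(1−p_j))`, frequencies estimated from
the sample unless supplied.  I/O in the GCTA binary triple and a gzipped
text lower triangle.

**REML.** The mixed model `y = Xb + g + e`, `cov(g) = σ²_g·GRM`,
`cov(e) = σ²_e·I`.  With a single GRM, rotating by its eigenvectors
decouples the model into independent 1×1 (univariate) or 2×2 (bivariate)
blocks with covariance `λ_i·G + E`, making every likelihood and
information quantity O(n) after one eigendecomposition.  Fitting runs two
matrix EM-REML warm-up steps (the classic EM update, which in the
univariate case is GCTA's) followed by average-information steps with
step-halving, so the restricted log-likelihood never decreases across
accepted iterations.  Convergence: relative log-likelihood change below
1e−6; at most 100 iterations; non-convergence is reported on the result,
never raised.  Variance components are floored at 1e−6 of the phenotypic
variance and fits at the floor carry a boundary flag; a GRM with constant
eigenvalues (e.g. the identity) raises a non-identifiability error because
σ²_g and σ²_e cannot be separated.  SEs of h², r_g and the components come
from the inverse average-information matrix by the delta method.
Missing phenotypes/covariates are handled complete-case per analysis (for
the bivariate model, complete on both traits).  Phenotypes are typically
inverse-normal transformed first (Blom offset: normal quantile of
`(rank − 3/8)/(n + 1/4)`, ties sharing mean ranks).

**Haseman–Elston regression** (independent moment check): the slope of
standardized-phenotype cross-products on GRM off-diagonals estimates h²;
a symmetrized cross-trait version estimates the co-heritability.

**Bivariate heritability.** `h²_AB = r_g·√(h²_A·h²_B) / r_p`, the share
of the phenotypic correlation attributable to genetics.  Values above 1
are legal (the numerator is not nested in the denominator) and diagnostic:
they indicate inflated genetic inputs or a suppressed phenotypic
correlation.  Its SE is Monte-Carlo: 10⁶ independent normal draws per
input (point estimate, SE), the statistic evaluated per draw, SE = SD of
the draws.  Negative heritability draws are truncated at zero; draws with
|r_p| < 1e−3 are rejected and the rejected fraction reported; all-zero SEs
short-circuit to exactly 0.  Because the inputs are drawn independently,
the SE is conservative when the inputs are positively correlated, as they
are when estimated from shared data.  The verdict thresholds are 0 and 2
on `(h²_AB − 1)/SE`, and verdicts are phrased as indicators of possible
bias, never causal conclusions.  `r_p` is computed on
covariate-residualized (and, in the pipeline, inverse-normal transformed)
traits; a switch is not needed in the simulator setting because the
residualization basis is explicit at every call site.

**Polygenic scores.** Weighted effect-allele counts over a retained set:
p < 5e−8 by default, then clumping — the smallest-p variant per 250-kb
window is kept and neighbours with r² > 0.1 removed.  Weight alleles are
harmonized against the dosage coding (sign flip for swapped alleles;
strand-ambiguous A/T and C/G variants dropped).  Scores are standardized
to unit SD in the scoring sample.  Nontransmitted scores use the same
retained set over the recorded nontransmitted parental alleles.  For real
(unphased) data nontransmitted alleles are only resolvable where a parent
is homozygous; this package's supported path is the simulator's explicit
transmission record.

**Trio analysis.** Child phenotype regressed on the child score alone, on
each parental score alone, and on all three jointly.  Attenuation is
`100·(b_ind − b_adj)/b_ind` with the independent-model coefficient as
denominator; its SE comes from bootstrap resampling of whole trios
(families, not individuals, because parental and child rows are
dependent), replicates with |b_ind| < 1e−8 dropped and counted.  The
difference between the two child coefficients is tested by stacking both
models' estimating equations with a robust joint (sandwich) covariance —
a seemingly-unrelated-regression Wald test — with a paired-bootstrap
p-value as a cross-check mode.  Both dynastic effects and assortative
mating produce conditional parental coefficients; the signature does not
distinguish them.

## Diagnostics

- Spousal correlations (phenotype and score) with normal-theory SE
  `√((1−r²)/(n−2))`.
- Heritability before/after PC adjustment; attenuation indicates
  stratification (re-adjusting with an already-included PC set is a
  no-op).
- Heritability conditioning on parental phenotypes, which strips dynastic
  and assortment pathways jointly; treated directionally, since the
  magnitude depends on unobserved real-data effect sizes.
- The full battery run on the negative-control trait must read null;
  a non-null verdict flags the harness itself.

## What the simulator does not emulate

Unlinked variants (no LD beyond what assortment itself induces), no
recombination map, mutation, selection, genotyping error, imputation
uncertainty, or X chromosome; discrete subpopulations rather than
continuous spatial structure; no school-like shared-environment
clustering.  Passing tests therefore demonstrate the estimators' behaviour
under the modelled mechanisms, not robustness to LD-architecture
misspecification or geography.

## Problem sizes and numerical choices

Parameter-recovery checks run 50 replicates at n = 2000 individuals and
m = 2000 variants; detection-calibration checks run 200 null and 25
power replicates at 1000 trios with m = 800.  Bootstrap and Monte-Carlo
defaults are 1000 replications and 10⁶ draws (the `paper` profile); the
`test` profile scales them to 200 and 10⁵.  The GRM accumulates in float32
(relative error ~1e−6, negligible against sampling noise) and REML runs
in float64.  Ties in clumping are broken by position; spouse-pair ranking
ties are impossible almost surely with continuous phenotypes.
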