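# Methods

This note documents the statistical models implemented in `hybridgp`, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the limitations a user should
keep in mind.

## Trial model, variance components and heritability

Multi-environment replicated hybrid phenotypes follow

    y_ijk = mu + g_i + e_j + (ge)_ij + r_k(j) + eps_ijk

with hybrid effect g_i and hybrid-by-environment interaction (ge)_ij
random, environment e_j and replicate-within-environment r_k(j) fixed, and
i.i.d. residuals. For balanced tables (every hybrid in every
environment × replicate cell) the components are solved in closed form
from expected mean squares:

    E[MS_G]  = s2_e + r·s2_ge + e·r·s2_g        df = g − 1
    E[MS_GE] = s2_e + r·s2_ge                   df = (g − 1)(e − 1)
    E[MS_R]  = s2_e                             df = e(g − 1)(r − 1)

where the residual stratum removes cell means and replicate-within-
environment means. Negative solutions are truncated at zero, which is
standard practice and keeps heritability well defined. The closed form
doubles as the exact oracle for the test suite. Unbalanced tables go
through a direct restricted-maximum-likelihood fit of the same model
(Nelder–Mead over the two log variance ratios with the residual variance
profiled out); it is O(n³) per evaluation and intended for tables of a few
thousand records.

The residual variance is modeled as homogeneous across environments. A
heterogeneous-error variant (a separate s2_e per environment) is a known
deviation: field analyses sometimes allow it, and component estimates on
real data can differ accordingly.

Broad-sense heritability is on an entry-mean basis,

    H = s2_g / (s2_g + s2_ge/e + s2_e/(e·r)),

clipped to [0, 1], with e the number of environments and r the number of
replicates actually present in the analyzed table.

## Marker QC conventions

Genotypes are coded −1 (homozygous reference), 0 (heterozygous), +1
(homozygous alternate), NaN missing. Minor-allele frequency counts two
allele copies per homozygote and one of each per heterozygote, over
non-missing calls only. Filtering keeps markers with MAF ≥ 0.05 **and**
missing rate ≤ 0.20 by default; both boundaries are inclusive on the
"keep" side, a choice that has to be made explicitly because thresholds
are usually quoted without inclusivity. Filtering runs before imputation.

The imputer is deliberately naive — per-marker modal code, ties resolved
by the marker mean rounded toward zero (so a +1/−1 tie imputes 0). It
stands in for haplotype-aware imputation and is adequate for the
low-missingness panels left after QC; it ignores linkage entirely.

Mean marker density per chromosome is reported as the integer-truncated
mean (total // chromosomes), matching the usual way such densities are
quoted.

## Hybrid design matrices

For a cross between parents with codes f, m ∈ {−1, +1} at a marker, the F1
is deterministic: K_A = (f + m)/2 ∈ {−1, 0, +1} and K_D = |f − m|/2 ∈
{0, 1}, i.e. K_D = 1 exactly where the hybrid is heterozygous. Swapping
parents changes nothing (no parent-of-origin effects). Residually
heterozygous parents (code 0) are handled by policy: the default
`expected` policy uses expected gamete contributions, giving fractional
entries (±0.5 in K_A, 0.5 in K_D); `strict` rejects them and is the right
choice when the inbred assumption must hold. Columns always follow the
genotype matrix so effect vectors stay aligned across modules.

## Relatedness and structure

The VanRaden genomic relationship matrix uses dosages M ∈ {0,1,2},
Z = M − 2p and G = ZZ′ / 2Σpₖ(1−pₖ), with allele frequencies p estimated
from the analyzed panel itself (no external reference population is
assumed). The co-ancestry distance is implemented as one minus the mean
proportion of alleles identical by state per marker — with ±1/0 codes
this is 1 − |x−y|/2 averaged over markers — because "coefficient of
co-ancestry from SNPs" does not pin down a unique estimator; IBS sharing
is the simplest defensible reading and is documented as such. PCA is the
SVD of the column-centered (unscaled) code matrix, the default of
general-purpose PCA routines; percent variance explained is the squared
singular value over the total and scores are defined up to sign.

## RR-BLUP

The additive-only ("partial") model y = 1μ + K_A a + ε with
a ~ N(0, σ²ₐI) is fit as the equivalent GBLUP with kernel G = K_A K_A′.
The REML estimate of λ = σ²_ε/σ²ₐ comes from a single eigendecomposition
of the intercept-projected kernel S(G+I)S (the one null eigenvalue of the
projection is dropped), followed by bounded scalar minimization of the
restricted likelihood over log λ ∈ [−20, 20] with tolerance 1e−8. Marker
effects are then recovered in closed form,

    a_hat = K_A′ (G + λI)⁻¹ (y − 1·mu_hat),

with mu_hat the generalized-least-squares intercept. This is numerically
identical (to ~1e−8; verified on randomized instances) to both the direct
penalized normal equations (K_A′K_A + λI)⁻¹K_A′(y − 1μ) and the kernel
form G(G+λI)⁻¹(y − 1μ).

The full model adds the dominance kernel G_D = K_D K_D′. The two variance
ratios (γₐ, γ_d) = (σ²ₐ, σ²_d)/σ²_ε are found by Nelder–Mead on the
profiled restricted likelihood, starting from (0.5, 0.5) with tolerance
1e−6; both effect vectors are back-solved from the fitted covariance. A
K_D that is identically zero (no segregating heterozygosity) falls back
to the partial model with a warning. Variance estimates are floored at
1e−9 of the phenotypic variance so λ stays finite when a component
collapses.

Environments enter prediction only through pre-averaging phenotypes into
per-hybrid entry means; the intercept is the sole fixed effect. Fitting
environment terms jointly with marker effects is a possible alternative
the package does not implement.

## Cross-validation and accuracy

Prediction accuracy is r(ĝ, g) = Pearson correlation between observed and
predicted values on the validation set, divided by √H. H is estimated
once per trait from the full phenotype table (not per fold): the
standardization is meant to express accuracy on the genetic scale of the
trait across environments, which is a property of the trait, not of a
fold. An explicit `heritability=` override exists for tables that cannot
support the trial model (e.g. a deliberately pure-noise trait).

Five-fold CV partitions hybrids into five random subsets (sizes differing
by at most one; 204 hybrids give 41/41/41/41/40), each fold serving once
as validation set, re-randomized every iteration; each fold × iteration is
one replicate and the reported mean is the exact mean of replicate-level
correlations (fold-level correlation first, then averaging — pooling
predictions before correlating is the other defensible convention and
gives slightly different numbers). TP-size CV draws a simple random
training population of fixed size per iteration. All fold and TP draws
are simple random subsets without replacement, and the entire stream is
determined by the scheme seed plus a stable per-trait key, so runs are
bit-reproducible.

Structured relatedness splits use the tester-group layout:

- **common-male**: hold out every hybrid of one female tester as
  validation; train on the other testers' hybrids. Both sides then share
  pollinator (male) parents but no females. The default held-out tester is
  the one whose group size is closest to the mean group size — on the
  77/59/68 reference design this selects the 68-hybrid group, giving the
  136/68 split.
- **common-female**: choose a pollinator subset (seeded greedy draw over
  the per-male hybrid counts) whose hybrids across all testers total the
  target training size; train on those, validate on the rest. Both sides
  share the female testers but no males. The default target is the largest
  tester-group size, which on the reference design yields 77/127.

The exact construction of such splits is under-specified in the field's
reporting conventions; this tester-group interpretation is validated by
reproducing the published split sizes, not by any stronger claim.

Percent accuracy gain across a TP-size series is 100·(last − first)/first
rounded half-away-from-zero to an integer, matching how such gains are
quoted.

## Synthetic-data generator

The generator emulates the structural features the analysis relies on:

- fully homozygous parental lines (codes ±1) — residual heterozygosity is
  not simulated, matching the inbred-parent assumption of the design
  matrices;
- subpopulation structure via round-robin assignment of lines to
  subpopulations, each drawing its own per-marker allele frequency
  uniformly from `allele_freq_range` (default (0.1, 0.9), 3
  subpopulations);
- the testcross mating design: a seeded shuffle picks the shared
  pollinator core present in every tester group; remaining slots fill
  round-robin so every pollinator is used when slot counts allow.
  `SimConfig.reference_design()` reproduces the study shape — 99
  pollinators × 3 testers, groups 77/59/68, 44 shared — and the desk-scale
  default (60 pollinators, groups 25/20/22, 10 shared, 2,000 markers on 10
  chromosomes) keeps tests fast; the full 66k-marker scale is reachable by
  config;
- genetic architecture: `n_qtl` markers drawn without replacement carry
  mean-zero Gaussian additive and dominance effects, rescaled so the
  realized variances of K_A·a and K_D·d among the designed hybrids equal
  `var_additive` and `var_dominance` exactly in-sample — this makes
  heritability targets testable at small n, at the cost that effect sizes
  are no longer strictly i.i.d.;
- phenotypes from the trial model above: environment and
  replicate-within-environment shifts drawn once per simulation (scales
  `env_effect_sd` = 1.0, `rep_effect_sd` = 0.5), hybrid × environment
  deviations i.i.d. with variance `var_gxe`, residuals i.i.d. with
  variance `var_residual`. Default variances (additive 1.0, dominance 0.3,
  G×E 0.5, residual 1.0 over 4 environments × 3 replicates) give an
  entry-mean heritability around 0.85 — a moderately-to-highly heritable
  trait; the published study reports no additive/dominance split, so these
  are free simulation parameters, not estimates of any real trait.

Not emulated: linkage disequilibrium and recombination maps (markers are
independent given subpopulation frequencies), selection or drift,
epistasis, structured G×E correlation, and unbalanced or spatially
trended field data. Passing tests therefore demonstrate correctness of
the estimators and the qualitative behavior of prediction accuracy under
the assumed architecture — not performance on real sorghum data, where LD
between markers and QTL, relatedness gradients and G×E structure drive
accuracy.

All randomness flows from one config seed through named per-stage streams
(parents / design / effects / phenotypes), so every artifact is
bit-reproducible and stages can be regenerated independently.

## Problem sizes used by the test and acceptance runs

The suites run at desk scale, chosen so the full test suite finishes in
well under a minute of compute per heavy module: panels of 300–600 markers
with 50–100 QTL on the 204-hybrid reference design for prediction checks;
~500 hybrids × 4 environments × 3 replicates × 20 seeds for
variance-component recovery (targets 10/4/7, mean estimates within 20%);
100 randomized 20 × 50 instances for solver equivalence at 1e−8; 100
iterations for the TP-size accuracy series; 10 paired seeds for the
full-vs-partial dominance comparison. These sizes are large enough that
every Monte-Carlo tolerance used in the tests (±0.05 on heritability,
0.02 on accuracy monotonicity, 5% on the null dominance ratio) holds with
comfortable margin under the stated seeds.

## Known limitations

- The homogeneous-error REML path is dense O(n³) and not suited to tens of
  thousands of records.
- The naive imputer ignores linkage; heavily missing data should be
  imputed with a haplotype-aware tool before entering the pipeline.
- The co-ancestry distance is an IBS estimator, not a pedigree-based
  kinship; its scale is not comparable to VanRaden coefficients.
- No G×E-aware prediction, multi-trait models, Bayesian marker priors, or
  GCA/SCA decompositions; single intercept, no additional fixed
  covariates in the prediction models.
- Three-way crosses and cytoplasmic-sterility bookkeeping are out of
  scope; the mating design is strictly female tester × male pollinator.
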