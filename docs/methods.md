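# Methods

`pedlod` implements family-based linkage mapping and statistical
fine-mapping of a quantitative trait: variance-components LOD scanning on
extended pedigrees, pedigree-specific LOD decomposition, linked-family
subsetting, kinship-adjusted association under the peak, per-variant and
joint conditional-LOD analysis, and a gene-dropping simulator that
generates data with exactly the statistical structure the estimators
assume.  This note records the models, the defaults and why, the numerical
choices, and what the simulator does and does not emulate.

## Variance-components linkage model

Within each family the adjusted trait vector is modelled as multivariate
normal,

    y ~ N( X b ,  s2_q * Pi_c  +  s2_a * 2 Phi  +  s2_e * I ),

where `Phi` is the pedigree kinship matrix, `Pi_c` the matrix of expected
proportions of alleles shared identical-by-descent (IBD) at map position
`c`, and (s2_q, s2_a, s2_e) the locus-specific, additive-polygenic and
residual variance components.  The likelihood factorizes over families.
The LOD score at `c` is

    LOD(c) = [ loglik(full at c) - loglik(polygenic null) ] / ln 10 ,

floored at zero because the null (s2_q = 0) lies on the boundary of the
parameter space; under the null, 2 ln10 LOD asymptotically follows the
half-and-half mixture  0.5 chi2_0 + 0.5 chi2_1.  A peak is declared
significant at LOD >= 3 and the fine-mapping window is the 1-LOD support
interval around it.

Estimation is maximum likelihood (not REML) so that full and null
log-likelihoods are directly comparable as a likelihood ratio; the cost is
a small downward bias in the absolute variance estimates, which does not
affect LOD differences.  Fixed effects are profiled out by generalized
least squares at every trial point, and the optimizer (bounded L-BFGS-B
with the analytic gradient of the profiled likelihood) runs from three
documented start points plus one randomized start under the caller's seed.
The variances are optimized on their natural scale with a zero lower
bound rather than on a log scale: the boundary value s2_q = 0 is then
exactly representable, and the polygenic-null solution is always included
among the candidate starts, which guarantees loglik(full) >= loglik(null)
and hence LOD >= 0 by construction.  Convergence tolerance is 1e-10 on the
objective; non-positive-definite trial covariances return a large penalty
so the optimizer retreats.  Reported heritability is
h2 = s2_a / (s2_a + s2_q + s2_e).

Pedigree-specific LODs are each family's log-likelihood contribution
evaluated at the *global* full and null optima (no per-family refit), so
they sum exactly to the total LOD; this additivity is what makes
"ranked pedigree LODs summing to a threshold" well defined.  No
household/shared-environment component and no dominance component are
modelled.

## Multipoint IBD

Two interchangeable sources feed `Pi_c`:

* **Inheritance-vector HMM (Lander-Green).**  A pedigree with `m = 2 x
  non-founders` meioses has `2^m` equally likely inheritance vectors a
  priori.  Marker emissions sum over all founder-allele assignments with
  alleles i.i.d. Bernoulli(allele frequency); transitions between map
  positions flip each meiosis bit independently with the Haldane
  recombination fraction  theta = (1 - exp(-2d/100)) / 2  for distance `d`
  cM (no interference, matching the simulator).  The forward-backward
  posterior gives E[pi_ij] at any grid position; with no genotype data the
  posterior equals the prior and pi = 2 phi exactly.  The transition
  operator is applied as `m` axis-wise mixes in O(m 2^m) rather than as a
  dense `2^m x 2^m` product.  Pedigrees above the bit limit (default 16
  meioses) or with more than 20 founder-allele slots raise a capability
  error directing the caller to truth-IBD mode.
* **Simulator-truth IBD.**  Exact sharing computed from the simulator's
  inheritance labels, available for any pedigree size.  This replaces the
  MCMC samplers used on large real pedigrees; the downstream linkage
  machinery is agnostic to which source produced `Pi`.

Marker thinning keeps at most 5 variants per half-open 0.5 cM window,
ranked by founder heterozygosity 2p(1-p) as the informativeness proxy (the
source analyses say only "tightly linked" markers; heterozygosity is the
natural single-marker criterion).

## Phenotype adjustment and association

The raw trait (seconds to completion of a timed test) is log-transformed
and residualized by OLS on age, age squared, sex, field center, education
and 10 genetic PCs; categorical covariates expand to indicators and
collinear columns are dropped with a warning.  Sensitivity covariates
(e.g. a correlated second test score or an APOE allele dosage) enter
through the same mechanism.  The two-stage design (residualize, then
model) mirrors common practice in family studies; the association model
still carries the kinship random effect, so family structure is not
double-counted.

Association of a residualized trait with a variant dosage uses

    y = b0 + b * dosage + a + e ,   a ~ N(0, s2_a * 2 Phi),

with variances by ML, `b` and its standard error from the profiled GLS at
the optimum, and a two-sided Wald P — the convention of the `lmekin`-style
mixed models this engine replaces.  When the analysis subset contains no
related pairs the mixed model degenerates to ordinary least squares and
the implementation computes exact OLS (t-based) inference instead.
Missing dosages are mean-imputed within the analysis subset to preserve
sample size in small family subsets (logged).  eQTL- and mQTL-style
analyses are the same engine applied to externally adjusted molecular
residual vectors.

## Fine-mapping logic

At the scan peak, families with pedigree-specific LOD > 0.1 form the
*linked* set; ranking families by LOD and taking the shortest prefix whose
LODs sum to >= 6 gives the *top-linked* set (ties broken by family id; if
the total never reaches 6, all positive-LOD families are returned with a
flag).  Pedigree LODs are read at the single peak grid position.

Association is run per family subset over the support interval.  Variants
reaching P < 1e-4 in at least one subset get a conditional LOD in both
subsets: the dosage is appended to the fixed effects of *both* the full
and the null model and the peak LOD re-estimated; the drop is
lod_pre - lod_post.  A variant is nominated when (1) P < 1e-4 in at least
one subset, (2) P < 0.05 in both, and (3) the drop exceeds 0.5 in both.
These fixed thresholds are applied without genome-wide correction,
matching the source design; the report records every threshold used.
Because the scan is evaluated on a discrete grid, the reported support
interval is the grid run with LOD >= peak - 1, while the association
window brackets it by one grid step on each side: the true 1-LOD crossing
lies between the last in-run grid point and its neighbour, and a sharp
peak would otherwise leave a window containing no variants.

Stepwise selection ("enter" P < 0.1, "stay" P < 0.05) runs as classical
forward-with-backward-elimination on ordinary regression of the globally
adjusted residuals within each subset — the variables enter singly, and
the final joint conditional LOD restores the variance-components model
with all selected dosages as covariates.  Percent of peak explained is
100 (lod_pre - lod_post) / lod_pre evaluated at the peak position; other
published per-variant percentages are not exactly reproducible from
printed drop/peak ratios, so this package defines the ratio above and uses
it consistently.  An empty selection is an explicit no-op (lod_post =
lod_pre, 0%).

## Synthetic data generator

The generator emulates a multigenerational family study of a timed
cognitive trait at its published scale: by default 76 three-generation
families — a grandparent couple, 4-6 adult children each with a married-in
spouse, and 2-4 grandchildren per couple — for roughly 2100 phenotyped
individuals, matching the ~2115-participant cohort the design targets.
Sibship sizes were fixed by a design-time power calculation: with the
default 15%-of-variance planted QTL this structure yields mean peak LODs
near 4.5, i.e. a typically detectable peak, which is the regime the
fine-mapping stage is meant to exercise.

Founder haplotypes are drawn in linkage equilibrium from per-variant
allele frequencies uniform on [0.05, 0.5]; an optional block-LD mode makes
variants within a block copy the block anchor with a configurable
probability `c` (dosage correlation ~ c, so c = 0.75 gives r2 ~ 0.56, the
moderate-LD regime of linked variant pairs).  Meioses place crossovers as
a Poisson process at 1 per Morgan (Haldane, no interference), matching the
HMM transition model, and every allele carries a founder-haplotype label
from which exact IBD is computed.

The trait is built on the log-seconds scale as

    y = mean + covariate effects + sum_v beta_v (dosage_v - 2 p_v)
        + a + e ,

with the polygenic `a` drawn per family from N(0, s2_a * 2 Phi) — i.e.
directly from the model the estimator assumes, making parameter recovery a
clean test — and `e` independent normal.  Defaults: total genetic +
environmental variance 0.25 on the log scale (log-SD 0.5, the dispersion
of a timed test with mean ~96 s and SD ~56 s), polygenic fraction
h2 = 0.29 (the published heritability estimate), mean log-seconds 4.5
(~90 s).  A planted QTL is specified by map position and variance
fraction; its per-allele effect is beta = -sqrt(frac * s2 / (2p(1-p)))
(negative = protective by default).  Covariates are age uniform by
generation (grandparents 75-95, parents 50-75, grandchildren 25-50), sex
from the pedigree, one field center per family (four centers at realistic
proportions), a college-education indicator at 85%, and 10 standard-normal
dummy PCs; their effects exercise the adjustment machinery without
claiming realism.  Both `trait_seconds = exp(y)` and `trait_log` are
emitted.

What the simulator does **not** emulate: realistic LD from reference
panels, ascertainment through long-lived probands, non-normal trait
tails, genotyping error, and molecular (expression/lipid) traits beyond
generic residual vectors.  Passing tests therefore demonstrate
correctness of the estimators under their own assumptions — not
robustness to the ways real cohort data violate them.

## Numerical and edge-case choices

* Variant QC: call rate >= 0.90 and exact Hardy-Weinberg P >= 1e-6, with
  the HWE exact test computed on founders only (pedigree structure
  violates the random-mating assumption and would inflate the test);
  monomorphic variants have HWE P = 1 and are kept unless a MAF floor is
  set.  Depth- or quality-based QC is out of scope (the data model carries
  dosages, not reads).
* Genetic-map interpolation is linear between anchors and clamps beyond
  the ends; region queries use 1-based inclusive bounds, the VCF
  convention.
* IBD matrices and kinship are stored as per-family blocks (they are
  exactly zero between families), and likelihood evaluations batch
  equal-sized families through stacked Cholesky factorizations.
* Identifiability guards: a polygenic fit with no related pairs raises an
  "unidentifiable" error; an uninformative locus (Pi = 2 Phi) collapses
  the full model onto the null, and the returned log-likelihoods agree to
  optimizer tolerance.
* Determinism: every stochastic step derives its generator from the
  configuration seed; a seeded simulate-mode pipeline run writes
  byte-identical reports, and stepwise/nomination tie-breaks are by
  variant or family id.

## Problem sizes used by the test suite

The suite runs the full pipeline at the default study scale (76 families,
~2100 individuals, 100 cM, 300 variants, 2 cM scan grid), the null LOD
calibration on 500 replicates of 50 eight-member pedigrees, heritability
recovery on 20 replicates of 100 ten-member families, and the exact-oracle
IBD comparisons on nuclear and 12-member pedigrees.  These sizes are the
package's chosen desk-scale study conditions; the published analyses they
mirror used access-restricted cohort data at comparable cohort size but
with much deeper pedigrees.

## Known limitations

* Variance-components linkage has limited power at desk scale: at the
  default conditions (15%-variance QTL, ~2100 individuals) the scan
  clears the LOD >= 3 gate in roughly three quarters of seeded
  replicates, so end-to-end recovery of the causal variant is bounded by
  detection, not by the fine-mapping logic (the recovery test in the
  suite reports the exact rate).
* Absolute variance components are ML (slightly biased downward); only
  likelihood differences are calibrated.
* Heterogeneity LODs (admixture mixtures over linked/unlinked families)
  are not modelled; family subsetting plays that role here.
* The exact HMM is exponential in pedigree size by design; large
  pedigrees must use truth-IBD (simulation) or an external IBD source.
* Stepwise selection inherits the classical caveats of forward-backward
  regression (greedy, P-value-based); it is used because it is the
  procedure the workflow specifies, not because it is optimal.
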