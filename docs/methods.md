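# Methods

`betameth` implements the statistical chain by which a binary prenatal
exposure — antenatal betamethasone (BET), a synthetic glucocorticoid given
for fetal lung maturation — is linked to placental DNA methylation and
downstream gene expression. This note documents each stage's model and
assumptions, the parameters that matter, what the built-in synthetic
cohort does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Genotype QC and ancestry axes

Variants carry additive alternate-allele dosages in {0, 1, 2}. Three
independent per-variant filters are applied (defaults in parentheses):
call rate (≥ 0.98), minor allele frequency (≥ 0.01), and an exact
Hardy–Weinberg equilibrium test (p > 1e-6). The HWE test uses the
conditional Levene–Haldane distribution of the heterozygote count given
the allele counts; the two-sided p-value sums the probabilities of all
configurations no more probable than the observed one. Probabilities are
computed in log space with a relative tie tolerance of 1e-12, and the test
is exact for any sample size (verified against rational-arithmetic
enumeration up to n = 200 in the tests).

LD pruning is greedy within a sliding window (200 variants, step 100,
r² threshold 0.2): while any kept pair within the window exceeds the
threshold, the member with the lower MAF is removed (ties drop the later
variant). The removal rule is a convention, not a canon; it matches common
practice and is fully deterministic.

Ancestry covariates are the leading axes of a classical (Torgerson)
multidimensional scaling of the identity-by-state distance
`d(i,j) = mean over variants of |dose_i − dose_j| / 2`, computed on the
pruned variants with per-variant mean imputation of missing calls
(imputation is used for the distance only, never in association models,
where samples missing the focal genotype are dropped). Whether the
distance behind such MDS axes should be IBS or a genome-wide IBD estimate
is ambiguous in common pipelines; IBS is implemented because it is
well-defined without relatedness estimation, which is out of scope (inputs
are assumed unrelated, pre-filtered upstream). The default of four axes
follows the convention of adjusting for the main axes of genetic
variation.

## Methylation preprocessing

Methylation is modelled on the beta scale (fraction methylated in [0, 1])
throughout; an M-value transform is available but off by default, matching
the practice of fitting linear models directly to betas. Probe filters:

* detection filter — a CpG is dropped when its detection p exceeds 0.01 in
  at least 25% of samples. The boundary is read inclusively ("at least"),
  a deliberate choice where either convention is defensible; at 136
  samples the distinction affects only CpGs failing in exactly 34.
* blacklist / sex chromosomes — explicit probe ids (SNP-containing,
  cross-hybridising) plus chrX/chrY probes are removed.

Batch adjustment is location-only: each batch's per-CpG mean is shifted
onto the global mean, with results clipped to [0, 1] and clipping counted.
This is a documented simplification of empirical-Bayes batch removal — it
handles additive batch shifts (the dominant slide effect in array data)
but not batch-specific scale differences, and it will slightly under-adjust
CpGs whose batch effect interacts with biology.

Cell-type composition enters as the leading principal components of the
sample-by-cell-type proportion matrix (six placental cell types), taking
the smallest number of components whose cumulative explained variance
reaches 70% — typically two for Dirichlet-like proportion data.

## EWAS

For each CpG, ordinary least squares of beta values on exposure plus
covariates (child sex, gestational age, four ancestry axes, maternal age,
smoking, two cell-type PCs; a sensitivity preset adds delivery mode, labor
and parity). The exposure coefficient is a beta-scale difference; the
two-sided p comes from the t distribution with residual degrees of
freedom, exactly reproducing `summary(lm(...))` conventions. Complete-case
analysis per CpG; CpGs with zero residual variance report a missing p with
a flag rather than failing.

The scan is vectorised: CpGs sharing a missingness pattern are solved in a
single factorisation, which makes a 5000-CpG × 136-sample scan essentially
instantaneous and exactly equal (to 1e-12) to per-CpG fits. Multiplicity
is handled with Benjamini–Hochberg step-up q-values over all tested CpGs
(via statsmodels, cross-checked against a literal step-up implementation),
plus an epigenome-wide significance flag at p < 9e-8, the conventional
EPIC-array threshold.

## Fine-mapping panel models

A targeted CpG panel (e.g. 106 amplicon CpGs around a focal locus, grouped
by annotation into intron/enhancer regions) is analysed with four models
per CpG, all sharing the EWAS covariates plus sequencing plate as a
categorical covariate:

1. exposure main effect;
2. SNP main effect, additive 0/1/2 dosage (a dominant recode contrasting
   alt-homozygotes is available);
3. nested comparison — extra-sum-of-squares F test of adding exposure to
   the genotype-only model, F = ((RSS₀−RSS₁)/1)/(RSS₁/df₁); the identity
   F = t² of the added coefficient is asserted on every call;
4. genotype × exposure interaction with main effects retained; sparse
   genotype-by-exposure cells trigger a warning with counts, since the
   rare-homozygote-by-exposed cell is typically tiny.

FDR is controlled across the whole panel ("over all investigated sites"),
one p-value column at a time. The direction-consistency statistic reports,
for k of n effects sharing a direction, both the fair-coin point
probability P(X = k) and the upper tail P(X ≥ k): published analyses are
ambiguous about which convention a printed value follows (for 8 of 10 the
point probability is 45/1024 ≈ 0.044 and the tail 56/1024 ≈ 0.055), so
both are always returned and none chosen silently.

## Expression and eQTM

Genes are kept when they show at least 10 raw counts in at least 90% of
samples (both boundaries inclusive). Normalisation is median-of-ratios
size factors (geometric-mean reference over genes expressed everywhere,
library-size fallback otherwise) followed by log2(count/sf + 1) — a
variance-stabilising stand-in chosen for transparency; any externally
produced transformed matrix can be substituted, since downstream stages
only require a numeric gene-by-sample frame.

The eQTM statistic is the Pearson correlation between one CpG's betas and
one gene's transformed expression, with the two-sided t-transform p
(n − 2 df). With covariates supplied, both variables are residualised and
the partial correlation is reported alongside (p with n − 2 − k df;
cross-checked against an independent partial-correlation implementation).
Pearson rather than a rank correlation is the default because the
correlation is interpreted on the measurement scales; Spearman can be
obtained by ranking the inputs. A median split (values ≤ median labelled
LOW) is provided for the boxplot convention; n is always reported next to
r because a correlation without its sample size is uninterpretable.

## Co-expression modules

Unsigned weighted network: adjacency |r|^β over gene pairs, with the soft
power β selected as the smallest power whose scale-free fit R² (log₁₀
frequency vs log₁₀ binned connectivity) reaches 0.8 with a negative slope,
*sustained at the next power in the grid* — the R² is estimated from ~10
binned points, and requiring two consecutive qualifying powers guards
against a single bin-noise crossing selecting a degenerately low power.
If no power qualifies, the best-R² power is used with a warning. Unsigned
adjacency is the historical default; a signed option exists.

The topological overlap matrix combines direct adjacency and shared
neighbourhood; modules are average-linkage clusters of 1 − TOM under a
static tree cut at 0.99 of the merge-height *range* (not of the absolute
maximum height, which becomes meaningless when high powers compress all
TOM values towards zero). Clusters below 30 genes are relabelled "grey"
(unassigned); surviving modules get size-ranked colour names, so the
largest module is deterministically "turquoise". A static cut is a
deliberate simplification of dynamic tree cutting: it is auditable and
fully deterministic, at the cost of occasionally splitting or absorbing
weakly separated modules — which is why module recovery is validated on
planted synthetic structure rather than by module counts.

Each module is summarised by its eigengene — the first right-singular
vector of the standardised member-expression matrix, sign-oriented to
correlate positively with the mean member profile — with the variance
explained reported. Module–trait association is the Pearson correlation
of the eigengene with a sample-level trait (e.g. focal-CpG methylation).

## Overlap and enrichment

The permutation overlap test draws B (default 1000) signature-sized gene
subsets uniformly without replacement from the expressed-gene universe and
counts permuted overlaps at least as large as the observed one (ties count
as extreme — the conservative choice). The empirical p is the add-one
estimator (b + 1)/(B + 1), never zero; a result above every permutation
yields exactly 1/1001 at the default B. Hypergeometric enrichment uses
the upper tail P(X ≥ k) with the universe as population, each gene set
restricted to the universe, and the module as the draw; BH-FDR across
sets; the reported ratio is overlap/set-size. The universe is always
explicit — enrichment against an unstated background is not supported.

## The synthetic cohort

The generator provides every input layer with the statistical structure
the analysis assumes, so each stage is testable without restricted cohort
data. Defaults (all in `SimConfig`):

* 52 exposed / 84 control methylation-cohort samples with sex, gestational
  age (weeks), maternal age, smoking, delivery covariates, plate and slide
  labels; Dirichlet cell-type proportions over six placental cell types.
* 5000 array CpGs plus a 106-CpG targeted panel with intron/enhancer
  region labels. Betas are generated on the logit scale: per-CpG baseline
  (a hyper/hypo/intermediate methylation mixture; the focal CpG at 0.952),
  additive covariate, batch, exposure and genotype effects, Gaussian noise
  (sd 0.35 logit units, giving realistic beta-scale noise of ~0.02 at
  highly methylated CpGs), inverse-logit back-transform — betas are
  therefore strictly inside (0, 1) by construction.
* Effect calibration: exposure (−0.027) and per-allele SNP (+0.02) effects
  are specified on the beta scale; the logit shift realising each target
  under the noise distribution is solved with 41-node Gauss–Hermite
  quadrature, so the simulated group mean difference matches the
  configured value without any post-hoc adjustment (the Monte-Carlo
  recovery tests confirm the mean estimate lands within 0.005).
* Genotypes: ~300 independent background SNPs in Hardy–Weinberg
  proportions (MAF uniform on 0.05–0.5, 0.5% missingness) plus a fully
  typed focal SNP at MAF 0.30 — a common-variant default chosen in the
  absence of a stated frequency.
* Expression cohort: 494 samples (≈2.4% exposed) with negative-binomial
  counts (dispersion 0.2) whose log-means carry planted low-rank module
  factors (default five modules of 150/120/100/80/60 genes among 2000).
  Factor 1 is tied to the focal CpG's beta-scale methylation with the
  configured correlation (−0.33), using noise orthogonalised against the
  anchor so the factor's sample correlation equals the target exactly;
  realised module-level correlations then vary only through count noise.
  Per-gene factor loadings are derived analytically from the target
  gene–factor correlation and the log-scale NB noise variance
  (trigamma(1/dispersion) plus the Poisson term), which places the focal
  gene's methylation correlation at −0.28 through the single path
  gene ← factor ← methylation.
* A 323-gene external signature sharing exactly 60 genes with the largest
  planted module, with signed per-gene effects for concordance counting,
  and a small GMT collection in which two sets are enriched in that module.
* Module sizes are kept well below the chance-overlap regime: with a
  2000-gene universe the expected null overlap of a 323-gene signature
  with a 150-gene module is ≈24, so the planted overlap of 60 genuinely
  exceeds its permutation null — the structure the overlap test assumes.

One PCG64 generator seeded from `SimConfig.seed` drives every layer in a
fixed order; a fixed seed reproduces the bundle bit-identically, including
written files. `simulate_null` zeroes all planted exposure/genotype/
methylation-coupling effects while keeping the module structure, giving
exact null calibration material (EWAS type-I error 5%, uniform interaction
p-values).

What the generator does **not** emulate: array intensity artefacts and
normalisation residue, probe cross-hybridisation, bisulfite conversion
error, LD between background SNPs, population stratification (available
separately via `simulate_two_population_genotypes` for MDS checks),
count-depth heterogeneity beyond size factors, and correlated
cell-type–methylation confounding beyond a single planted axis. Passing
tests therefore demonstrate correctness of the statistical machinery on
data satisfying its assumptions, not robustness to the full messiness of
real placental data.

## Problem sizes used in the checks

The automated checks run the EWAS null calibration at the full 5000 CpGs ×
136 samples, effect recovery over 50 seeds at n = 136, correlation
recovery at n = 494 with the default 2000-gene expression layer, module
recovery over 20 seeds at the default module sizes, and interaction
calibration over 200 seeds with a trimmed expression layer (the
interaction model never touches expression). These sizes were chosen as
the smallest that leave the Monte-Carlo error comfortably inside each
check's tolerance.

## Known limitations

* Location-only batch adjustment (above).
* Static tree cut; no module merging by eigengene similarity, no
  block-wise computation for very large gene sets (> ~20k genes).
* The LD-pruning removal rule and the inclusive detection-filter boundary
  are conventions; both are logged so a run documents its own choices.
* Surrogate variables, reference-based cell deconvolution and
  empirical-Bayes batch correction are accepted as externally supplied
  covariates/inputs rather than estimated here.
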