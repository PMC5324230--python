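# Methods

## Data model

The central object is the beta-value matrix: per CpG probe and sample,
β = methylated intensity / (methylated + unmethylated), a proportion in
[0, 1]. Detection p-values quantify, per probe and sample, the
probability that the signal is indistinguishable from background.
Probe annotations carry gene symbols, a genic-region label (TSS1500,
TSS200, 5'UTR, 1stExon, Body, 3'UTR, intergenic), the CpG-island
relation (Island, N/S Shore, N/S Shelf, OpenSea) and a SNP flag. The
sample sheet carries group (case/control), age, BMI, batch, estimated
cell-type proportions (inputs here — deconvolution is upstream), the
eight RAND-36 category scores in [0, 100], and ME/CFS onset type.
All interchange is TSV with probes as rows and samples as columns;
missing betas are encoded `NA` and such probes are dropped at read time
with a logged count (our convention; significance testing assumes
complete rows).

## Probe filtering

Probes are removed sequentially (each counted once, under the first
rule that hits):

1. detection p > 0.01 in any sample (the fraction of failing samples
   tolerated is configurable; any-sample is the default, matching the
   platform's usual QC reading that a *large* detection p flags an
   unreliable probe);
2. SNP-flagged probes (polymorphisms at the interrogated CpG or
   single-base extension confound the methylation signal);
3. invariant probes, cross-sample mean β ≥ 0.95 or ≤ 0.05, bounds
   inclusive.

Filtering is idempotent, and the report reconciles every input probe.

## Batch and covariate adjustment

Parametric empirical-Bayes location/scale adjustment (the canonical
ComBat formulation), applied directly to beta-values: per probe, fit
an OLS model with batch indicators plus protected covariates
(intercept, group, age, BMI, cell proportions minus one — proportions
are compositional and would otherwise be collinear with the
intercept); standardize; estimate per-batch additive (γ) and
multiplicative (δ²) effects; shrink them across probes toward a normal
location prior and inverse-gamma scale prior with method-of-moments
hyperparameters, iterating the posterior updates to a relative
tolerance of 1e-4; remove the shrunken effects and restore the
covariate fit. Output is clipped into [1e-6, 1 − 1e-6]. Group is
included in the protected design so real case-control signal survives
adjustment. A one-batch input is returned unchanged. The
implementation agrees with Bioconductor `sva::ComBat` to ~1e-15 on a
shared fixture (tested via Rscript).

## Differential methylation

Per probe, Δβ = mean(case) − mean(control); hypermethylated means
Δβ > 0. Two-sided Wilcoxon rank-sum p (exact enumeration when
n₁ + n₂ ≤ 12 with no ties; otherwise normal approximation with midrank
tie correction and continuity correction), BH step-up q over all
retained probes of the comparison. A site is a DMS when |Δβ| ≥ 0.05,
p ≤ 0.05 and q ≤ 0.05; the subgroup comparisons drop the q gate (the
assay strata are far smaller, and confirmation shifts to the
permutation test). Context enrichment crosses direction (hyper/hypo)
with island-relation or genic-region categories: global Pearson χ²
(no continuity correction), then pairwise 2×2 tests of each category
against a reference (Island), BH-adjusted, plus the S Shelf vs S Shore
contrast.

## Permutation null

For a two-group comparison, the group assignment is reshuffled and the
mean beta-difference of every probe recomputed under each shuffle —
one shared shuffle stream for all probes, preserving inter-probe
correlation under the null. The approximate p per probe is the
proportion of null draws with |null Δβ| ≥ |observed Δβ| (equality
counts; a constant probe gets p = 1). Default 10,000 shuffles drawn
uniformly with replacement over label orderings; an exhaustive mode
enumerates all C(n, n₁) distinct assignments (feasible ≤ 1e5) and is
the oracle the sampled mode converges to. Sidedness is two-sided on
the absolute difference since both directions are findings of
interest. The literal-proportion estimator can return 0; an
`add_one` option gives (k+1)/(n+1) for strictly positive p.
Concordance between nominal and permutation calls is the fraction of
probes with |Δβ| ≥ 0.05 and nominal p ≤ 0.05 that also reach
permutation p ≤ 0.05 (NA when nothing is nominally significant).

## Glucocorticoid-sensitivity stratification

inhibition% = (stimulated − suppressed)/stimulated × 100 on triplicate
means; triplicates with a coefficient of variation above 0.2 are
logged. Case stratification formalizes a visually bimodal inhibition
distribution as a two-component univariate Gaussian mixture (EM, 10
restarts, tolerance 1e-8); the higher-mean component is
GC-Hypersensitive, maximum-posterior assignment, posterior ties toward
Typical. A degenerate fit (a component holding less than 2/n weight,
or spread-free data) falls back to a fixed threshold at the midpoint
of the component means, with a warning; a user-supplied fixed
threshold is also available for reproducing hand-drawn splits.
Between-group inhibition tests are two-tailed Welch t-tests (the
equal-variance assumption is not defensible across strata of different
size and biology); subgroup-vs-onset association uses logistic
regression, and inhibition-vs-RAND-36 associations use Pearson
correlations per category and against PC1.

GC-sensitivity-associated loci come from the three-comparison set
logic: per comparison the significant set requires |Δβ| ≥ 0.05,
nominal p ≤ 0.05 and permutation p ≤ 0.05; the GC set is
(Hypersensitive-vs-Typical ∩ Hypersensitive-vs-Control) minus
Typical-vs-Control. Both this exclusive set (default) and the
inclusive variant that keeps the triple overlap are emitted, since
either reading of the published Venn structure is defensible. The
"magnitude vs pooled reference" of a locus is the Hypersensitive mean
β minus the unweighted average of the Typical and Control means, in
percentage points — the only reference definition consistent with all
three published top-loci values.

## Quality of life

PCA is computed on the correlation scale (each RAND-36 category
z-scored: the categories share a 0–100 range but differ widely in
variance). PC1's sign is fixed so General Health loads positively —
higher PC1 = better self-reported health. Regions are (gene symbol,
genic region) groups with ≥ 2 member probes each at |Δβ| ≥ 0.05;
multi-gene probes contribute to each listed gene, and only qualifying
probes are members. Region methylation per sample is the unweighted
mean of member betas (the simplest summary consistent with a
minimum-2-sites rule), regressed on PC1 by OLS across the pooled
cohort; R² is the squared correlation and BH-FDR runs across all
emitted regions. A group-adjusted variant is deliberately not the
default: the cohort's quality-of-life separation *is* part of the
signal being examined.

## Synthetic data

The generator emulates the study's structure, not its raw chemistry
(no two-channel intensities, Infinium I/II bias, or genetic effects on
hybridization). Effects are additive on the logit scale and mapped
back by the inverse logit, keeping betas strictly inside (0, 1); for a
planted case-control difference δ the group means are set to
logit(β₀ ± δ/2), so the beta-scale gap is δ by construction.

Defaults mirror the study dimensions: 49 cases / 25 controls, an assay
subset of 33 cases / 24 controls with a 14/19 hypersensitive/typical
split, 2 batches (logit offset 0.5), 5,000 probes in the standard
configurations, 3% of probes carrying case-control effects with
magnitudes uniform in [0.05, 0.17] and 71.6% hypermethylated (exact
count in the truth table), 13 hypersensitive-specific loci at
|δ| = 0.12, 10% invariant probes, 5% SNP-flagged probes, and a 0.2%
detection-failure rate. Half of the planted case-control effects land
as probe pairs sharing a gene/genic-region block, reflecting the local
correlation of methylation that makes region-level analysis possible.
Within-group dispersion is logit-scale SD 0.15 (≈ 0.02–0.04 on the
beta scale at mid-range), matching typical per-probe variability on
this platform. RAND-36 scores are drawn per category from the
published cohort means with SD = SE·√n at the reference cohort sizes,
truncated to [0, 100] (truncation slightly biases the most extreme
category means). Assay plates draw a target inhibition per subject
from its stratum mode — controls 40 ± 5, typical 45 ± 5,
hypersensitive 85 ± 3 (inhibition %) — and back out the suppressed OD
from a stimulated OD of 1.6 ± 0.15 with 3% replicate CV. Truth tables
record every planted effect, SNP/invariant probe and true subgroup
label, so downstream sensitivity and specificity are directly
scorable. Fixing the seed fixes every emitted byte.

What passing tests on this generator do *not* show: robustness to
probe-type chemistry bias, cell-composition estimation error,
non-Gaussian assay noise, or annotation errors — all are assumed away
by construction.

## Numerical and design choices

- Wilcoxon switches to the exact distribution only for untied pooled
  samples of ≤ 12 observations; all study-scale comparisons use the
  tie-corrected normal approximation.
- Permutation "equal or more extreme" uses a 1e-12 absolute tolerance
  so dot-product summation order cannot drop exact equalities.
- BH is computed once per comparison over all retained probes, never
  per category or chromosome.
- χ² tests are Pearson (no Yates correction), configurable.
- Top-k report tables break |Δβ| ties by probe id.
- Detection-rule direction: a probe fails QC when detection p > 0.01;
  the fraction-of-samples threshold is configurable (default: any).
- Sub-problem sizes in the test and acceptance suites (600–5,000
  probes, 200–10,000 permutations) are chosen as the smallest scales
  at which every planted-recovery property is stable across seeds.

## Known limitations

- The region-level R² against PC1 on fully synthetic cohorts runs high
  relative to real data: planted regions separate the groups and the
  simulated RAND-36 separation is strong, so region methylation and
  PC1 share the group axis almost deterministically.
- The permutation/nominal concordance on the default synthetic design
  is near 100% — the planted effects are cleanly exchangeable — where
  heterogeneous real cohorts sit lower.
- Calling operates on beta-values throughout (as the upstream
  normalization convention dictates); an M-value testing mode is not
  offered.
- The logistic regression of subgroup on onset type is unpenalized and
  reports NA under complete separation rather than switching to exact
  methods.
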