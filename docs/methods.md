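# Methods

This note documents the statistical model behind `bopscan`, its parameter
defaults, the synthetic cohort the tests run on, and the numerical choices
that were genuinely open.

## Probe classes and blocks of probes

Every array probe is assigned one of four classes by two binary attributes:
CpG-island relation (island/shore/shelf vs open sea) and gene annotation
(genic vs intergenic). Class A = CpG-rich genic, B = CpG-rich intergenic,
C = open-sea genic, D = open-sea intergenic. The partition is total: each
probe gets exactly one label.

Class A/B probes are grouped into blocks of probes (BOPs): all probes in the
same island, the same shore, or the same shelf, keyed additionally by gene
for Class A. Design choices here:

* an empty island-relation cell in the manifest means open sea (the standard
  manifest dialect leaves the cell blank);
* a probe annotated to *k* genes joins *k* Class A blocks, one per gene
  (configurable to "first gene only"). Per-gene keying preserves per-gene
  interpretability of region calls at the cost of counting such probes more
  than once across blocks;
* north and south shores (and shelves) of one island are distinct blocks —
  they are separated by the island and not spatially contiguous;
* coordinates are 1-based inclusive (manifest convention); BED exports
  convert to 0-based half-open; chromosome labels are normalised by stripping
  any `chr` prefix; gene matching is exact string match after
  upper-casing/trimming, with no alias resolution.

## Quality control

Two filters run in a fixed order on the beta / detection-p matrix pair.
Sample filter: drop a sample iff *strictly more than* 75% of its probes have
detection p > 1e-5. Probe filter, sequential so per-rule counts are
disjoint: (1) detection p > 0.05 in strictly more than 75% of samples;
(2) any missing beta; (3) sex-chromosome location. "More than" is strict
inequality at both levels. No normalisation is applied — the pipeline starts
from background-subtracted beta values, and the QC'd matrix is guaranteed
complete (no missing entries) and in [0, 1].

## Leukocyte deconvolution

Whole blood is a mixture of cell types with distinct methylomes, and the
proband group's composition differs systematically from relatives (notably
fewer CD19+ B and CD3+CD4+ T cells, more CD3+CD8+ T cells), so composition is
a confounder for any case/control methylation contrast. The deconvolution
step is a constrained projection onto sorted-cell reference profiles:

1. *Site selection.* CpGs are ranked by the one-way across-cell-type ANOVA F
   statistic in the reference; the top n = 500 are used. Ties break
   lexicographically on CpG id so selection is deterministic. The
   informativeness criterion is a documented stand-in for the reference
   method's unpublished ranking; it is pluggable.
2. *Projection.* With S the per-cell-type mean matrix over selected sites and
   y a target sample's betas, solve min‖y − Sx‖² s.t. x ≥ 0 (NNLS), then
   normalise to the simplex. Both raw and normalised solutions are reported;
   the raw solution recovers a noiseless single-type target to machine
   precision. Within-type reference variance is not propagated.
3. *Covariates.* Five of the six estimated fractions enter the design
   (granulocytes, the largest compartment, is dropped) to avoid the exact
   sum-to-one collinearity of all six with the intercept.

Sites missing from the target matrix are dropped with a warning and counted —
mirroring the real situation where a reference chip's top sites are only
partially present on the target platform.

## Differential methylation testing

The design matrix has intercept, group indicator (proband vs sibling; mothers
never enter this contrast), dummy-coded sex and batch, and the five cell
fractions. The group term is always tested by comparing the full model with
the model without the group column (a type-II style partial test, invariant
to covariate order; with a single-df group term this coincides with type
III).

*Region level.* For each block with ≥ 3 QC-surviving probes, a width-3,
step-1 window slides along the probes in genomic order. Each window is a
3-variate response Y regressed on the design; the group effect is tested with
Pillai's trace V = tr(H(H+E)⁻¹) and the standard F approximation (Wilks'
lambda with Rao's F is available by option; with a 1-df hypothesis all
classical MANOVA statistics give the identical F). The block's statistic is
the *minimum* window p, carried to BH without within-block multiplicity
correction. This is anti-conservative for blocks with many windows — it is
the procedure's definition, documented rather than "fixed"; calibration
claims in the tests therefore use single-window (3-probe) blocks, where the
minimum is the sole window p and exactly uniform under the null.

*Site level.* Class C/D probes get a per-probe partial F test in the linear
model beta ~ group + covariates, vectorised across probes. With no
covariates this is algebraically the pooled-variance two-sample t-test
(F = t²), which the tests assert to 1e-10.

Betas are analysed on the original [0, 1] scale by default; an M-value
(logit₂) option exists. Reported effect sizes (deltas) are always raw
group-mean beta differences, because they are interpretable as methylation
fractions. Degenerate fits — constant probes, singular residual
cross-products (condition number > 1e10) — return p = 1 with a flag instead
of aborting a genome-wide scan.

*FDR.* Benjamini-Hochberg step-up with enforced monotonicity, applied
separately within each probe class (the four classes are separate analyses
with very different test counts and signal densities). Under a global null
the probability that BH at q = 0.05 makes *any* discovery is ≈ 5% per cohort
(the Simes identity for independent uniform p-values), so over 20 null
cohorts the zero-discovery count is Binomial(20, ≈0.95) — the calibration
check's 19/20 expectation sits exactly at the mean, and individual seed sets
can legitimately score 18.

*Chromosome-level distributions.* Per chromosome, all (probe, sample) betas
of each group are pooled and groups are compared pairwise with the two-sample
KS test; raw p-values are Bonferroni-multiplied by the number of
chromosome × comparison tests (capped at 1). The 100-bin equal-width
histograms are attached for reporting and plotting only — the test runs on
the pooled values themselves, not on binned counts, since binning can only
lose information.

## Signature selection and downstream summaries

A block enters the stringent signature iff q < 0.05 and it contains at least
one run of ≥ 2 genomically consecutive probes, each with |Δβ| > 0.15 *with
the same sign*. The absolute-value-plus-sign-consistency reading was an open
choice: a region whose adjacent probes move in opposite directions is not a
coherent DMR, so sign consistency is required by default (it can be switched
off). "Adjacent" means consecutive among the block's QC-surviving probes,
not distance-bounded. Lowering the delta threshold can only grow the
selection (tested as a monotonicity property).

Each selected block is represented by its most significant probe, using
*site-level* p-values for the block's probes (the alternative — membership in
the best window — is less granular); ties break to the smaller genomic
position. Enrichment units are blocks for Classes A/B and probes for C/D.
Fisher tests are two-tailed; the reported odds ratio is the sample OR
(a·d)/(b·c) (infinite when b·c = 0 with a·d > 0), while the p-value comes
from the exact conditional test. Gene-set collections are user-supplied GMT
files; no pathway database is bundled, since database-version-dependent
results are out of scope.

The per-family case-minus-sib difference matrix cancels any additive effect
shared by both members of a family — this is the analytical payoff of the
trio design, and the tests assert exact (1e-12) invariance to per-family
shifts. Ordination uses classical (Torgerson) MDS via double-centering
eigendecomposition, which reproduces exactly 2-dimensional configurations to
1e-8; axis signs are fixed by making the first non-zero loading positive.
Clustering is average-linkage on Euclidean distance with input rows sorted by
label for deterministic tie behaviour; dendrograms export as Newick with
merge heights as node depths.

## Synthetic cohort generator

The generator emulates the study conditions end to end: 29 families, each
contributing a proband (DSP), an unaffected sibling (DSS) and a mother (DSM);
proband sex split 18M/11F and sibling 7M/22F; families assigned round-robin
to 2 batches. Signal means compose additively:

    mu = clip(base + family + sex + batch + planted group delta
              + composition-driven effects, 1e-6, 1 − 1e-6)

* base level by island relation (islands low, shores intermediate, open sea
  high — the canonical bimodal methylome);
* family effect: a shared N(0, 0.02) shift per (probe, family) — exactly the
  nuisance the trio design is meant to cancel, and the tests verify that the
  pair-difference matrix does cancel it;
* sex and batch effects N(0, 0.01) per probe;
* planted effects: a chosen number of Class A island blocks get a fixed delta
  (default scenarios: 20 blocks at Δβ = 0.2) added to proband samples;
* composition: per-sample true cell proportions are Dirichlet with
  concentration 200 around group-specific means (probands: B 0.04 vs 0.07,
  CD4 0.11 vs 0.15, CD8 0.14 vs 0.08). Reference-site rows are S·x mixtures
  of the sorted-cell profiles; optionally a fraction of Class C probes get
  per-cell-type loadings so that composition differences confound unadjusted
  tests (the confounding scenario uses loading sd 0.4 on half the Class C
  probes and a stronger composition shift, sized by a power calculation so
  the composition-driven effect is unambiguous at n = 29 + 29);
* observation noise is Beta-distributed around mu with precision 100
  (mean-preserving, respects the [0, 1] support without clipping artifacts;
  sd ≈ 0.05 at mu = 0.5, ≈ 0.03 at mu = 0.1). `noise_precision=None` gives
  noiseless output for exactness tests.

Randomness uses spawned seed substreams — one per effect layer and one per
sample for observation noise — so output is bit-reproducible under a fixed
seed and individual layers can be switched off without perturbing the others.
Detection p-values are tiny by default with configurable random failures,
engineered always-failing probes, and injectable missing betas to exercise
every QC rule. The ground truth (planted blocks and probes, true proportions,
assignments) serialises to JSON alongside every cohort.

What the generator does *not* emulate: probe-type chemistry differences,
SNP-under-probe artifacts, spatial correlation beyond block membership,
age effects, and realistic genome-wide probe density. Passing tests
therefore demonstrate the statistical machinery's calibration, recovery and
confounding control under the modelled data-generating process — not
performance on raw array data.

## Problem sizes

Desk-scale defaults keep every stage fast: cohorts of ~2–6 thousand probes ×
87 samples, 500–900 region blocks per scan, 500-site deconvolution on a
2000-CpG reference, and a 10,000-draw permutation oracle. The full test
suite runs in well under a minute of compute for the statistical checks; the
acceptance script completes in ~10 seconds.

## Known limitations

* The minimum-window-p summary is anti-conservative for long blocks (see
  above); block-level q-values are comparable only within a class and a
  fixed block-length mix.
* The MANOVA assumes independent samples; sibling pairs sharing a family
  effect make the independent-samples test mildly conservative. The null
  calibration therefore zeroes the family effect — it is a property of the
  design, not of the statistic.
* Deconvolution accuracy degrades if the reference's informative sites are
  absent from the target platform or if target composition lies outside the
  simplex spanned by the reference types (NNLS then projects onto the
  boundary).
* Fisher enrichment treats blocks as exchangeable units; block length and
  probe density are not modelled as covariates.
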