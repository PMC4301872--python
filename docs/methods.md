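# Methods

This note records the modeling choices behind `sigscore`: what each stage
assumes, which parameters matter, what the synthetic data do and do not
emulate, and where the design was genuinely open.

## Data model and conventions

All expression values are log2(sample/reference) ratios from two-color
arrays; readers never re-log. Missing cells (NaN) are legal everywhere, and
every mean and correlation is computed pairwise-complete. Features observed
in fewer than 70% of arrays are dropped at read time (`min_present_fraction`
in `read_expression`); the original spot-quality filters applied upstream of
public deposits are not reproducible, so a missingness filter stands in.
Cohort merging inner-joins features — only probes present on every platform
survive, mirroring how multi-platform compendia are restricted to the common
probe set. Probe→gene collapsing averages all of a gene's probes per array,
and is applied to both the compendium and the signature before any
Entrez-space correlation.

## Signature derivation

Membership requires the cross-replicate *mean* log2FC to pass the 2-fold
gate at both 12 h and 24 h. The wording "mean change … across all
replicates" admits a stricter per-replicate reading; that is available as
`per_replicate=True`, but the mean-based reading is the default because the
averaging clause governs the sentence. The idealized induction pattern spans
all eight columns — 0 at the three baselines, 1 at 2–24 h — and the pattern
correlation is computed per replicate, then averaged, to match an "average
correlation > 0.8" rule. For repressed genes the pattern is negated.
Centroids are in log2 fold-change space, directly comparable to the
compendium's log2 ratios. A 2-fold gate on the linear scale is exactly
|log2FC| ≥ 1. Genes passing the gate in opposite directions at 12 h and
24 h are excluded and logged. Imported signatures (externally defined gene
lists, e.g. an in-vivo drug response derived by a p-value cutoff) bypass
both gates and default to ±1 weights.

## Batch adjustment (parametric ComBat)

The model is the standard location/scale empirical-Bayes adjustment without
covariates: per-gene standardization against the size-weighted grand mean
and the pooled residual variance (denominator N, the sva convention),
per-batch location γ̂ and scale δ̂² estimates, normal and inverse-gamma
hyperpriors moment-matched across genes, and coordinate iteration of the
posterior means to a 1e-4 relative tolerance (cap 100 iterations). The
parametric prior is the only variant implemented: it is closed-form
testable, and it is the canonical setting of the GenePattern module. No
biological covariates enter the design; protection of subset structure is
verified downstream by subset-recovery tests rather than modeled.

One degenerate case is defined here rather than inherited: when the
cross-gene spread of δ̂² is (numerically) zero the inverse-gamma moment
match divides by zero. `sigscore` then uses each batch's mean scale
normalized by the size-weighted mean scale across batches, which leaves
scale-homogeneous batches untouched. In that regime the adjustment reduces
exactly to per-batch mean subtraction and is idempotent; outside it the
implementation agrees with the Bioconductor reference implementation to
~1e-4 (verified in the test suite by running `sva::ComBat` through Rscript
on a shared fixture). Zero-variance genes pass through unadjusted with a
warning; a batch with fewer than two arrays is a hard error.

Missing values are handled with per-gene per-batch counts, so genes with
scattered missing spots are adjusted using their observed arrays only; a
gene entirely missing within a batch is a hard error.

## Guided PCA

Samples are centered gene-wise (missing spots imputed at the gene mean,
i.e. zero after centering). The batch indicator is unscaled 0/1. delta is
the variance of sample scores on the first right singular vector of
(batchᵀ·X) divided by the variance on the first right singular vector of X
itself, so δ ∈ (0, 1]; the permutation p-value uses the add-one correction.
The default permutation count is 1000 in the CLI; tests and the acceptance
script use 100–200, which bounds the attainable p at ~0.005–0.01 and is
sufficient for a 0.05 decision. The variance shares of the first two
unguided components are reported alongside for inspection.

## Intrinsic gene selection

The statistic is S_g = W_g/B_g: W_g is the mean within-patient variance
over patients with ≥ 2 arrays, B_g the variance of per-patient mean values
over all patients (single-array patients inform B only). Small S is
intrinsic. The published "intrinsic gene identifier" executable is not
reproduced; the variance-ratio form is this package's reading of
"consistent expression within an individual patient, along with high
variance between patients". Serial biopsies and technical replicates are
both treated as repeat arrays of their patient.

The null permutes the array→patient assignment preserving group sizes;
FDR(t) = 100 · mean over permutations of #{null S ≤ t} / #{observed S ≤ t},
capped at 100. Both targeting modes are supported (an FDR percentage or a
probe count). When an FDR target is unattainable the selection falls back
to the minimum-estimated-FDR threshold (ties resolve to the smaller
selection), and if even that minimum is ≥ 95% — the estimator's way of
saying the scores carry no patient signal — the selection is returned empty
with a warning. This conservative fallback is what makes pure-noise inputs
yield near-empty selections instead of arbitrary large ones.

Because every array of a patient shares a patient-level intercept, *all*
genes carry some patient consistency; the permutation FDR is therefore
estimated against a fully exchangeable null and is conservative (effective
π₀ = 1). This is the standard behavior of permutation FDRs for this class
of statistic.

## Clustering and subset assignment

Distance is 1 − centered Pearson correlation, pairwise-complete, with
average linkage for both arrays and genes (the Cluster 3.0 convention);
genes are median-centered first (exposed as config, default on). The array
tree is cut into k = 5 main clusters by default and clusters smaller than
`min_cluster_size = 8` become *unassigned* — the cut rule behind published
four-subsets-plus-unassigned dendrograms is not stated anywhere, so both
knobs are configuration. (The synthetic-recovery tests use k = 4 with a
small minimum because the planted truth has exactly four subsets.) Clusters
are named by the subset whose marker genes have the highest mean expression
within the cluster, ties broken by margin then lexicographically;
normal-like versus limited separation rides on the presence versus absence
of the lipid-metabolism program markers. Concordance against a prior
labelling reports per-subset retention with whole-percent rounding and a
chi-squared independence test with unassigned arrays excluded (they remain
visible in the full contingency table). Trees export as CDT/GTR/ATR for
Java TreeView.

## Scoring and enrichment

Scores are plain Pearson correlations between centroid and array over the
aligned genes; no Fisher z-transform is applied when averaging r across a
subset, matching the use of simple average correlations. The enrichment
p-value treats r̄ as a correlation over n gene pairs with
t = r̄√((n−2)/(1−r̄²)); n is the number of signature genes *present in the
compendium* (the overlap count), because the alignable set is what the
correlation actually uses — the alternative (pre-alignment size) reading is
noted here and is a one-line change. Within-array gene-wise centering
before scoring is off by default: both sides are already log-ratio scaled.

## Clinical associations

Array selection implements the study design: general comparisons restrict
to diffuse SSc, one array per patient per time point, lesional preferred,
technical replicates collapsed by first array_id; biopsy-site comparisons
require both sites at one time point and keep both arrays. Early disease is
duration ≤ 2 years. Continuous covariates use Pearson correlation with a
two-sided t-based p; categorical covariates use one-way ANOVA even with two
levels (so F values remain comparable across covariates; F = t² in the
two-level case and the suite asserts this identity to 1e-9). Raw p-values
are flagged at α = 0.05 with no multiplicity correction, matching the
reporting convention of the analysis this package implements; a
Benjamini–Hochberg column is emitted for reuse but never drives the flags.

## Synthetic data

The compendium generator emulates the structural features the analysis
relies on: three cohorts (batches) with patients nested inside them; four
patient-level subsets with disjoint 50-gene programs, each half induced and
half repressed at a 1.5 log2 effect; patients contributing 1–3 arrays
(probabilities 0.3/0.45/0.25), with a 50% chance that a multi-array SSc
patient contributes a paired lesional/non-lesional biopsy; a patient random
intercept (sd 0.3) so within-patient consistency exceeds between-patient;
additive per-batch gene offsets (sd 0.5) and a mild per-batch noise scale
(log-sd 0.1) on top of spot noise (sd 0.5); and a lesional bonus (+0.5) on
the severity-driving program. Pathway activation is a patient-level latent
(subsets are stable across serial biopsies); MRSS is generated for SSc
samples as 15 + 8·activation + N(0, 4), rounded and clipped at zero, with
the fibroproliferative program standing in for the TGFβ-like severity axis.
The default cohort of 4 × 10 patients (~80 arrays) is a proportionate
scale-down of the real multi-cohort compendium (111 patients, 329 arrays).

The time-course generator plants sustained (up and down), transient
(induced 2–8 h, back to baseline by 12 h) and late-partial (12 h only)
responders with effect sizes drawn from U(1.2, 3) log2 units and Gaussian
noise (sd 0.2 by default), over the 0,0,0,2,4,8,12,24 h design with
triplicate baselines.

What the generators do *not* emulate: raw two-color intensities, dye bias,
spatial artifacts, probe-level annotation noise, correlated gene programs
shared between subsets, missing-data patterns, or longitudinal subset
transitions. Passing recovery tests therefore demonstrate that the
pipeline's logic is correct under the stated generative model, not that the
published cohort-level results are reproduced — those depend on deposited
data this package deliberately does not download.

## Problem sizes and numerical choices

Repeated-seed suites (gPCA clearance over 50 compendia, null calibration
over 100, clustering over 10, clinical nulls over 20) run on reduced
generator settings (150–400 genes, 4–6 patients per subset) chosen so each
suite completes in seconds while keeping per-seed power adequate; the
single-run recovery checks use the full defaults. Permutation counts:
gPCA 100–200 in suites (1000 in the CLI default), intrinsic FDR 25–50 in
suites (100 default). Tolerances: ComBat EB iteration 1e-4 relative;
ComBat-vs-reference agreement 1e-4 absolute; closed-form oracles 1e-6 to
1e-9. Tie-breaks: cluster naming by margin then lexicographic; clinical
replicate collapsing by array_id order. Degenerate inputs (constant arrays,
zero-variance genes, all-missing baselines) are excluded with warnings
rather than propagating NaN.

## Known limitations

* The intrinsic statistic is a variance ratio, not the published
  executable's exact criterion; thresholds tuned on one are not guaranteed
  to transfer to the other.
* Non-parametric ComBat, reference-batch mode and covariate designs are out
  of scope.
* Enrichment p-values inherit the strong independence assumptions of the
  n-gene t approximation; they are comparable across signatures of similar
  size but are not calibrated tail probabilities for correlated gene sets.
* The clinical screen reports raw p-values by design; users re-purposing it
  for larger covariate sets should use the emitted BH column.
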