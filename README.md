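# sigscore

Pathway-signature scoring and intrinsic-subset analysis of systemic
sclerosis (SSc) skin transcriptomes.

Genome-wide expression profiling of SSc skin biopsies stratifies patients
into four reproducible "intrinsic" subsets — fibroproliferative,
inflammatory, limited and normal-like — but the signaling pathways driving
each subset's expression program are not directly observable in biopsy data.
`sigscore` implements the meta-analysis workflow that connects the two: it
derives pathway activation signatures from agonist treatment time courses in
dermal fibroblasts, merges multi-cohort biopsy compendia with batch
adjustment, rediscovers the intrinsic subsets by clustering, scores every
biopsy against every pathway signature, and tests the scores against
clinical covariates. It is written for computational biologists analyzing
two-color microarray (log2-ratio) skin expression data, and every stage is
exercisable on synthetic data with planted ground truth.

## The method

**Signature derivation.** For an agonist time course sampled at
0,0,0,2,4,8,12,24 h (triplicate baselines), a gene joins the pathway
signature when its mean log2 fold change across replicates is ≥ log2(2) at
*both* 12 h and 24 h (≤ −log2(2) for repressed genes), and its trajectory
correlates (mean Pearson r > 0.8 across replicates) with an idealized
sustained-induction pattern — 0 at the baselines, full induction from 2 h
on. The signature's *centroid* is each member's mean 12/24 h response.

**Compendium assembly.** Cohorts are inner-joined on shared probes and
adjusted with parametric empirical-Bayes batch correction (ComBat):
gene-standardize, estimate per-batch location/scale, shrink toward
moment-matched normal / inverse-gamma priors, back-transform. Residual batch
bias is tested with guided PCA (gPCA): the statistic
δ = Var(X·v₁ᵍ)/Var(X·v₁) compares the variance captured by the first
batch-guided principal component with the first unguided one; significance
comes from batch-label permutations.

**Intrinsic selection and clustering.** Each gene gets an intrinsic score
S\_g = W\_g/B\_g — mean within-patient variance over between-patient variance
of patient means; small S marks genes stable inside a patient but variable
across patients. A permutation null (shuffling the array→patient map)
converts a score threshold into an estimated FDR. Biopsies are clustered on
the selected genes with average linkage on 1 − centered Pearson correlation,
the tree is cut into k clusters, small clusters become *unassigned*, and
clusters are named by their dominant marker program.

**Scoring and association.** Each array's pathway score is the Pearson
correlation between the signature centroid and the array's expression over
the aligned genes (probe IDs when available, Entrez with multi-probe
averaging otherwise). Per subset, the mean score r̄ becomes an enrichment
p-value via t = r̄·√((n−2)/(1−r̄²)) with n − 2 df, n = signature genes
present in the compendium. Clinical screens use Pearson correlation for
continuous covariates (MRSS, age) and one-way ANOVA for categorical ones
(sex, biopsy site, early/late disease at 2 years), on diffuse-SSc arrays
selected one-per-patient-per-timepoint with lesional biopsies preferred.

## Worked example

The `pipeline` subcommand runs the whole chain on a synthetic three-cohort
compendium (defaults: 2000 genes, 4 × 10 patients, 4 disjoint 50-gene subset
programs at a 1.5 log2 effect, batch offsets of 0.5 sd):

```sh
$ sigscore pipeline --seed 0 --out demo/
arrays: 83, genes: 2000
gPCA p before/after ComBat: 0.0050 / 1.0000
intrinsic genes selected: 456 (estimated FDR 4.99%)
subset recovery ARI: 0.885
subset sizes: limited=24, fibroproliferative=21, inflammatory=19, normal_like=19
strongest MRSS association: fibroproliferative_program (r = 0.643, p = 1.1e-06)
```

Reading the output: the simulated cohort offsets are highly significant
before adjustment (gPCA p = 0.005) and undetectable after (p = 1.0);
intrinsic selection at a 5% FDR target keeps 456 of 2000 genes; clustering
those genes recovers the four planted subsets almost exactly (adjusted Rand
index 0.885 against ground truth); and the planted severity axis — MRSS was
generated from the fibroproliferative-program activation — is recovered as
the top-ranked clinical correlation. Per-array scores, subset enrichment and
the full association table land in `demo/`.

The same stages are available individually (`simulate`, `merge`, `combat`,
`gpca`, `intrinsic`, `cluster`, `derive`, `score`, `associate`) and as
library functions (`sigscore.derive_signature`, `sigscore.score_arrays`,
…).

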