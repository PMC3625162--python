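# Methods

## Scope and model

`zygoct` implements the quantification and classification stack for
threshold-cycle (Ct) data from microfluidic qPCR cards ("low-density
arrays"), together with the high-density-array candidate-selection stage that
typically precedes them, and synthetic generators that plant known structure
so every stage can be validated end to end. The motivating application is
the comparison of expression signatures between KIT-mutant genotypes that
differ in zygosity: hemizygous exon-11 deletions (one mutant allele, no
wild-type), heterozygous combinations (mutant + wild-type), and wild-type
KIT, in an NIH3T3-like cell-line panel and in GIST (gastrointestinal stromal
tumour) cohorts.

The quantitative core is standard ΔΔCt algebra under an assumed PCR
efficiency of 2 (one cycle = one doubling):

* **Cut-off.** Ct values beyond a cut-off (35 cycles for cell-line cards, 37
  for tumour series) are unreliable late amplifications and become
  non-detects. Non-detects are masked out of every downstream statistic;
  they are never imputed.
* **Card-median ("virtual housekeeping") correction.** For card *j* with
  median Ct *m<sub>j</sub>* over present values, every Ct on the card is
  shifted by *(target − m<sub>j</sub>)*. All cards then share one median —
  a perfect "virtual housekeeping gene" — so ΔCt = corrected Ct − target has
  per-card median 0. The default target is the **median of per-card
  medians**, which is robust to cards carrying different non-detect loads;
  an explicit numeric target is accepted for pipelines that must match a
  fixed anchor.
* **ΔΔCt.** Per assay, ΔΔCt = ΔCt − reference, where the default reference
  is the **arithmetic mean of the assay's present ΔCt across samples**
  rather than one calibrator sample: group statistics downstream are then
  centred, and the per-assay geometric mean of RQ = 2^(−ΔΔCt) is exactly 1
  (this is asserted to 1e-9 in the tests). Choosing a calibrator sample
  instead gives RQ ≡ 1 in that sample.
* **Single-plex alternatives.** `ntarget_reference_gene` computes
  Ntarget = 2^(Ct_ref − Ct_target) per sample against a reference gene;
  `tumor_correcting_factors` pins a stable reference (e.g. ETV6) to its
  grand-mean Ct in every tumour by the additive per-tumour factor
  F<sub>j</sub> = mean(Ct_ref) − Ct_ref(j), applied to all assays of tumour
  *j* (additive on the Ct scale = multiplicative on the linear scale).
  The grand mean averages all measurements equally, without first collapsing
  technical replicates; with balanced replication the two conventions agree,
  and the unweighted mean is the only one computable when replicate
  structure is not recorded.
* **Folds vs a baseline group** divide each RQ by the **geometric** mean of
  the baseline group (folds are ratios; an arithmetic-mean option exists for
  sensitivity checks), so the baseline's own geometric-mean fold is 1 and
  the result is invariant to global rescaling.
* **geNorm stability.** M(gene) = mean over partner genes of the SD across
  samples of the pairwise log2 expression ratio (ddof = 1). On the Ct scale
  the log2 ratio of genes *i, k* in a sample is Ct<sub>k</sub> −
  Ct<sub>i</sub>, so constant offsets cancel. The ranking sorts ascending
  by full-panel M with ties broken by assay id; worst-first iterative
  exclusion down to a floor of two genes and the pairwise-variation series
  V(n/n+1) are also reported.

Sign conventions are fixed throughout so that **higher expression ⇒ lower
Ct ⇒ larger RQ**.

## High-density array stage

Each array is divided by its median intensity (median = 1 afterwards); the
detection threshold is mean + k·SD of the ~100 negative-control probes
(k = 3 default), with calls absent (< threshold), marginal ([threshold,
1.2·threshold)) and present (≥ 1.2·threshold). The marginal band and k are
configurable because scanner software conventions vary. Candidate genes are
selected by the symmetric pairwise fold change max(a/b, b/a) averaged over
all cross-group sample pairs (≥ 2 to retain), an amplitude floor (> 1.3 in
at least one sample), and a detection-call rule. The call rule is read as
"present or marginal in **all samples of at least one** compared group" —
the gene must be expressed above background somewhere — with a strict
all-samples variant behind a flag. Zero intensities are clamped to a
configurable floor (default 0.01) before ratios, and flagged.

## Statistics

All group statistics run on log2 RQ (= −ΔΔCt): the cycle scale is where
qPCR noise is closest to Gaussian. The ANOVA is the classic one-way
fixed-effects equal-variance test; zero total variance is defined as p = 1
(no evidence of effect) and zero within-group variance with distinct means
as p = 0. No multiple-testing correction is applied by default, matching
raw-alpha selection practice in this workflow; Benjamini–Hochberg is an
explicit opt-in that logs a warning. The control-line (empty-vector)
nonspecific filter excludes assays whose expression varies across culture
conditions in the control line at raw alpha — such assays respond to
handling, not to the oncogene.

Mann–Whitney is exact by enumeration when n ≤ 12 without ties, otherwise a
tie-corrected normal approximation; Fisher's test sums hypergeometric
probabilities ≤ the observed table's. Both are checked in the test suite
against independent brute-force enumeration oracles. Univariate logistic
regression reference-codes the factor and reports per-level Wald p-values;
levels that perfectly predict the outcome (a zero cell in the level ×
outcome table) have no finite MLE and are **flagged as separated with NaN
estimates** instead of emitting the near-1 p-value artifacts some software
produces in that situation. Clinical factors are dichotomized at fixed
cutpoints (age 60 years, tumour size 6 cm, mitoses 2 per 5 mm²; value ≥
cutpoint → high stratum).

The "frequently deregulated genes" PCA selection is a **reconstruction**:
genes are ranked by the Euclidean norm of their variance-weighted loadings
on the first two principal components of the gene-centred log2 RQ matrix.
No authoritative criterion exists for this step; the record attached to the
result marks the method accordingly.

## Clustering and topology read-offs

Samples are clustered on log2 RQ with Euclidean distances (cycle units).
Missing cells are handled by pairwise-complete distances rescaled by
(total assays / shared assays); with no missing data this is plainly
Euclidean, and listwise deletion is available behind a flag. Linkage
defaults to average (UPGMA) — the linkage is not dictated by the workflow,
and complete/Ward are available; topology conclusions should be checked for
linkage sensitivity. Samples are sorted lexicographically before distance
computation so the tree is invariant to input order. Genes are not
z-scored by default (the heatmap convention this mirrors plots relative
levels); per-gene standardization is a flag.

Visual dendrogram read-offs are replaced by quantitative checks: monophyly
of a label set (some subtree contains exactly those samples), disjointness
of smallest enclosing subtrees, and the adjusted Rand index of a k-cut
against annotation. The 2-component PCA centres genes, mean-imputes missing
cells per gene, fixes component signs so the largest-magnitude loading is
positive, and reports all explained-variance fractions (they sum to 1).

## Synthetic designs

The generators emit Ct = baseline − effect + card offset + Gaussian noise,
with readings past the cut-off emitted as non-detects — missingness arises
mechanistically, the way instruments produce it, so cut-off handling is
exercised realistically (independent dropout and heavy-tailed noise exist as
robustness options). Fixed seed ⇒ identical output (single generator
algorithm, `numpy.random.default_rng`).

**Cell-line panel** (94 mRNA assays + a nominally stable MYH9 control that
is only moderately stable, SD 0.8): replicate structure 3/3/3/2/2 for
WT/D6/D54/WT-D6/WT-D54 under SCF+, 2 each under imatinib, and 2 MIGR
empty-vector controls in each of three conditions. Planted structure: a
16-assay signature shared by both hemizygous deletions plus 12 D6-specific
and 12 D54-specific assays at 1.5 cycles; heterozygous lines express 0.15 ×
their hemizygous partner's effect; 20 KIT-responsive assays (1 cycle)
separate every KIT line from MIGR and are attenuated ×0.3 under imatinib;
10 nonspecific assays shift with culture condition in all lines and carry
extra jitter — the material the control-line filter exists to remove.
Technical noise is 0.3 cycles; card offsets SD 0.5, one sample per card.
The effect-size *ratios* encode the qualitative claims the design is meant
to reproduce (heterozygous ≈ WT; D6 and D54 mutually distinct); the absolute
sizes are reconstructions chosen to make that topology reproducible, not
measurements.

**Tumour cohort** (384 miRNA assays): exactly 6 homozygous + 13 heterozygous
exon-11-mutated tumours, one card each, with a 13-assay zygosity signature
at 1.5 cycles and appended stable (ETV6-like, SD 0.2) and unstable
(18S-like, SD 2.0) candidate references. The default noise of 0.8 cycles
lumps technical noise with inter-tumour biological heterogeneity — archival
FFPE tumour material is far more variable than replicate cultures — and is
what makes the signature recoverable by supervised ANOVA selection yet
invisible to unsupervised clustering over the full card. Simulations that
specifically probe test calibration (null rejection rates, selection
sensitivity/FPR) run at 0.3 cycles, the technical-replicate level.

**High-density arrays**: log-normal target intensities with per-array scale
factors (what median normalization must undo), 100 low-intensity negative
controls per array, and planted 2.5-fold (true candidates) and 1.2-fold
(sub-threshold) genes at 5 % multiplicative noise, 3 arrays per group.

### What the generators do not emulate

Real data differ in ways the synthetics deliberately omit: amplification
efficiency below 2 and efficiency differences between assays; correlated
(pathway-level) noise across genes; plate-position and inter-run effects
beyond a single additive card offset; partial degradation profiles of FFPE
RNA; and non-detects from reaction failure unrelated to abundance (available
only as the independent-dropout option). Passing the planted-recovery tests
therefore demonstrates the *algorithms* behave as specified under their own
assumptions, not that any particular biological dataset would yield the same
gene lists.

## Problem sizes and numerical choices

The simulation-based checks use 100 seeds per scenario (200 random matrices
for the normalization-exactness check; 1000 assays for the null-calibration
check), sizes chosen so the whole validation runs in a few minutes on one
core while keeping Monte-Carlo error well inside the asserted margins.
Exactness assertions (card medians, geometric means) use 1e-9; observed
deviations are at machine precision (~1e-15). Ties in geNorm rankings and
gene orderings break lexicographically by assay id so outputs are
deterministic. Degenerate inputs (empty cards, all-zero arrays, constant
matrices, undetected reference genes, separated logistic factors) raise
typed errors or flags rather than propagating NaNs.

## Known limitations

* Efficiency correction, calibrator samples shared across plates, and
  non-detect imputation are out of scope by design.
* The PCA-based gene ranking is one defensible reading of an
  under-specified procedure; its selections should be treated as a ranking,
  not a hypothesis test.
* Monophyly-based topology checks are strict set conditions; on small
  panels they are sensitive to single-sample placement, which is why the
  recovery guarantees are stated as rates over many seeds rather than
  per-dataset certainties.
* The logistic stage detects separation but does not implement penalized
  (Firth) estimation; sparse categorical factors simply report as
  non-estimable.
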