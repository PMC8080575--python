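# Methods

This note documents the models and procedures implemented in `asceco`, the
parameters that matter, the numerical choices made where the procedure was
underdetermined, and what the synthetic generators do and do not emulate.

## Expression units and QC

Full-length (plate/microfluidic) data are transformed as
`E = log2(TPM/10 + 1)`; the ÷10 deflation damps TPM inflation in
low-complexity single-cell libraries. Droplet data are rescaled per cell to
10,000 (`pseudoTPM`) and transformed as `log2(pseudoTPM + 1)`. Both
transforms are monotone and map 0 → 0; "expressed" always means **strictly**
`E > 1` (the confident-expression call used by QC, typing and the
interaction analysis).

Cell/gene filtering is a single pass, cells first: cells expressing fewer
than `min_genes` (default 1000) genes are dropped, then genes expressed in
fewer than `min_cells` (default 10; 2 for very small cohorts) of the
*retained* cells. The order is not dictated by the procedure's description,
so it is fixed (deterministic, idempotent) and recorded in the QC report.
Droplet QC keeps cells satisfying all three inclusive bounds
(1000 ≤ nCounts ≤ 150,000, 200 ≤ nFeatures ≤ 10,000, mito % ≤ 20).

Marker typing is a conjunction of per-gene threshold clauses; a cell matching
zero or ≥ 2 rules is `unassigned` (ambiguity flagged). Equality clauses
("EPCAM = 0") are evaluated as `|E| < 1e-12` to absorb float noise; whether
"= 0" means raw zero or below-detection is not observable from the data, so
exact (tolerance) zero was chosen. Duplicate gene rows on input are an error,
not auto-summed: isoform-level TPM is assumed pre-summed upstream.

## Chromosomal expression pattern (CEP)

Autosomal genes (chromosomes 1–22 from the annotation) are Z-normalized per
gene across cells (population SD, ddof = 0; zero-variance genes map to zero)
and clipped to [−clip, clip], default 3, so single outlier cells cannot
mimic amplifications. Genes are sorted by (chromosome, start, gene id) — the
id tie-break makes the order deterministic — and averaged over every fully
contained window of 150 consecutive genes within a chromosome (step 1).
Chromosomes shorter than the window contribute no windows and are logged;
shrinking edge windows were rejected because they inflate variance exactly
where smoothing support is weakest. Each cell's genome-wide window mean is
then subtracted ("centering"), removing cell-level baseline shifts; the
per-cell CEP mean is 0 within 1e-9 by construction.

Copy-number instability is MS = mean of squared CEP values per cell.
Cell–cell similarity is the Pearson correlation over windows (not raw
genes); cells are clustered agglomeratively on distance 1 − r. Linkage is a
configuration knob defaulting to `average`. Zero-variance CEP profiles get
correlation 0 with a warning instead of NaNs. Group MS differences use
Welch's two-sample *t*-test; groups outside the tested pair (e.g. a 5-cell
mesothelial population) are ignored.

A structural point worth knowing: because genes are Z-scored across *all*
cells, a copy-number segment shared by a fraction f of cells deviates those
cells by ∝ (1−f) and everyone else by ∝ −f. Between two equal-sized groups
the squared deviations are identical, so MS cannot distinguish them; the
tumor-vs-macrophage MS contrast works because aneuploid clones are
minorities against a flat majority. Test scenarios are constructed
accordingly (tumor cells ≤ 1/3 of the mixture).

## Ligand–receptor interaction counting

With binary calls `E > 1`, for each curated (ligand L, receptor R) pair and
ordered group pair (g₁ → g₂), the intercellular count is the number of
ordered distinct cell pairs (c₁ ∈ g₁ expressing L, c₂ ∈ g₂ expressing R);
the self-sufficient count per group is the number of single cells expressing
both. The two categories are independent — a co-expressing cell still
partners intercellularly with other cells. Counting is implemented by group
expresser-count products minus the same-cell correction, which is exactly
the exhaustive enumeration (verified against a triple-loop oracle in the
tests). Pair tables are TSV (`ligand  receptor  source`); pairs whose genes
are absent from the matrix are skipped with a log entry, never fatal, and
duplicate pairs across merged databases count once.

Top pairs per direction are ranked by count with (ligand, receptor)
lexicographic tie-breaks. Salient-gene labeling keeps genes whose mean E
across the group's cells strictly exceeds the q-quantile (type-7 linear
interpolation) of the subset's means *and* whose expressing-cell fraction
strictly exceeds the floor (defaults 0.95/0.75; the cytokine-focused variant
uses 0.5/0.1).

## M1/M2 signature extraction

The differential-expression engine is a negative-binomial GLM
likelihood-ratio test written for this package:

* counts may be fractional (RSEM-style expected counts); the NB likelihood
  needs integers, so counts are rounded half-even (the rounding rule is part
  of the contract);
* size factors come from one of two schemes — **TMM** (trimmed mean of
  M-values against the cell whose library size is closest to the median;
  30% two-sided trim on M, 5% on A, inverse-variance weights) or
  **median-of-ratios** (per-cell median ratio to the per-gene geometric mean
  over all-positive genes) — both scaled to geometric mean 1. The
  median-of-ratios factors are cross-checked against an independent
  implementation in the tests;
* per-gene dispersion α is a method-of-moments estimate on normalized counts
  pooled within groups, shrunk on the log scale toward a log-linear
  mean–dispersion trend (shrinkage weight 0.35 by default, configurable);
* the full model (intercept + group) factorizes into per-group intercept
  fits, each solved by a vectorized Newton iteration; the LRT statistic
  2(ℓ_full − ℓ_null) is referred to χ²₁ and BH-adjusted per analysis;
* log2 fold changes use normalized group means with pseudocount 0.5; the
  contrast orientation (which group is "up") is explicit metadata.

This engine deliberately does not reproduce any specific package's
dispersion machinery (Cox–Reid adjusted likelihoods, empirical-Bayes
moderation), and it does not model zero inflation. Its null calibration is
checked directly: on simulated null data (2000 genes, 40+40 cells,
dispersion 0.2) the fraction of p < 0.05 must land in [0.03, 0.07].

Signature extraction intersects DE calls (log2FC > 2 up / < −2 down,
FDR < 0.05) across the two normalization schemes within each donor, then
across donors. The intersection is what suppresses donor-specific and
method-specific false positives; under a no-DE null the final signatures are
empty in ≥ 95% of seeds. Empty intersections warn but do not raise. An
optional exclusion filter removes dissociation-induced stress genes (EGR1,
FOS, FOSB, JUN, ...) from a signature; it is off by default.

Scores are `E_s(S) = mean E` over the signature genes detected in the
matrix (missing genes reduce `genes_used`, they are not imputed). Rescaling
to [−1, 1] is the affine map min → −1, max → +1 and is undefined (error) for
constant scores. Polarization is summarized by the OLS slope of M2 score on
M1 score (with 95% CI) *and* by mean(M2 − M1); neither alone is treated as
the criterion of inclination.

## Survival stratification

Bulk samples are scored like cells (genes detected in the cohort only),
then split at the 25th/75th percentiles (linear interpolation): 'high' is
strictly above the 75th, 'low' strictly below the 25th, and everything else
— including boundary ties — is excluded. Strictness makes the two groups
symmetric and deterministic under ties; the rule is recorded in the result.
Curves are Kaplan–Meier product-limit estimates; the two-group log-rank test
uses the standard hypergeometric variance with the simultaneous-risk-set
convention for ties (a hand-computed 4-sample table is a frozen test
oracle). Overall survival only; stage is carried as metadata (no Cox
modeling). Per-gene analyses apply the same quartile rule to one gene's
expression; leave-one-out re-scores with each signature gene removed.

## Synthetic generators

All generators are pure functions of (config, seed); counts are
negative-binomial (gamma–Poisson) with log-normal gene means and per-cell
log-normal depth factors. They emulate the statistical structure each stage
assumes — nothing more. Deliberately absent: transcriptome-wide gene–gene
correlation, zero inflation beyond NB sampling, doublets, ambient RNA, batch
effects other than the donor shift. Passing tests therefore demonstrate that
the pipeline recovers planted structure under its own model assumptions, not
performance on real tissue.

**Ascites mixture** (default 5000 genes × 162 cells): four patient-specific
tumor clones (25 cells each), 57 macrophages, 5 mesothelial cells. Gene
means are log-normal (median 30 TPM-like units, σ = 1.3); dispersions are
log-normal around 0.3 (typical full-length scRNA-seq); depth σ = 0.2. Genes
are laid out on chromosomes 1–22 in blocks proportional to human
protein-coding gene counts, so at 5000 genes most chromosomes exceed the
150-gene window. Each clone carries 2 contiguous segments (factors 0.6–1.7)
on distinct chromosomes. A named marker panel plants the cell-typing and
signaling programs: macrophage markers (CD86, CD68, CD163) and ligands
(CCL3, CCR1, IL1B, IL10, IL10RA) at 250–450 units in macrophages and ~1
(i.e. not expressed) elsewhere; EPCAM/KRT8 and the IL1B decoy receptor IL1R2
in tumor cells; MUC16 in mesothelial cells; CD3D nowhere (no T cells).
Genes whose means are exactly 0 yield exact zero counts, which is what makes
the "= 0" marker clauses recoverable. The companion pair database holds the
three planted cytokine pairs plus 25 decoy pairs drawn deterministically
from moderately expressed background genes (baseline mean 5–30 units), so
decoys are genuine but weaker competitors, as curated pair lists mostly are.

**M1/M2 reference** (default 2000 genes; 49+48 M1 and 23+22 M2 cells across
two donors, matching the 97/45 reference design): 60 shared M1-up and 20
shared M2-up genes at log2FC 3 (split symmetrically ±1.5 around baseline),
15 donor-specific decoy DE genes per donor, a per-donor log-normal baseline
shift (σ = 0.3) emulating donor variability, dispersion 0.2, depth σ = 0.3.

**Bulk cohort**: each sample has a latent standard-normal M2 activity z;
signature genes express base + slope·z (slopes U(0.3, 0.7), E units, noise
σ = 0.4, clipped at 0), background genes are noise around their base.
Survival is exponential with hazard h₀·exp(β·z/Δ) where Δ ≈ 2.542 is the
expected top-minus-bottom-quartile mean gap of a standard normal — so
exp(β) *is* the planted hazard ratio between the quartile groups (verified
empirically: ≈ 2.46 at n = 2000 for β = log 2.5). Baseline hazard defaults
to log 2 / 730 days (two-year median survival). Censoring is independent
U(0, τ) with τ solved numerically so the expected censored fraction matches
the configured value (default 0.2).

## Problem sizes used in the checks

The acceptance-style checks run at: 5000 genes × 150–162 cells for CEP and
interactions; 2000 genes × 142 cells for signature extraction (nulls at 1000
genes over 100 seeds); 2000 null genes for DE calibration; 300-sample
cohorts over 500 null seeds and 100 power replicates, and one 378-sample
cohort for the end-to-end survival run. These sizes keep every planted
effect comfortably detectable while the full pipeline remains a
single-machine, minutes-scale computation.

## Known limitations

* CEP has no breakpoint model, no HMM segmentation, and ignores sex
  chromosomes; it is a smoothing-based proxy, not a CNV caller.
* The MS contrast is blind to copy-number changes shared by a majority of
  cells (see the Z-scoring note above).
* The DE engine's dispersion shrinkage is a simple trend blend; very small
  groups (< ~10 cells) will be less well calibrated than the tested 20–50
  cell regime.
* Interaction counts are descriptive tallies; no permutation null is
  attached to them.
* The survival module fits no covariate-adjusted model; stage is metadata.
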