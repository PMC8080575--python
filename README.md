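# asceco — single-cell analysis of the malignant-ascites tumor ecosystem

Gastric-cancer patients who develop malignant ascites carry a fluid
microenvironment of disseminated tumor cells and tumor-associated macrophages
(TAMs). `asceco` re-implements, as a tested analysis pipeline, the
computations used to characterize that ecosystem from single-cell RNA-seq:

1. **Normalization & QC** (`asceco.io_qc`) — full-length expression values
   `E_ij = log2(TPM_ij/10 + 1)`; droplet values `E_ij = log2(pseudoTPM_ij + 1)`
   with `pseudoTPM_ij = UMI_ij / Σ_i UMI_ij × 10,000`; removal of cells
   expressing < 1000 genes and genes expressed (`E > 1`) in < 10 cells;
   droplet QC (`1000 ≤ nCounts ≤ 150,000`, `200 ≤ nFeatures ≤ 10,000`,
   mito ≤ 20%); marker-threshold cell typing (e.g. macrophage:
   `CD86 > 2, MUC16 < 1.1, EPCAM = 0, CD3D = 0`).
2. **Chromosomal expression pattern** (`asceco.cep`) — a CNV proxy: per-gene
   Z-normalization across cells clipped to [−3, 3], moving averages over
   150-gene windows in genome order within chromosomes 1–22, per-cell
   centering; copy-number instability per cell as the mean of squares (MS) of
   its CEP values; Pearson-correlation hierarchical clustering of CEP
   profiles; Welch *t* comparison of MS between cell groups.
3. **Ligand–receptor interactions** (`asceco.interactions`) — binary
   expression calls (`E > 1`) intersected with a curated pair list; ordered
   cell pairs (ligand cell → receptor cell, distinct cells) counted as
   *intercellular interactions* per sender→receiver direction, single cells
   expressing both genes as *self-sufficient signaling*; top-pair ranking and
   salient-gene labeling (mean expression above a quantile of the subset and
   expressing-cell fraction above a floor).
4. **M1/M2 signatures** (`asceco.signatures`) — per-gene negative-binomial
   GLM likelihood-ratio tests (`y_gj ~ NB(s_j·exp(x_jᵀβ_g), α_g)`, full model
   intercept+group vs intercept, `2Δℓ ~ χ²₁`, BH FDR) under two normalization
   schemes (TMM and median-of-ratios size factors); signature = genes with
   `|log2FC| > 2` and `FDR < 0.05` under **both** schemes and in **both**
   donors; signature scoring `E_s,j(S) = mean(E_1..n,j)`, [−1, 1] rescaling,
   and the M2-on-M1 polarization regression.
5. **Survival stratification** (`asceco.survival`) — signature scores on a
   bulk cohort, 'high' (> 75th percentile) vs 'low' (< 25th percentile)
   groups, Kaplan–Meier curves, two-group log-rank test, per-gene and
   leave-one-out variants.
6. **Synthetic data** (`asceco.synthetic`) — seeded generators for every
   stage: an ascites mixture with patient-specific copy-number segments and
   planted CCL3/CCR1, IL1B→IL1R2 and IL10/IL10RA programs; two-donor M1/M2
   reference macrophages with shared planted markers and donor-specific
   decoys; bulk cohorts whose exponential hazard tracks a latent M2 activity.

It is written for computational biologists who want the bespoke pieces of
this analysis — expression-based CNV inference, interaction counting,
intersection-based signature extraction, quartile survival stratification —
as reusable, tested functions that run end-to-end on synthetic data with
known ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the
synthetic study (seed 1 by default, `python analysis/03_cep_cnv.py 7` to
change it), writing tables under `results/` and bulky matrices under
`scratch/`. For example:

```sh
$ python analysis/03_cep_cnv.py
1985 windows of 150 genes (chromosomes skipped: [13, 18, 20, 21, 22])
MS tumor 0.0655 vs macrophage 0.0131; Welch t = 40.6, p = 3.42e-70
CEP correlation clustering recovers the 4 planted clones: ARI = 1.000
```

The 162-cell mixture yields 1985 genome-ordered windows (five short
chromosomes have fewer than 150 annotated genes and contribute none). Tumor
cells, which carry the planted copy-number segments, show a five-fold higher
mean instability score than macrophages, and clustering the tumor-cell CEP
profiles recovers the four planted patient clones exactly.

```sh
$ python analysis/06_survival.py
M2 signature (20 genes) on 378 samples: high n=95, low n=95, log-rank chi2 = 15.28, p = 9.26e-05
...
leave-one-out: max p over 20 reduced signatures = 0.0003 (association is not driven by any single gene)
```

Here the M2 signature extracted in step 05 stratifies a simulated 378-sample
cohort (planted high-vs-low quartile hazard ratio 2.5) into quartile groups
whose survival separates at p ≈ 1e−4, and the association survives removal
of any single gene.

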