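# Methods

## The statistic

For gene *g* observed in *n* cells with rpkm values *x₁…x_n*, the
relative divergence is the coefficient of variation

    CV_g = s_g / x̄_g,

with *s_g* the sample (n−1) standard deviation.  CV is undefined
(flagged, never coerced to 0) when the mean is 0, and is invariant to
any positive rescaling of the gene's expression, so it is unaffected by
gene length and by global normalization choices.

rpkm is computed as `count / (length_kb × library_size/10⁶)` with the
library size taken as the per-cell total of tags assigned to biological
genes; spike-in rows are excluded from the denominator (they reflect
added RNA, not cellular mRNA mass) and reported separately.  An
`all_mapped` denominator switch exists for sensitivity analysis.  This
yields the exact conservation identity Σ_g rpkm × length_kb = 10⁶ per
cell, which the tests assert to floating tolerance.

## Expression-matched divergence test

CV depends systematically on the mean (shot noise contributes 1/μ to
CV²), so each gene is tested only against controls in a two-fold mean
window (closed interval; ties included for determinism), capped at
1,000 by uniform subsampling from a seeded stream.  The test statistic
is

    F = CV²_g / median(CV²_controls),

referred to an F distribution with (n−1, n−1) degrees of freedom,
two-sided (p = 2·min(upper, lower tail), capped at 1), direction
"more" when F > 1.  Design choices, made where the procedure was
genuinely open:

* **Median** as the background center: robust to the heavy right tail
  of control CVs; with ≥ 10 controls its own sampling noise is small
  relative to the F reference width.
* **(n−1, n−1) df**: both the gene's CV² and each control's are
  variance-like quantities estimated from the same n cells; the F
  family with equal df is the classical reference for their ratio.
  Because the median of many controls is far more stable than a single
  variance estimate, the test is mildly conservative for low-CV data;
  at CVs typical of these data (≈ 0.5–1) the extra mean-variability in
  CV² brings the null rejection rate close to nominal (the calibration
  test asserts 2–10 % at α = 0.05, n = 50).
* An empirical-percentile alternative (rank of CV_g among controls) is
  available via `method="percentile"`; its resolution is limited to
  1/(n_controls+1).
* No multiple-testing correction by default; raw P < 0.05 defines the
  more/less diverse lists.  Genes with mean ≤ 5 rpkm are carried but
  not tested.

Enrichment of the resulting lists uses Fisher's exact test
(two-sided probability-mass rule) against the universe of *testable*
genes — genes that could have entered a list — not all annotated genes.

## Drug-response comparisons

Mean fold change uses a pseudocount of 0.1 rpkm (below the 5 rpkm
eligibility floor) so on/off switches remain finite; CV fold change is
left unregularized and flagged undefined when either CV is 0 or
undefined.  A gene is eligible when its mean exceeds 5 rpkm in at least
one condition, which keeps strong induction/repression events visible.
Responder thresholds are strict inequalities, so a gene at exactly
two-fold is not selected and results are stable at boundaries.

## Spike-in QC

Each cell's count for each spike-in is converted to a leave-one-out
z-score (mean and sample SD of the *other* cells); any |z| > 2 discards
the cell.  The default scale is log₁₀(count+1) because spike-in counts
span orders of magnitude; linear mode is retained.  One pass only — no
iterative re-filtering.  When the leave-one-out SD is 0, z is defined
as 0 if the cell matches the common value and ±∞ otherwise.

## Saturation analyses

Depth titration binomially thins each cell's counts with
p_c = target/depth_c (cells below target kept unthinned), which
reproduces read-subsampling in first moments; rpkm is unchanged in
expectation because the thinning factor cancels in the normalization.
Expression strata (1–5, 5–10, 10–50, 50–100, 100–500 rpkm) are assigned
at full depth and frozen across the grid so stratum migration cannot
masquerade as a depth effect.  Cell titration subsamples cells without
replacement (default 20 replicates) and reports the across-replicate SD
of the stratum-mean CV as the estimator's sampling spread.

## Clustering and PCA

Cells are embedded on log₁₀(rpkm + 0.01) of a gene panel.  Clustering:
per-gene standardized values, Euclidean distance, complete linkage
(mirroring the cited R clustering default), cut at K = number of
distinct line/treatment groups.  Purity = (1/n) Σ_clusters max-label
count, reported with a 1,000-permutation chance baseline.  PCA centers
each gene and fixes each component's sign (largest-magnitude loading
positive), making the embedding deterministic and cell-order invariant.
Noisy low-expression genes dilute complete-linkage separation, so the
analysis drivers cluster on the best-expressed genes of the panel of
interest.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the sequencing chemistry:

* **Means**: Zipf-like power law over gene rank (exponent −1 by
  default, matching the observed distribution of average expression
  levels); with the default 20,000 genes and ~10⁶ gene tags per cell,
  rpkm spans ~2.5 to tens of thousands so every expression stratum is
  populated.
* **Counts**: negative binomial via gamma-Poisson with gene-specific
  dispersion φ (log-normal, median 0.5), giving CV² = 1/μ + φ — the
  minimal family that reproduces both the decline of CV with mean and
  its plateau near 1 for well-expressed, highly variable genes.  An
  optional mean-dependent dropout law exists but defaults to off: at
  this sequencing depth zeros arise naturally from the NB tail.
* **Cells**: log-normal depth factors (σ = 0.3) emulate library-size
  variation; three spike-in channels (100/1,000/10,000 input copies,
  10 % capture) are Poisson with expectation copies × efficiency ×
  depth factor — linear in copies by construction.  Planted outlier
  cells distort *only* the spike-in expectations (default 10×), so QC
  recovery can be validated independently of biology.
* **Conditions**: per-line scalar mean/CV multipliers, optional
  per-line per-gene log-normal profiles (`line_profile_sigma`,
  default 0 — enable to emulate line-specific expression signatures),
  and treatment effects on named gene subsets.  CV folds are applied
  exactly on CV² = 1/μ + φ (φ clipped at 0), not approximated by
  scaling φ.
* **Truth**: per-(gene, group) true mean/dispersion and planted-effect
  membership, per-cell labels and outlier flags, for recovery tests.

What the generator does **not** emulate: amplification bias and
transcript-coverage nonuniformity, cell-cycle or microenvironment
structure, correlated gene modules, UMI chemistry, and batch effects.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to those real-data
phenomena.

## Problem sizes and determinism

Test and acceptance runs use scaled cohorts chosen to keep the full
suite fast while leaving every effect detectable: null calibration at
2,000 genes × 50 cells (Gaussian expression at CV 0.7, a typical
relative divergence for well-expressed genes in these data); planted-SD
recovery at 1,550 genes; QC recovery at 96-cell chips over 20 seeds;
saturation at 8,000 genes × 40 cells; the analysis drivers at 8,000
genes × 163 cells across four conditions.  Every stochastic step
(simulation, control subsampling, thinning, subsampling, permutation
baselines) takes an explicit seed or Generator; same seed → bit-identical
output.

## Known limitations

* The F-test's null behavior depends on the true CV scale (conservative
  for CV ≪ 0.5); the percentile method is the distribution-free
  fallback.
* CV is a blunt summary when expression is bimodal (a gene off in half
  the cells shows high CV regardless of its "on" variability).
* Per-set enrichment p-values are reported without aggregation across
  related sets and without multiple-testing correction, mirroring the
  raw-P selection convention used throughout.
* GTF gene length is the union of exon intervals per gene_id — a
  convention (isoform-level length is not resolvable from tag counts);
  strand is ignored as lengths are strand-symmetric.
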