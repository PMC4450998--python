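# scdiverge

Cell-to-cell variability analysis for deep single-cell RNA-seq of cancer
cell lines.

Single cells of the same cultured line do not express their genes at the
same level: even with millions of sequence tags per cell, per-gene
expression varies severalfold between cells, and the degree of
variability is itself a gene- and line-specific trait.  `scdiverge`
implements the full analysis chain for quantifying that variability:

* **Spike-in cell QC** — cells whose spike-in control counts deviate by
  more than 2 leave-one-out standard deviations from the other cells are
  discarded.
* **rpkm quantification** — tag counts normalized per million mapped
  gene tags per kilobase of transcript, with library summaries
  (in-gene mapping fraction, tag complexity).
* **Relative divergence** — for gene *g* with per-cell rpkm values
  *x₁…x_n*, the statistic is the coefficient of variation
  CV_g = s_g / x̄_g (sample SD over mean).  Because CV falls with
  expression level (shot noise contributes 1/μ to CV²), a gene is called
  *more* or *less* diverse only against **expression-matched controls**:
  background genes whose mean lies within two-fold of the gene's mean
  (at most 1,000, subsampled).  The test refers
  F = CV²_g / median(CV²_controls) to an F distribution with
  (n−1, n−1) degrees of freedom, two-sided, at P < 0.05.
* **Gene-set enrichment** — Fisher's exact test of the diverse/uniform
  gene lists in GMT gene sets over the testable-gene universe.
* **Drug response** — per-gene fold changes of mean expression and of
  relative divergence between conditions; responders at two-fold;
  quadrant summaries of (log₂ mean-FC, log₂ CV-FC).
* **Saturation** — stability of the CV estimate under binomial depth
  thinning and under cell subsampling, stratified by expression.
* **Multivariate** — hierarchical clustering of cells (complete linkage,
  Euclidean on standardized log rpkm) with purity against line labels,
  and deterministic PCA.
* **Synthetic cohorts** — a negative-binomial generator with Zipf-like
  mean profile, gene-specific overdispersion (CV² = 1/μ + φ), spike-in
  channels linear in input copies, per-line profiles, treatment effects
  and planted QC-outlier cells, plus a ground-truth table, so every
  stage is testable without external data.

## Worked example

Published per-line summaries (mean ± SD rpkm across single cells) for
five cancer-related genes are bundled as `table2_fixture()`.  Relative
divergence of EGFR in the parental line versus the line carrying an
EGFR driver mutation:

```python
from scdiverge import table2_fixture

fx = table2_fixture()
mean_p, sd_p = fx["EGFR"]["LC2/ad"]   # (13, 14)
mean_m, sd_m = fx["EGFR"]["PC-9"]     # (56, 34)
print(round((sd_p / mean_p) / (sd_m / mean_m), 1))
```

prints `1.8`: expression of the driver-mutated gene is not only ~4-fold
higher on average but 1.8-fold *tighter* across cells, consistent with
stricter selection on its expression.  The full synthetic-cohort
pipeline lives in `analysis/01_simulate.py` … `08_multivariate.py`; for
example the QC stage prints

```
155 of 163 cells passed the 2-SD spike-in filter
planted outliers removed: 5 of 5
clean cells lost: 3 of 158
```

and the divergence stage

```
tested 7318 genes >5 rpkm: 807 more diverse, 692 less diverse at P<0.05
planted high-CV block recovered: 52 of 60
```

— the planted variability block is recovered at 87% recall while clean
genes are called at roughly the nominal false-positive rate.

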