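"""Saturation analyses: stability of the relative-divergence estimate
under binomial depth thinning and under cell subsampling.

The depth curve thins the untreated primary line's counts to a grid of
target depths; the cell curve subsamples cells.  Both stratify genes by
full-depth expression (1-5 ... 100-500 rpkm).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_design import COHORT_DIR, RESULTS

from scdiverge import cell_count_curve, depth_curve, read_count_matrix, read_gene_lengths


def main() -> None:
    spec = dict(pd.read_csv(COHORT_DIR / "spikein_spec.tsv", sep="\t",
                            header=None, index_col=0)[1])
    matrix = read_count_matrix(COHORT_DIR / "counts_filtered.tsv", spikein_spec=spec)
    lengths = read_gene_lengths(COHORT_DIR / "gene_lengths.tsv")
    meta = pd.read_csv(COHORT_DIR / "cell_metadata.tsv", sep="\t", index_col=0)
    cells = [c for c in matrix.cells
             if meta.at[c, "line"] == "LC2/ad" and meta.at[c, "treatment"] == "none"]
    sub = matrix.subset_cells(cells)

    depth = float(sub.gene_counts().sum(axis=0).median())
    grid = [depth * f for f in (0.02, 0.05, 0.1, 0.25, 0.5, 1.0)]
    dcurve = depth_curve(sub, lengths, grid, replicates=3, seed=1)
    dcurve.data.to_csv(RESULTS / "saturation_depth.tsv", sep="\t", index=False)
    spread = dcurve.data.groupby("stratum")["mean_cv"].agg(lambda s: s.max() - s.min())
    print("depth titration, cv spread (max-min over grid) per stratum:")
    for stratum, val in spread.items():
        print(f"  {stratum:>8} rpkm: {val:.3f}")

    n_grid = [5, 10, 20, 30, len(cells)]
    ccurve = cell_count_curve(sub, lengths, n_grid, replicates=15, seed=2)
    ccurve.data.to_csv(RESULTS / "saturation_cells.tsv", sep="\t", index=False)
    sd = ccurve.data.pivot(index="stratum", columns="grid_value", values="sd_cv")
    print("cell titration, across-replicate SD of the stratum cv estimate:")
    print(sd.round(4).to_string())


if __name__ == "__main__":
    main()
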