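"""Generate the synthetic study cohort and write all on-disk artifacts.

Emits under results/cohort/: the gene-by-cell tag-count matrix (TSV),
cell metadata, spike-in specification, gene lengths, and the simulation
truth tables used by later recovery checks.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_design import COHORT_DIR, study_config

from scdiverge import simulate_counts, write_count_matrix


def main() -> None:
    cfg = study_config()
    matrix, meta, spec, lengths, truth = simulate_counts(cfg)
    COHORT_DIR.mkdir(parents=True, exist_ok=True)

    write_count_matrix(matrix, COHORT_DIR / "counts.tsv")
    meta.to_csv(COHORT_DIR / "cell_metadata.tsv", sep="\t")
    with open(COHORT_DIR / "spikein_spec.tsv", "w") as fh:
        for s, copies in spec.items():
            fh.write(f"{s}\t{copies}\n")
    lengths.to_csv(COHORT_DIR / "gene_lengths.tsv", sep="\t", header=False)
    truth.gene_params.to_csv(COHORT_DIR / "truth_genes.tsv", sep="\t", index=False)
    truth.cell_params.to_csv(COHORT_DIR / "truth_cells.tsv", sep="\t")

    n_out = int(truth.cell_params["is_outlier"].sum())
    print(f"cohort: {matrix.n_genes} genes x {matrix.n_cells} cells "
          f"({int(matrix.is_spikein.sum())} spike-ins), "
          f"{n_out} planted outlier cells")
    for (line, treat), n in cfg.cells_per_group.items():
        print(f"  {line} / {treat}: {n} cells")
    print(f"artifacts written to {COHORT_DIR}")


if __name__ == "__main__":
    main()
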