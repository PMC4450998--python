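"""Spike-in quality control: drop cells whose spike-in counts deviate by
more than 2 SD (leave-one-out, log scale) from the other cells.

Writes the per-cell QC report and the filtered count matrix, and checks
the calls against the planted outlier truth.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_design import COHORT_DIR, RESULTS

from scdiverge import (filter_cells, qc_report, read_count_matrix,
                       spikein_zscores, write_count_matrix)


def main() -> None:
    spec = dict(pd.read_csv(COHORT_DIR / "spikein_spec.tsv", sep="\t",
                            header=None, index_col=0)[1])
    matrix = read_count_matrix(COHORT_DIR / "counts.tsv", spikein_spec=spec)

    z = spikein_zscores(matrix, spec, scale="log")
    report = qc_report(z, threshold=2.0)
    filtered = filter_cells(matrix, report)

    out = z.copy()
    out["passed"] = report.passed
    out["failing_spikeins"] = report.failing_spikeins.map(",".join)
    out.to_csv(RESULTS / "qc_report.tsv", sep="\t")
    write_count_matrix(filtered, COHORT_DIR / "counts_filtered.tsv")

    truth = pd.read_csv(COHORT_DIR / "truth_cells.tsv", sep="\t", index_col=0)
    planted = truth.index[truth["is_outlier"]]
    caught = (~report.passed[planted]).sum()
    print(f"{int(report.passed.sum())} of {matrix.n_cells} cells passed the "
          f"2-SD spike-in filter")
    print(f"planted outliers removed: {caught} of {len(planted)}")
    clean = truth.index[~truth["is_outlier"]]
    print(f"clean cells lost: {int((~report.passed[clean]).sum())} of {len(clean)}")


if __name__ == "__main__":
    main()
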