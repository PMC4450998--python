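"""Gene-set enrichment of the divergent-gene lists (Fisher's exact test).

Builds a small GMT: the planted high-CV block as one set, the planted
treatment blocks and random sets as negatives, then tests the more/less
diverse lists against the testable-gene universe.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_design import (HIGH_CV_BLOCK, INDUCED_BLOCK, N_GENES, RESULTS,
                          RIBOSOMAL_LIKE)

from scdiverge import enrich_all, read_gene_sets


def main() -> None:
    calls = pd.read_csv(RESULTS / "divergence_calls.tsv", sep="\t", index_col=0)
    universe = set(calls.index)
    sig = calls[calls["significant"]]
    lists = {
        "more": set(sig.index[sig["direction"] == "more"]),
        "less": set(sig.index[sig["direction"] == "less"]),
    }

    rng = np.random.default_rng(99)
    all_genes = [f"G{i:05d}" for i in range(1, N_GENES + 1)]
    gmt = RESULTS / "gene_sets.gmt"
    with open(gmt, "w") as fh:
        fh.write("planted_high_cv\tplanted variability block\t"
                 + "\t".join(HIGH_CV_BLOCK) + "\n")
        fh.write("housekeeping_like\tlow-divergence block\t"
                 + "\t".join(RIBOSOMAL_LIKE) + "\n")
        fh.write("drug_induced\tinduction block\t" + "\t".join(INDUCED_BLOCK) + "\n")
        for i in range(3):
            members = rng.choice(all_genes, 60, replace=False)
            fh.write(f"random_{i}\tnegative control\t" + "\t".join(members) + "\n")
    gene_sets = read_gene_sets(gmt)

    res = enrich_all(lists, gene_sets, universe, alpha=0.05)
    res.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    for _, row in res.iterrows():
        flag = " *" if row["significant"] else ""
        print(f"{row['gene_set']:>18} x {row['list']:<4} "
              f"overlap={row['in_list_in_set']:>3}  P={row['p']:.3g}{flag}")


if __name__ == "__main__":
    main()
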