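"""Fisher's exact enrichment of gene lists in gene sets.

The 2x2 table for a (selected list, gene set) pair over a universe is

                 in set   not in set
    selected        a          b
    not selected    c          d

and the two-sided p is the exact hypergeometric probability-mass rule:
the sum of probabilities of all tables with fixed margins whose
probability does not exceed the observed table's.  No multiple-testing
correction is applied by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fisher_enrichment", "enrich_all"]


def fisher_enrichment(
    selected: set[str], set_members: set[str], universe: set[str]
) -> dict:
    """One enrichment row: 2x2 table, odds ratio, two-sided exact p.

    ``selected`` must lie within ``universe``; ``set_members`` is
    intersected with the universe before tabulation.  Odds ratio follows
    the unadjusted a*d / (b*c) convention (inf or nan on zero cells).
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected:
        raise ValueError("empty selected list")
    stray = selected - universe
    if stray:
        raise ValueError(f"selected genes outside universe: {sorted(stray)[:5]}")
    members = set_members & universe
    a = len(selected & members)
    b = len(selected) - a
    c = len(members) - a
    d = len(universe) - a - b - c
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "in_list_in_set": a, "in_list_out_set": b,
        "out_list_in_set": c, "out_list_out_set": d,
        "odds_ratio": float(res.statistic), "p": float(res.pvalue),
    }


def enrich_all(
    lists: dict[str, list[str] | set[str]],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of every (gene set, list) pair; rows with p < alpha flagged.

    Gene sets that are empty after intersection with the universe are
    skipped with a warning.
    """
    rows = []
    for set_name, members in gene_sets.items():
        if not (members & universe):
            warnings.warn(f"gene set {set_name!r} is empty after universe "
                          "intersection; skipped")
            continue
        for list_name, genes in lists.items():
            genes = set(genes)
            if not genes:
                continue
            row = fisher_enrichment(genes, members, universe)
            row.update({"gene_set": set_name, "list": list_name,
                        "significant": row["p"] < alpha})
            rows.append(row)
    cols = ["gene_set", "list", "in_list_in_set", "in_list_out_set",
            "out_list_in_set", "out_list_out_set", "odds_ratio", "p", "significant"]
    return pd.DataFrame(rows, columns=cols)
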