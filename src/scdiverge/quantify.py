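"""rpkm normalization and library-level summary statistics.

rpkm (tags per million mapped tags per kilobase of transcript) is computed
per gene and cell as

    rpkm[g, c] = count[g, c] / (length_kb[g] * library_size[c] / 1e6)

with the library size taken as the per-cell total of tags assigned to
biological (non-spike-in) genes; spike-in rows are excluded from the
denominator and reported separately.  An ``all_mapped`` denominator that
also counts spike-in tags is available for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix

__all__ = [
    "ExpressionMatrix",
    "compute_rpkm",
    "refseq_fraction",
    "complexity",
    "read_tag_coordinates",
    "library_summary",
    "compare_replicates",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-cell rpkm values plus the per-cell library sizes used.

    ``rpkm`` covers biological genes only; ``spikein_rpkm`` (if spike-ins
    were present) holds their rpkm on the same denominator for reference.
    """

    rpkm: pd.DataFrame
    library_sizes: pd.Series
    spikein_rpkm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.rpkm.to_numpy()).all():
            raise ValueError("rpkm contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.rpkm.index)

    @property
    def cells(self) -> list[str]:
        return list(self.rpkm.columns)


def compute_rpkm(
    counts: CountMatrix,
    lengths: pd.Series,
    denominator: str = "gene_total",
) -> ExpressionMatrix:
    """Normalize a count matrix to rpkm.

    ``lengths`` must cover every biological gene (missing genes are a hard
    error, never a silent drop).  Cells whose library size is zero are
    excluded with a warning.
    """
    gene_counts = counts.gene_counts()
    missing = gene_counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no transcript length for genes: {list(missing[:5])}")

    if denominator == "gene_total":
        libsize = gene_counts.sum(axis=0)
    elif denominator == "all_mapped":
        libsize = counts.counts.sum(axis=0)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")

    dead = libsize.index[libsize == 0]
    if len(dead):
        warnings.warn(f"excluding {len(dead)} cell(s) with zero library size: "
                      f"{list(dead[:5])}")
        gene_counts = gene_counts.drop(columns=dead)
        libsize = libsize.drop(index=dead)

    len_kb = lengths.loc[gene_counts.index].astype(float) / 1e3
    per_million = libsize.astype(float) / 1e6
    rpkm = gene_counts.div(len_kb, axis=0).div(per_million, axis=1)

    spike = counts.spikein_counts()
    spike_rpkm = None
    if len(spike):
        spike = spike.drop(columns=dead, errors="ignore")
        spike_len = lengths.reindex(spike.index)
        if spike_len.notna().all():
            spike_rpkm = spike.div(spike_len.astype(float) / 1e3, axis=0).div(
                per_million, axis=1)
    return ExpressionMatrix(rpkm=rpkm, library_sizes=libsize, spikein_rpkm=spike_rpkm)


def refseq_fraction(mapped_total: int, in_gene_total: int) -> int:
    """Percentage of mapped tags falling in annotated gene regions.

    Rounded to integer percent, e.g. 3,581,044 of 4,567,666 -> 78.
    """
    if mapped_total <= 0:
        raise ValueError("mapped_total must be > 0")
    if not 0 <= in_gene_total <= mapped_total:
        raise ValueError("in_gene_total must lie in [0, mapped_total]")
    return int(round(100.0 * in_gene_total / mapped_total))


def complexity(tag_coordinates) -> float:
    """Mean multiplicity of mapped tags: total tags / distinct (start, end).

    A value of 1.0 means every tag has unique mapping coordinates; higher
    values indicate PCR-duplicate load.
    """
    coords = list(tag_coordinates)
    if not coords:
        raise ValueError("complexity of an empty tag set is undefined")
    return len(coords) / len(set(coords))


def read_tag_coordinates(path: str | Path) -> list[tuple[int, int]]:
    """Read (start, end) pairs from a BED-like 3-column file (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[1, 2],
                     names=["start", "end"], comment="#")
    return list(zip(df["start"].astype(int), df["end"].astype(int)))


def library_summary(mapped: pd.Series, in_gene: pd.Series,
                    mean_multiplicity: pd.Series | None = None) -> pd.DataFrame:
    """Per-cell summary: mapped tags, in-gene tags, in-gene fraction, complexity."""
    out = pd.DataFrame({"mapped_tags": mapped, "in_gene_tags": in_gene})
    out["in_gene_percent"] = [
        refseq_fraction(m, g) for m, g in zip(out["mapped_tags"], out["in_gene_tags"])]
    if mean_multiplicity is not None:
        out["complexity"] = mean_multiplicity
    return out


def compare_replicates(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    min_mean_rpkm: float = 5.0,
    log_epsilon: float = 0.01,
) -> tuple[float, float]:
    """Pearson correlations of per-gene means and CVs between two replicates.

    Means are compared on log10(x + epsilon); CVs on the raw scale.  Only
    genes whose mean passes ``min_mean_rpkm`` in both tables (and whose CV
    is defined) enter the correlation.
    """
    shared = table_a.index.intersection(table_b.index)
    a = table_a.loc[shared]
    b = table_b.loc[shared]
    keep = (a["mean"] > min_mean_rpkm) & (b["mean"] > min_mean_rpkm) \
        & a["cv"].notna() & b["cv"].notna()
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("fewer than 3 shared genes pass the expression floor")
    r_means = stats.pearsonr(np.log10(a["mean"] + log_epsilon),
                             np.log10(b["mean"] + log_epsilon)).statistic
    r_cvs = stats.pearsonr(a["cv"], b["cv"]).statistic
    return float(r_means), float(r_cvs)
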