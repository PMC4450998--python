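"""Readers/writers for on-disk artifacts and the analysis configuration.

Formats handled: gene-by-cell count TSV, MatrixMarket (.mtx) with gene/cell
sidecar files, two-column gene-length TSV, GTF exon annotation, GMT gene
sets, and a YAML analysis configuration.

Counts live in a :class:`CountMatrix` — a thin, validated wrapper around a
pandas DataFrame (genes as rows, cells as columns) plus a per-gene spike-in
flag. All downstream stages consume this container, so the readers are the
only place where on-disk layout matters.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp
import yaml

__all__ = [
    "CountMatrix",
    "AnalysisConfig",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_lengths",
    "read_gene_sets",
    "load_config",
]


class FormatError(ValueError):
    """Malformed input file; message locates the offending element."""


@dataclass
class CountMatrix:
    """Gene-by-cell non-negative integer tag counts.

    Attributes
    ----------
    counts : pandas.DataFrame
        Integer tag counts, index = gene ids, columns = cell ids.
    is_spikein : pandas.Series
        Boolean flag per gene, aligned with ``counts.index``.
    """

    counts: pd.DataFrame
    is_spikein: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] < 1 or c.shape[1] < 1:
            raise ValueError("count matrix needs at least 1 gene and 1 cell")
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()][0]
            raise FormatError(f"duplicate cell id {dup!r}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise FormatError(
                    f"non-integer count at gene {c.index[bad[0]]!r}, "
                    f"cell {c.columns[bad[1]]!r}: {arr[tuple(bad)]}"
                )
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {c.index[bad[0]]!r}, "
                f"cell {c.columns[bad[1]]!r}"
            )
        self.is_spikein = self.is_spikein.reindex(self.counts.index, fill_value=False).astype(bool)

    # convenience views -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cells(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_counts(self) -> pd.DataFrame:
        """Counts restricted to biological (non-spike-in) genes."""
        return self.counts.loc[~self.is_spikein]

    def spikein_counts(self) -> pd.DataFrame:
        """Counts restricted to spike-in rows."""
        return self.counts.loc[self.is_spikein]

    def subset_cells(self, cells: list[str]) -> "CountMatrix":
        missing = set(cells) - set(self.counts.columns)
        if missing:
            raise KeyError(f"cells not in matrix: {sorted(missing)}")
        return CountMatrix(self.counts[cells].copy(), self.is_spikein.copy())


@dataclass
class AnalysisConfig:
    """Thresholds and knobs shared across pipeline stages.

    qc_sd_threshold : spike-in leave-one-out z-score cutoff (cells with any
        |z| above it are discarded).
    min_mean_rpkm : expression floor; genes below it are carried but not
        tested / not used for fold changes.
    control_fold_window : expression-matched controls lie within this fold
        of the tested gene's mean (closed interval).
    max_controls : cap on the matched-control set; excess is subsampled.
    alpha_divergence / alpha_enrichment : raw p-value cutoffs.
    fc_threshold : responder fold-change cutoff (strict inequality).
    pseudocount : added to means before fold changes to tame zeros (rpkm).
    log_epsilon : added inside log10 transforms (rpkm).
    seed : base seed for every stochastic step.
    """

    qc_sd_threshold: float = 2.0
    min_mean_rpkm: float = 5.0
    control_fold_window: float = 2.0
    max_controls: int = 1000
    alpha_divergence: float = 0.05
    alpha_enrichment: float = 0.05
    fc_threshold: float = 2.0
    pseudocount: float = 0.1
    log_epsilon: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("qc_sd_threshold", "min_mean_rpkm", "control_fold_window",
                     "fc_threshold", "pseudocount", "log_epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("alpha_divergence", "alpha_enrichment"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.max_controls < 1:
            raise ValueError("max_controls must be >= 1")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(
    path: str | Path,
    format: str = "tsv",
    spikein_spec: Mapping[str, float] | None = None,
) -> CountMatrix:
    """Read a gene-by-cell count matrix.

    TSV layout: first column gene id, header row of cell ids.  MTX layout:
    ``<stem>.mtx`` plus sidecars ``<stem>.genes.txt`` and ``<stem>.cells.txt``
    with one id per line.  Rows named in ``spikein_spec`` are flagged as
    spike-ins.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[1] == 0:
            raise FormatError(f"{path}: no cell columns found (malformed header?)")
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                bad = df[~df[col].astype(str).str.fullmatch(r"-?\d+")].index
                raise FormatError(
                    f"{path}: non-integer count in column {col!r}"
                    + (f", row {bad[0]!r}" if len(bad) else "")
                )
        vals = df.to_numpy()
        if not np.array_equal(vals, np.round(vals)):
            g, c = np.argwhere(vals != np.round(vals))[0]
            raise FormatError(
                f"{path}: non-integer count {vals[g, c]} at row {df.index[g]!r}, "
                f"column {df.columns[c]!r}"
            )
        counts = df.astype(np.int64)
        counts.index.name = None
    elif format == "mtx":
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        mat = spio.mmread(str(stem) + ".mtx")
        genes = Path(str(stem) + ".genes.txt").read_text().split()
        cells = Path(str(stem) + ".cells.txt").read_text().split()
        dense = np.asarray(mat.todense() if sp.issparse(mat) else mat)
        if dense.shape != (len(genes), len(cells)):
            raise FormatError(
                f"{stem}: matrix shape {dense.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        if not np.array_equal(dense, np.round(dense)):
            g, c = np.argwhere(dense != np.round(dense))[0]
            raise FormatError(
                f"{stem}.mtx: non-integer count at gene {genes[g]!r}, cell {cells[c]!r}"
            )
        counts = pd.DataFrame(dense.astype(np.int64), index=genes, columns=cells)
    else:
        raise ValueError(f"unknown format {format!r}")

    spike_ids = set(spikein_spec) if spikein_spec else set()
    flag = pd.Series([g in spike_ids for g in counts.index], index=counts.index)
    return CountMatrix(counts, flag)


def write_count_matrix(matrix: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a count matrix in the layout :func:`read_count_matrix` expects."""
    path = Path(path)
    if format == "tsv":
        matrix.counts.to_csv(path, sep="\t", index_label="gene")
    elif format == "mtx":
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        spio.mmwrite(str(stem) + ".mtx", sp.coo_matrix(matrix.counts.to_numpy()))
        Path(str(stem) + ".genes.txt").write_text("\n".join(matrix.genes) + "\n")
        Path(str(stem) + ".cells.txt").write_text("\n".join(matrix.cells) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# gene lengths
# ---------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open [start, end) intervals."""
    total = 0
    cur_start, cur_end = None, None
    for s, e in sorted(intervals):
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def read_gene_lengths(path: str | Path, format: str = "tsv") -> pd.Series:
    """Per-gene transcript length in bases.

    TSV: two columns, gene id and length, no header required.  GTF: exon
    features with ``gene_id`` attributes; the length is the size of the
    per-gene union of exon intervals (GTF coordinates are 1-based inclusive).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "length"],
                         comment="#", dtype={"gene": str})
        if df["gene"].iloc[0] == "gene":  # tolerate a header row
            df = df.iloc[1:]
        lengths = pd.to_numeric(df["length"], errors="raise").astype(np.int64)
        lengths.index = df["gene"].to_list()
        if (lengths <= 0).any():
            bad = lengths.index[lengths <= 0][0]
            raise FormatError(f"{path}: non-positive length for gene {bad!r}")
        if lengths.index.has_duplicates:
            dup = lengths.index[lengths.index.duplicated()][0]
            raise FormatError(f"{path}: duplicate gene {dup!r}")
        return lengths
    if format == "gtf":
        cols = ["seqname", "source", "feature", "start", "end",
                "score", "strand", "frame", "attribute"]
        df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
        exons = df[df["feature"] == "exon"]
        per_gene: dict[str, list[tuple[int, int]]] = {}
        for _, row in exons.iterrows():
            m = pd.Series(row["attribute"]).str.extract(r'gene_id "([^"]+)"').iloc[0, 0]
            if pd.isna(m):
                raise FormatError(f"{path}: exon without gene_id: {row['attribute']!r}")
            start, end = int(row["start"]), int(row["end"])
            if end < start:
                raise FormatError(f"{path}: exon end {end} < start {start} for {m!r}")
            # GTF 1-based inclusive -> half-open 0-based
            per_gene.setdefault(m, []).append((start - 1, end))
        return pd.Series({g: _union_length(iv) for g, iv in per_gene.items()},
                         dtype=np.int64)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name, description, member ids, tab-separated.

    Duplicate members within a line collapse; an empty file gives an empty
    mapping.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, _desc, *members = parts
            sets[name] = {m for m in members if m}
    return sets
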