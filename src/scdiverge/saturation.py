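"""Stability of the relative-divergence estimate under reduced depth and
reduced cell numbers.

Depth titration uses binomial thinning: each cell's counts are downsampled
by keeping every tag independently with probability p_c = target_depth /
depth_c, which matches read-level subsampling in its first moment.  Cell
titration subsamples cells without replacement.  Both report, per
expression stratum fixed at full depth, the mean relative divergence at
each grid point averaged over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .divergence import divergence_table
from .io_formats import CountMatrix
from .quantify import compute_rpkm

__all__ = ["DEFAULT_STRATA", "SaturationCurve", "thin_counts",
           "depth_curve", "cell_count_curve"]

# expression strata (rpkm at full depth), lower-inclusive
DEFAULT_STRATA = ((1, 5), (5, 10), (10, 50), (50, 100), (100, 500))


@dataclass
class SaturationCurve:
    """Long-format saturation result.

    axis : "depth" or "cells".
    data : rows (grid_value, stratum, mean_cv, sd_cv, n_genes), where
        mean_cv averages the per-gene CV over the stratum and replicates
        and sd_cv is the across-replicate SD of the stratum mean.
    """

    axis: str
    data: pd.DataFrame


def thin_counts(
    matrix: CountMatrix, target_depth: float, seed: int | np.random.Generator = 0
) -> CountMatrix:
    """Binomially thin each cell to an expected ``target_depth`` gene tags.

    p_c = target_depth / depth_c per cell; cells already at or below the
    target are kept unthinned.  Spike-in rows are thinned with the same
    per-cell probability (they ride along with the library).
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depth = matrix.gene_counts().sum(axis=0).to_numpy(dtype=float)
    p = np.minimum(target_depth / np.maximum(depth, 1.0), 1.0)
    arr = matrix.counts.to_numpy()
    out = arr.copy()
    for j in range(arr.shape[1]):
        if p[j] < 1.0:
            out[:, j] = rng.binomial(arr[:, j], p[j])
    thinned = pd.DataFrame(out, index=matrix.counts.index, columns=matrix.counts.columns)
    return CountMatrix(thinned, matrix.is_spikein.copy())


def _stratify(full_table: pd.DataFrame, strata) -> dict[tuple, pd.Index]:
    """Assign genes to expression strata at full depth and freeze them."""
    out = {}
    for lo, hi in strata:
        idx = full_table.index[(full_table["mean"] >= lo) & (full_table["mean"] < hi)]
        if len(idx) == 0:
            warnings.warn(f"stratum [{lo}, {hi}) rpkm is empty; omitted")
            continue
        out[(lo, hi)] = idx
    return out


def depth_curve(
    matrix: CountMatrix,
    lengths: pd.Series,
    depth_grid: list[float],
    strata=DEFAULT_STRATA,
    replicates: int = 5,
    seed: int = 0,
) -> SaturationCurve:
    """Mean relative divergence per stratum as sequencing depth is titrated.

    Strata are defined once from the full-depth rpkm table; at each grid
    depth the matrix is thinned, rpkm and the divergence table recomputed,
    and the per-stratum mean CV averaged over replicates.
    """
    if sorted(depth_grid) != list(depth_grid):
        raise ValueError("depth_grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    full = divergence_table(compute_rpkm(matrix, lengths))
    strat = _stratify(full, strata)

    rows = []
    for d in depth_grid:
        per_rep = {k: [] for k in strat}
        for _ in range(replicates):
            thinned = thin_counts(matrix, d, rng)
            table = divergence_table(compute_rpkm(thinned, lengths))
            for key, idx in strat.items():
                per_rep[key].append(table.loc[idx, "cv"].mean())
        for (lo, hi), vals in per_rep.items():
            vals = np.asarray(vals, dtype=float)
            rows.append({"grid_value": d, "stratum": f"{lo}-{hi}",
                         "mean_cv": float(np.nanmean(vals)),
                         "sd_cv": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0,
                         "n_genes": len(strat[(lo, hi)])})
    return SaturationCurve(axis="depth", data=pd.DataFrame(rows))


def cell_count_curve(
    matrix: CountMatrix,
    lengths: pd.Series,
    n_grid: list[int],
    strata=DEFAULT_STRATA,
    replicates: int = 20,
    seed: int = 0,
) -> SaturationCurve:
    """Stability of the relative-divergence estimate versus cell number.

    For each n in the grid, sample n cells without replacement and
    recompute the divergence table; report per-stratum mean CV and the
    across-replicate SD of that mean (the estimator's sampling spread).
    """
    if sorted(n_grid) != list(n_grid):
        raise ValueError("n_grid must be strictly increasing")
    if min(n_grid) < 2:
        raise ValueError("need at least 2 cells per subsample")
    if max(n_grid) > matrix.n_cells:
        raise ValueError("n_grid exceeds available cells")
    rng = np.random.default_rng(seed)
    full = divergence_table(compute_rpkm(matrix, lengths))
    strat = _stratify(full, strata)
    cells = np.array(matrix.cells)

    rows = []
    for n in n_grid:
        per_rep = {k: [] for k in strat}
        reps = 1 if n == matrix.n_cells and replicates == 1 else replicates
        for _ in range(reps):
            chosen = list(rng.choice(cells, size=n, replace=False)) \
                if n < matrix.n_cells else list(cells)
            sub = matrix.subset_cells(chosen)
            table = divergence_table(compute_rpkm(sub, lengths))
            for key, idx in strat.items():
                per_rep[key].append(table.loc[idx, "cv"].mean())
        for (lo, hi), vals in per_rep.items():
            vals = np.asarray(vals, dtype=float)
            rows.append({"grid_value": n, "stratum": f"{lo}-{hi}",
                         "mean_cv": float(np.nanmean(vals)),
                         "sd_cv": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0,
                         "n_genes": len(strat[(lo, hi)])})
    return SaturationCurve(axis="cells", data=pd.DataFrame(rows))
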