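"""Spike-in based cell quality control.

Cells receive exogenous spike-in RNA of known input copies at lysis; a
library whose tag count for any spike-in deviates by more than a set
number of standard deviations from the other cells is discarded.  The
deviation is a leave-one-out z-score: each cell is compared against the
mean and sample SD of the remaining cells, by default on the
log10(count + 1) scale because spike-in counts span orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

__all__ = ["CellQCReport", "spikein_zscores", "qc_report", "filter_cells"]


@dataclass
class CellQCReport:
    """Per-cell spike-in QC outcome.

    zscores : cells x spike-ins leave-one-out z-scores.
    passed : boolean per cell; False iff any |z| exceeds the threshold.
    failing_spikeins : per cell, the list of spike-ins that tripped.
    threshold : the SD cutoff used.
    """

    zscores: pd.DataFrame
    passed: pd.Series
    failing_spikeins: pd.Series
    threshold: float


def spikein_zscores(
    matrix: CountMatrix,
    spec: Mapping[str, float],
    scale: str = "log",
) -> pd.DataFrame:
    """Leave-one-out z-scores of spike-in counts, cells x spike-ins.

    For cell c and spike-in s, z = (x_cs - mean of the other cells) / SD of
    the other cells (sample SD, n-1).  If that SD is 0, z is 0 when the
    cell matches the common value and +/-inf otherwise.
    """
    n = matrix.n_cells
    if n < 3:
        raise ValueError("spike-in QC needs at least 3 cells")
    missing = [s for s in spec if s not in matrix.counts.index]
    if missing:
        raise KeyError(f"spike-ins absent from matrix: {missing}")

    x = matrix.counts.loc[list(spec)].to_numpy(dtype=float)  # spikes x cells
    if scale == "log":
        x = np.log10(x + 1.0)
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")

    total = x.sum(axis=1, keepdims=True)
    sumsq = (x ** 2).sum(axis=1, keepdims=True)
    loo_mean = (total - x) / (n - 1)
    # sample variance of the n-1 remaining values
    loo_var = (sumsq - x ** 2 - (n - 1) * loo_mean ** 2) / (n - 2)
    loo_var = np.maximum(loo_var, 0.0)
    loo_sd = np.sqrt(loo_var)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - loo_mean) / loo_sd
    degenerate = loo_sd == 0
    if degenerate.any():
        diff = x - loo_mean
        signed_inf = np.where(diff > 0, np.inf, -np.inf)
        z = np.where(degenerate, np.where(diff == 0, 0.0, signed_inf), z)
    return pd.DataFrame(z.T, index=matrix.cells, columns=list(spec))


def qc_report(zscores: pd.DataFrame, threshold: float = 2.0) -> CellQCReport:
    """Turn a z-score table into pass/fail calls at ``threshold`` SDs."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    tripped = zscores.abs() > threshold
    passed = ~tripped.any(axis=1)
    failing = tripped.apply(lambda row: list(zscores.columns[row]), axis=1)
    return CellQCReport(zscores=zscores, passed=passed,
                        failing_spikeins=failing, threshold=threshold)


def filter_cells(matrix: CountMatrix, report: CellQCReport) -> CountMatrix:
    """Restrict a matrix to the QC-passing cells, order preserved."""
    if list(report.passed.index) != matrix.cells:
        raise ValueError("QC report does not match matrix cells")
    keep = [c for c in matrix.cells if report.passed[c]]
    if not keep:
        raise ValueError(
            "all cells failed spike-in QC; review the SD threshold or scale")
    return matrix.subset_cells(keep)
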