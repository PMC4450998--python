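"""Relative divergence and the expression-matched divergence test.

The relative divergence of a gene is the coefficient of variation of its
rpkm across cells: sample standard deviation (n-1) divided by the mean.
Because the CV falls with expression level, a gene is judged "more" or
"less" diverse only against expression-matched controls: background genes
whose mean lies within a fold window (default two-fold, closed interval)
of the tested gene's mean, capped at ``max_controls`` by uniform
subsampling.

The test itself is a variance-ratio F-test on squared CVs: the statistic
F = cv_gene^2 / median(cv_controls^2) is referred to an F distribution
with (n_cells - 1, n_cells - 1) degrees of freedom, two-sided.  The
median gives a robust center of the matched background; the F family with
equal df is the classical reference for a ratio of variance-like
quantities estimated from the same number of cells.  An empirical
percentile alternative (rank of the gene's CV among its controls) is
available via ``method="percentile"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnalysisConfig
from .quantify import ExpressionMatrix

__all__ = [
    "divergence_table",
    "divergence_table_from_moments",
    "match_controls",
    "divergence_test",
    "classify_divergent",
    "DivergenceCalls",
]


def divergence_table(expr: ExpressionMatrix, min_mean_rpkm: float = 5.0) -> pd.DataFrame:
    """Per-gene mean, SD, relative divergence (cv) and cell count.

    Genes with zero mean get cv = NaN (undefined, not 0).  Genes below the
    expression floor are carried with ``low_expression = True`` rather than
    dropped, so the caller decides what to test.
    """
    if expr.rpkm.shape[1] < 2:
        raise ValueError("divergence needs at least 2 cells (sd undefined)")
    mean = expr.rpkm.mean(axis=1)
    sd = expr.rpkm.std(axis=1, ddof=1)
    cv = sd / mean.where(mean > 0)
    table = pd.DataFrame({
        "mean": mean,
        "sd": sd,
        "cv": cv,
        "n_cells": expr.rpkm.shape[1],
        "low_expression": mean <= min_mean_rpkm,
    })
    return table


def divergence_table_from_moments(
    means: pd.Series, sds: pd.Series, n_cells: int, min_mean_rpkm: float = 5.0
) -> pd.DataFrame:
    """Build a divergence table directly from published (mean, sd) pairs."""
    means = means.astype(float)
    sds = sds.astype(float)
    cv = sds / means.where(means > 0)
    return pd.DataFrame({
        "mean": means, "sd": sds, "cv": cv, "n_cells": n_cells,
        "low_expression": means <= min_mean_rpkm,
    })


def match_controls(
    gene: str,
    table: pd.DataFrame,
    fold_window: float = 2.0,
    max_controls: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Expression-matched control genes for ``gene``.

    Controls are the other genes whose mean falls in the closed interval
    [mean/fold_window, mean*fold_window].  When more than ``max_controls``
    qualify, a uniform sample without replacement of exactly
    ``max_controls`` is drawn (reproducible from ``rng``).  An empty result
    marks the gene untestable.
    """
    if gene not in table.index:
        raise KeyError(f"gene {gene!r} not in table")
    m = table.at[gene, "mean"]
    if not m > 0:
        raise ValueError(f"gene {gene!r} has zero mean; controls undefined")
    lo, hi = m / fold_window, m * fold_window
    eligible = table.index[(table["mean"] >= lo) & (table["mean"] <= hi)
                           & (table.index != gene)]
    eligible = list(eligible)
    if len(eligible) > max_controls:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        eligible = list(rng.choice(eligible, size=max_controls, replace=False))
    return eligible


def divergence_test(
    gene: str,
    controls: list[str],
    table: pd.DataFrame,
    n_cells: int | None = None,
    method: str = "f",
    min_controls: int = 10,
) -> tuple[float, str]:
    """Two-sided test of a gene's relative divergence against its controls.

    Returns ``(p, direction)`` with direction "more" when the gene's CV
    exceeds the control center.  Raises when the gene or the control
    background cannot support a test.
    """
    cv_gene = table.at[gene, "cv"]
    if not np.isfinite(cv_gene):
        raise ValueError(f"gene {gene!r} has undefined cv")
    ctrl_cv = table.loc[controls, "cv"].dropna()
    if len(ctrl_cv) < min_controls:
        raise ValueError(
            f"gene {gene!r}: only {len(ctrl_cv)} controls with defined cv "
            f"(need >= {min_controls})")
    if n_cells is None:
        n_cells = int(table.at[gene, "n_cells"])

    if method == "f":
        med = float(np.median(ctrl_cv ** 2))
        if med == 0:
            raise ValueError(f"gene {gene!r}: control cv^2 median is 0")
        F = cv_gene ** 2 / med
        df = n_cells - 1
        p = 2.0 * min(stats.f.sf(F, df, df), stats.f.cdf(F, df, df))
        p = min(p, 1.0)
        direction = "more" if F > 1 else "less"
        return float(p), direction
    if method == "percentile":
        frac_below = float((ctrl_cv < cv_gene).mean())
        p = 2.0 * min(frac_below, 1.0 - frac_below)
        p = max(min(p, 1.0), 1.0 / (len(ctrl_cv) + 1))
        direction = "more" if frac_below > 0.5 else "less"
        return float(p), direction
    raise ValueError(f"unknown method {method!r}")


@dataclass
class DivergenceCalls:
    """Outcome of classify_divergent.

    results : per tested gene: p, direction, n_controls, significant flag.
    more_diverse / less_diverse : significant gene lists split by direction.
    untestable : genes skipped (no controls, undefined cv, ...) with reason.
    """

    results: pd.DataFrame
    more_diverse: list[str]
    less_diverse: list[str]
    untestable: pd.Series


def classify_divergent(
    table: pd.DataFrame,
    config: AnalysisConfig | None = None,
    method: str = "f",
    alpha: float | None = None,
) -> DivergenceCalls:
    """Run the matched-control divergence test over every eligible gene.

    Eligible genes have mean above the expression floor and a defined CV.
    The control subsampling stream derives from ``config.seed``, so the
    classification is deterministic end to end.  ``alpha`` overrides the
    configured cutoff (0 is allowed and yields empty lists: p < 0 never).
    """
    cfg = config or AnalysisConfig()
    if alpha is None:
        alpha = cfg.alpha_divergence
    rng = np.random.default_rng(cfg.seed)
    rows = []
    untestable = {}
    eligible = table.index[(~table["low_expression"]) & table["cv"].notna()]
    for gene in eligible:
        controls = match_controls(gene, table, cfg.control_fold_window,
                                  cfg.max_controls, rng)
        if not controls:
            untestable[gene] = "no expression-matched controls"
            continue
        try:
            p, direction = divergence_test(gene, controls, table, method=method)
        except ValueError as exc:
            untestable[gene] = str(exc)
            continue
        rows.append({"gene": gene, "p": p, "direction": direction,
                     "n_controls": len(controls),
                     "significant": p < alpha})
    results = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["p", "direction", "n_controls", "significant"])
    sig = results[results["significant"]] if len(results) else results
    more = list(sig.index[sig["direction"] == "more"]) if len(sig) else []
    less = list(sig.index[sig["direction"] == "less"]) if len(sig) else []
    return DivergenceCalls(
        results=results,
        more_diverse=more,
        less_diverse=less,
        untestable=pd.Series(untestable, dtype=object),
    )
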