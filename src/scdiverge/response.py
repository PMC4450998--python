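"""Condition comparisons: fold changes of mean expression and of
relative divergence, responder selection, and quadrant summaries.

Two divergence tables (reference condition A, e.g. untreated; condition
B, e.g. drug-treated) are joined on their shared genes.  For genes whose
mean passes the expression floor in at least one condition:

    mean FC = (mean_B + pc) / (mean_A + pc)        (pc = pseudocount)
    cv FC   = cv_B / cv_A                          (unregularized)

Responders are genes with mean FC above the threshold (induced) or below
its reciprocal (repressed), strict inequalities.  The quadrant summary
counts genes by the signs of (log2 mean FC, log2 cv FC), optionally per
gene group, which exposes e.g. a global loss of divergence (upper-left
enrichment) after treatment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import AnalysisConfig

__all__ = ["compare_conditions", "select_responders", "shift_summary"]


def compare_conditions(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-gene comparison of condition B against reference A.

    Returns a frame with means, CVs, fold changes and a responder class in
    {"induced", "repressed", "unchanged", "ineligible"}.
    """
    cfg = config or AnalysisConfig()
    shared = table_a.index.intersection(table_b.index)
    if len(shared) == 0:
        raise ValueError("condition tables share no genes")
    a = table_a.loc[shared]
    b = table_b.loc[shared]
    pc = cfg.pseudocount

    out = pd.DataFrame(index=shared)
    out["mean_a"] = a["mean"]
    out["mean_b"] = b["mean"]
    out["cv_a"] = a["cv"]
    out["cv_b"] = b["cv"]
    eligible = (a["mean"] > cfg.min_mean_rpkm) | (b["mean"] > cfg.min_mean_rpkm)
    out["mean_fc"] = np.where(eligible, (b["mean"] + pc) / (a["mean"] + pc), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_fc = b["cv"] / a["cv"]
    cv_fc = cv_fc.where(eligible & a["cv"].gt(0) & b["cv"].notna())
    out["cv_fc"] = cv_fc

    cls = np.full(len(shared), "unchanged", dtype=object)
    cls[~eligible.to_numpy()] = "ineligible"
    fc = out["mean_fc"].to_numpy()
    thr = cfg.fc_threshold
    cls[eligible.to_numpy() & (fc > thr)] = "induced"
    cls[eligible.to_numpy() & (fc < 1.0 / thr)] = "repressed"
    out["responder_class"] = cls
    return out


def select_responders(
    cmp: pd.DataFrame, fc_threshold: float = 2.0
) -> tuple[list[str], list[str]]:
    """Genes induced (mean FC > threshold) or repressed (< 1/threshold).

    Strict inequalities: a gene at exactly the threshold is not selected.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    fc = cmp["mean_fc"]
    induced = list(cmp.index[fc > fc_threshold])
    repressed = list(cmp.index[fc < 1.0 / fc_threshold])
    return induced, repressed


def shift_summary(
    cmp: pd.DataFrame,
    gene_groups: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Quadrant counts and medians of (log2 mean FC, log2 cv FC).

    One row per gene group (plus "all"): counts of genes in each quadrant
    of the fold-change plane and the medians of both log2 fold changes.
    Genes with undefined fold changes are excluded; an empty group yields
    zero counts.
    """
    groups = {"all": set(cmp.index)}
    if gene_groups:
        groups.update({k: set(v) for k, v in gene_groups.items()})

    lfc_m = np.log2(cmp["mean_fc"])
    lfc_c = np.log2(cmp["cv_fc"])
    ok = lfc_m.notna() & lfc_c.notna()

    rows = []
    for name, members in groups.items():
        sel = ok & cmp.index.isin(members)
        m, c = lfc_m[sel], lfc_c[sel]
        rows.append({
            "group": name,
            "n": int(sel.sum()),
            "up_up": int(((m > 0) & (c > 0)).sum()),
            "up_down": int(((m > 0) & (c < 0)).sum()),
            "down_up": int(((m < 0) & (c > 0)).sum()),
            "down_down": int(((m < 0) & (c < 0)).sum()),
            "median_log2_mean_fc": float(m.median()) if len(m) else np.nan,
            "median_log2_cv_fc": float(c.median()) if len(c) else np.nan,
        })
    return pd.DataFrame(rows).set_index("group")
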