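"""Synthetic single-cell tag-count cohorts with known ground truth.

The generator emulates the statistical structure of deep single-cell
RNA-seq of cultured cell lines:

* average expression over genes follows a Zipf-like power law of rank;
* counts per gene and cell are negative binomial, so the squared
  coefficient of variation decomposes as CV^2 = 1/mu + phi, reproducing
  the observed decline of CV with mean and its plateau at the per-gene
  overdispersion phi;
* per-cell library-size factors are log-normal;
* three spike-in channels have expected counts linear in their known
  input copy numbers (copies x capture efficiency x cell depth factor);
* optional per-line multipliers and treatment effects shift means and/or
  CVs for chosen gene subsets;
* planted outlier cells have all spike-in expectations multiplied by a
  distortion factor, leaving biological counts untouched, so spike-in QC
  can be validated independently of biology.

Everything is reproducible from the seed, and the returned
:class:`SimulationTruth` records the generative parameters for recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

__all__ = [
    "TreatmentEffect",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_counts",
    "table2_fixture",
]


@dataclass
class TreatmentEffect:
    """Planted effect of a treatment on a gene subset within one line.

    ``mean_fold`` multiplies the NB mean; ``cv_fold`` multiplies the CV
    (implemented exactly on CV^2 = 1/mu + phi, clipping phi at 0).
    """

    line: str
    treatment: str
    genes: list[str]
    mean_fold: float = 1.0
    cv_fold: float = 1.0


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    Defaults mirror the study design this package targets: a ~20,000-gene
    transcriptome whose mean expression is Zipf-like (rank^-1, so rpkm
    spans from a few up to tens of thousands and every expression stratum
    from 1-5 to 100-500 rpkm is populated), ~50 cells per condition
    captured on a microfluidic chip at about a million gene-assigned tags
    per cell, log-normal per-gene overdispersion with median 0.5 (so CVs
    plateau between ~0.3 and ~1 for well-expressed genes), three spike-in
    channels spaced over two orders of magnitude of input copies, and a
    handful of planted QC-outlier cells with 10x distorted spike-ins.
    """

    n_genes: int = 20000
    cells_per_group: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("LINE1", "none"): 50})
    mean_law: str = "powerlaw"  # or "lognormal"
    zipf_exponent: float = -1.0
    top_mean_count: float = 100000.0  # expected counts of the rank-1 gene
    lognormal_mu: float = 2.0
    lognormal_sigma: float = 1.5
    dispersion_median: float = 0.5
    dispersion_sigma: float = 0.5  # 0 -> constant dispersion
    dropout_rate: float = 0.0  # per-gene extra dropout p = exp(-rate * mu)
    depth_sigma: float = 0.3  # log-normal per-cell depth factor
    spikein_copies: dict[str, float] = field(
        default_factory=lambda: {"SPIKE1": 100.0, "SPIKE2": 1000.0, "SPIKE3": 10000.0})
    spikein_efficiency: float = 0.1
    line_mean_fold: dict[str, float] = field(default_factory=dict)
    line_cv_fold: dict[str, float] = field(default_factory=dict)
    # per-line, per-gene log-normal mean multipliers emulating line-specific
    # expression profiles (0 = all lines share one profile)
    line_profile_sigma: float = 0.0
    treatment_effects: list[TreatmentEffect] = field(default_factory=list)
    n_outlier_cells: int = 3
    outlier_distortion: float = 10.0
    gene_length_median: int = 2000
    gene_length_sigma: float = 0.5
    spikein_length: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.cells_per_group or any(n < 1 for n in self.cells_per_group.values()):
            raise ValueError("every (line, treatment) group needs >= 1 cell")
        for name in ("top_mean_count", "spikein_efficiency", "outlier_distortion"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0")
        for name in ("dispersion_median", "dispersion_sigma", "dropout_rate",
                     "depth_sigma", "line_profile_sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        gene_ids = {f"G{i:05d}" for i in range(1, self.n_genes + 1)}
        for eff in self.treatment_effects:
            stray = set(eff.genes) - gene_ids
            if stray:
                raise ValueError(f"treatment effect names unknown genes: {sorted(stray)[:5]}")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated cohort.

    gene_params : per (gene, line, treatment): true NB mean and dispersion,
        and membership flags for planted mean/CV effect sets.
    cell_params : per cell: group labels, depth factor, outlier flag.
    """

    gene_params: pd.DataFrame
    cell_params: pd.DataFrame


def _rank_means(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    ranks = np.arange(1, cfg.n_genes + 1, dtype=float)
    if cfg.mean_law == "powerlaw":
        return cfg.top_mean_count * ranks ** cfg.zipf_exponent
    if cfg.mean_law == "lognormal":
        draws = rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, cfg.n_genes)
        return np.sort(draws)[::-1]
    raise ValueError(f"unknown mean_law {cfg.mean_law!r}")


def _apply_cv_fold(mu: np.ndarray, phi: np.ndarray, fold: float) -> np.ndarray:
    """Return phi' such that CV is multiplied by ``fold`` at mean ``mu``."""
    cv2 = 1.0 / np.maximum(mu, 1e-12) + phi
    new_phi = fold ** 2 * cv2 - 1.0 / np.maximum(mu, 1e-12)
    return np.maximum(new_phi, 0.0)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, dict[str, float], pd.Series, SimulationTruth]:
    """Draw one cohort.

    Returns ``(matrix, cell_metadata, spikein_spec, gene_lengths, truth)``.
    ``cell_metadata`` has columns line/treatment/replicate indexed by cell
    id; ``spikein_spec`` maps spike-in id to known input copies;
    ``gene_lengths`` covers biological genes and spike-ins.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    genes = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]
    spikes = list(cfg.spikein_copies)

    base_mu = _rank_means(cfg, rng)
    if cfg.dispersion_sigma > 0:
        phi = rng.lognormal(np.log(cfg.dispersion_median), cfg.dispersion_sigma, cfg.n_genes)
    else:
        phi = np.full(cfg.n_genes, cfg.dispersion_median)

    # cells ---------------------------------------------------------------
    cell_rows = []
    for (line, treatment), n in cfg.cells_per_group.items():
        for i in range(n):
            cell_rows.append({"line": line, "treatment": treatment,
                              "replicate": "r1", "cell": f"{line}_{treatment}_c{i + 1:03d}"})
    meta = pd.DataFrame(cell_rows).set_index("cell")
    n_cells = len(meta)

    depth = np.exp(rng.normal(0.0, cfg.depth_sigma, n_cells)) if cfg.depth_sigma > 0 \
        else np.ones(n_cells)

    outliers = np.zeros(n_cells, dtype=bool)
    if cfg.n_outlier_cells > 0:
        if cfg.n_outlier_cells > n_cells:
            raise ValueError("more planted outlier cells than cells")
        outliers[rng.choice(n_cells, cfg.n_outlier_cells, replace=False)] = True

    # per-line expression profiles (shared across treatments of a line)
    profiles: dict[str, np.ndarray] = {}
    for line, _treatment in cfg.cells_per_group:
        if line not in profiles:
            profiles[line] = (
                np.exp(rng.normal(0.0, cfg.line_profile_sigma, cfg.n_genes))
                if cfg.line_profile_sigma > 0 else np.ones(cfg.n_genes))

    # per-group gene parameters ------------------------------------------
    group_params: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    truth_rows = []
    for line, treatment in cfg.cells_per_group:
        mu = base_mu * cfg.line_mean_fold.get(line, 1.0) * profiles[line]
        ph = phi.copy()
        if line in cfg.line_cv_fold:
            ph = _apply_cv_fold(mu, ph, cfg.line_cv_fold[line])
        mean_set: set[str] = set()
        cv_set: set[str] = set()
        for eff in cfg.treatment_effects:
            if eff.line == line and eff.treatment == treatment:
                idx = [genes.index(g) for g in eff.genes]
                if eff.mean_fold != 1.0:
                    mu = mu.copy()
                    mu[idx] = mu[idx] * eff.mean_fold
                    mean_set |= set(eff.genes)
                if eff.cv_fold != 1.0:
                    ph = ph.copy()
                    ph[idx] = _apply_cv_fold(mu[idx], ph[idx], eff.cv_fold)
                    cv_set |= set(eff.genes)
        group_params[(line, treatment)] = (mu, ph)
        truth_rows.append(pd.DataFrame({
            "gene": genes, "line": line, "treatment": treatment,
            "true_mean": mu, "true_dispersion": ph,
            "planted_mean_effect": [g in mean_set for g in genes],
            "planted_cv_effect": [g in cv_set for g in genes],
        }))
    gene_truth = pd.concat(truth_rows, ignore_index=True)

    # draw counts ---------------------------------------------------------
    counts = np.zeros((cfg.n_genes, n_cells), dtype=np.int64)
    for j, (cell, row) in enumerate(meta.iterrows()):
        mu, ph = group_params[(row["line"], row["treatment"])]
        lam = mu * depth[j]
        # NB via gamma-Poisson; phi == 0 reduces to Poisson
        lam_eff = lam.astype(float).copy()
        pos = ph > 0
        if pos.any():
            lam_eff[pos] = rng.gamma(1.0 / ph[pos], ph[pos] * lam[pos])
        counts[:, j] = rng.poisson(lam_eff)
    if cfg.dropout_rate > 0:
        keep_p = 1.0 - np.exp(-cfg.dropout_rate * base_mu)  # detection prob
        drop = rng.random((cfg.n_genes, n_cells)) > keep_p[:, None]
        counts[drop] = 0

    # spike-ins -----------------------------------------------------------
    spike_counts = np.zeros((len(spikes), n_cells), dtype=np.int64)
    for si, s in enumerate(spikes):
        expect = cfg.spikein_copies[s] * cfg.spikein_efficiency * depth
        expect = np.where(outliers, expect * cfg.outlier_distortion, expect)
        spike_counts[si] = rng.poisson(expect)

    all_counts = pd.DataFrame(
        np.vstack([counts, spike_counts]),
        index=genes + spikes, columns=meta.index)
    flag = pd.Series([False] * cfg.n_genes + [True] * len(spikes),
                     index=all_counts.index)
    matrix = CountMatrix(all_counts, flag)

    lengths = pd.Series(
        np.concatenate([
            np.round(np.exp(rng.normal(np.log(cfg.gene_length_median),
                                       cfg.gene_length_sigma, cfg.n_genes))).astype(np.int64),
            np.full(len(spikes), cfg.spikein_length, dtype=np.int64),
        ]),
        index=genes + spikes)
    lengths = lengths.clip(lower=100)

    cell_truth = meta.copy()
    cell_truth["depth_factor"] = depth
    cell_truth["is_outlier"] = outliers

    truth = SimulationTruth(gene_params=gene_truth, cell_params=cell_truth)
    spec = dict(cfg.spikein_copies)
    return matrix, meta, spec, lengths, truth


# ---------------------------------------------------------------------------
# printed worked-example fixture
# ---------------------------------------------------------------------------

_TABLE2 = {
    #          LC2/ad      LC2/ad (rep)  LC2/ad-R     PC-9            VMRC-LCD
    "EGFR": [(13, 14),    (17, 15),     (12, 14),    (56, 34),       (0.03, 0.1)],
    "RET":  [(1.9, 5),    (2.0, 4),     (1.6, 5),    (0.005, 0.015), (1.0, 7)],
    "MYC":  [(99, 117),   (84, 95),     (179, 123),  (23, 23),       (0.05, 0.2)],
    "KRAS": [(29, 17),    (27, 19),     (17, 14),    (21, 15),       (26, 19)],
    "TP53": [(22, 15),    (25, 14),     (105, 94),   (126, 43),      (14, 9)],
}
_TABLE2_CONDITIONS = ["LC2/ad", "LC2/ad (rep)", "LC2/ad-R", "PC-9", "VMRC-LCD"]


def table2_fixture() -> dict[str, dict[str, tuple[float, float]]]:
    """Published per-line (mean, sd) rpkm of five cancer-related genes.

    Worked-example inputs for the divergence operations: e.g. EGFR in PC-9
    is (56, 34) and in LC2/ad (13, 14), so the PC-9 relative divergence is
    (34/56)/(14/13) ~ 1.8-fold narrower.
    """
    return {g: dict(zip(_TABLE2_CONDITIONS, vals)) for g, vals in _TABLE2.items()}
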