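"""Shared study design for the analysis drivers.

One synthetic cohort emulating the study layout: three lung-adenocarcinoma
lines plus a drug-treated arm of the first line, with cell numbers matching
the sequenced libraries (43 / 46 / 46 / 28), planted QC-outlier cells, a
treatment effect that suppresses divergence of a housekeeping-like gene
block while inducing/repressing two other blocks, and line-level CV
differences (PC-9 tightest, then VMRC-LCD, then LC2/ad).
"""

from pathlib import Path

from scdiverge import SimulationConfig, TreatmentEffect

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_DIR = RESULTS / "cohort"

N_GENES = 8000

# planted gene blocks (mid-expression ranks, disjoint)
RIBOSOMAL_LIKE = [f"G{i:05d}" for i in range(200, 280)]      # cv halved on drug
INDUCED_BLOCK = [f"G{i:05d}" for i in range(300, 360)]       # mean x4 on drug
REPRESSED_BLOCK = [f"G{i:05d}" for i in range(400, 460)]     # mean /4 on drug
HIGH_CV_BLOCK = [f"G{i:05d}" for i in range(500, 560)]       # cv doubled, all lines


def study_config(seed: int = 2014) -> SimulationConfig:
    return SimulationConfig(
        n_genes=N_GENES,
        top_mean_count=40000,
        cells_per_group={
            ("LC2/ad", "none"): 43,
            ("PC-9", "none"): 46,
            ("VMRC-LCD", "none"): 46,
            ("LC2/ad", "vandetanib"): 28,
        },
        line_cv_fold={"PC-9": 0.75, "VMRC-LCD": 0.9},
        line_profile_sigma=0.4,  # line-specific expression signatures
        treatment_effects=[
            TreatmentEffect("LC2/ad", "vandetanib", RIBOSOMAL_LIKE, cv_fold=0.5),
            TreatmentEffect("LC2/ad", "vandetanib", INDUCED_BLOCK, mean_fold=4.0),
            TreatmentEffect("LC2/ad", "vandetanib", REPRESSED_BLOCK, mean_fold=0.25),
            TreatmentEffect("LC2/ad", "none", HIGH_CV_BLOCK, cv_fold=2.0),
            TreatmentEffect("LC2/ad", "vandetanib", HIGH_CV_BLOCK, cv_fold=2.0),
            TreatmentEffect("PC-9", "none", HIGH_CV_BLOCK, cv_fold=2.0),
            TreatmentEffect("VMRC-LCD", "none", HIGH_CV_BLOCK, cv_fold=2.0),
        ],
        n_outlier_cells=5,
        outlier_distortion=10.0,
        seed=seed,
    )
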