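import numpy as np
import pandas as pd
import pytest

from scdiverge import (AnalysisConfig, CountMatrix, SimulationConfig,
                       compute_rpkm, simulate_counts)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort (1,000 genes, 40 cells) shared read-only."""
    cfg = SimulationConfig(
        n_genes=1000,
        cells_per_group={("L1", "none"): 40},
        n_outlier_cells=2,
        seed=11,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_expr(small_cohort):
    matrix, _meta, _spec, lengths, _truth = small_cohort
    return compute_rpkm(matrix, lengths)


@pytest.fixture()
def tiny_matrix():
    counts = pd.DataFrame(
        [[1, 2, 3], [4, 5, 6], [100, 110, 90]],
        index=["G1", "G2", "S1"], columns=["c1", "c2", "c3"])
    return CountMatrix(counts, pd.Series([False, False, True], counts.index))


@pytest.fixture()
def default_config():
    return AnalysisConfig()
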