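import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from scdiverge import (SimulationConfig, cluster_cells, cluster_purity,
                       compute_rpkm, dendrogram_newick, pca_cells,
                       simulate_counts)
from scdiverge.quantify import ExpressionMatrix


def _expr(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=cells)
    return ExpressionMatrix(rpkm=df, library_sizes=pd.Series(1.0, df.columns))


@pytest.fixture(scope="module")
def two_lines():
    # two lines with strongly separated means on a marker panel
    cfg = SimulationConfig(
        n_genes=400,
        cells_per_group={("LINE_A", "none"): 25, ("LINE_B", "none"): 25},
        line_mean_fold={"LINE_A": 1.0, "LINE_B": 1.0},
        n_outlier_cells=0, seed=41)
    m, meta, _, lengths, _ = simulate_counts(cfg)
    expr = compute_rpkm(m, lengths)
    # separate the lines on a 40-gene panel by shifting one line 8-fold
    panel = [f"G{i:05d}" for i in range(50, 90)]
    b_cells = meta.index[meta["line"] == "LINE_B"]
    expr.rpkm.loc[panel, b_cells] *= 8.0
    return expr, meta, panel


class TestClustering:
    def test_two_lines_recovered_exactly(self, two_lines):
        expr, meta, panel = two_lines
        assign = cluster_cells(expr, panel, k=2)
        purity = cluster_purity(assign, meta["line"], n_permutations=50)
        assert purity["purity"] == 1.0

    def test_duplicated_cells_co_cluster_first(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(2, 1, size=(30, 6))
        doubled = np.hstack([x, x])
        cells = [f"c{i}" for i in range(6)] + [f"d{i}" for i in range(6)]
        expr = _expr(doubled, cells=cells)
        assign = cluster_cells(expr, list(expr.rpkm.index), k=6)
        for i in range(6):
            assert assign.labels[f"c{i}"] == assign.labels[f"d{i}"]

    def test_line_profiles_alone_separate_lines(self):
        # with line-specific expression signatures (and no planted panel),
        # cells cluster by originating line
        cfg = SimulationConfig(
            n_genes=500,
            cells_per_group={("A", "none"): 20, ("B", "none"): 20},
            line_profile_sigma=0.5, n_outlier_cells=0, seed=51)
        m, meta, _, lengths, _ = simulate_counts(cfg)
        expr = compute_rpkm(m, lengths)
        # panel: the 100 best-expressed genes (least shot noise)
        assign = cluster_cells(expr, list(expr.rpkm.index[:100]), k=2)
        out = cluster_purity(assign, meta["line"], n_permutations=50)
        assert out["purity"] >= 0.95

    def test_disjoint_subset_rejected(self, two_lines):
        expr, _, _ = two_lines
        with pytest.raises(ValueError, match="disjoint"):
            cluster_cells(expr, ["NOPE1", "NOPE2"], k=2)

    def test_k_below_two_rejected(self, two_lines):
        expr, _, panel = two_lines
        with pytest.raises(ValueError):
            cluster_cells(expr, panel, k=1)

    def test_excluded_genes_irrelevant(self, two_lines):
        expr, _, panel = two_lines
        a = cluster_cells(expr, panel, k=2).labels
        b = cluster_cells(expr, panel + ["ABSENT"], k=2).labels
        pd.testing.assert_series_equal(a, b)

    def test_newick_export_parses(self, two_lines):
        expr, _, panel = two_lines
        assign = cluster_cells(expr, panel, k=2)
        nwk = dendrogram_newick(assign, expr.cells)
        assert nwk.endswith(";") and nwk.count("(") == len(expr.cells) - 1
        for cell in expr.cells:
            assert cell in nwk


class TestPurity:
    def test_perfect_labels(self):
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=[f"c{i}" for i in range(10)])
        from scdiverge.multivariate import ClusterAssignment
        assign = ClusterAssignment(
            labels=pd.Series([1] * 5 + [2] * 5, index=labels.index),
            k=2, linkage_matrix=np.zeros((0, 4)))
        out = cluster_purity(assign, labels, n_permutations=100)
        assert out["purity"] == 1.0

    def test_single_cluster_two_equal_labels(self):
        from scdiverge.multivariate import ClusterAssignment
        idx = [f"c{i}" for i in range(10)]
        assign = ClusterAssignment(
            labels=pd.Series(1, index=idx), k=1, linkage_matrix=np.zeros((0, 4)))
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=idx)
        out = cluster_purity(assign, labels, n_permutations=10)
        assert out["purity"] == 0.5

    def test_shuffled_labels_sit_at_baseline(self, two_lines):
        expr, meta, panel = two_lines
        assign = cluster_cells(expr, panel, k=2)
        rng = np.random.default_rng(3)
        shuffled = pd.Series(rng.permutation(meta["line"].to_numpy()),
                             index=meta.index)
        out = cluster_purity(assign, shuffled, n_permutations=500, seed=4)
        assert abs(out["purity"] - out["baseline_mean"]) <= 3 * out["baseline_sd"]


class TestPCA:
    def test_rank_one_structure_captured(self):
        rng = np.random.default_rng(5)
        direction = rng.normal(size=20)
        weights = rng.normal(size=40)
        x = np.exp(np.outer(direction, weights) + 0.001 * rng.normal(size=(20, 40)))
        emb = pca_cells(_expr(x), [f"G{i}" for i in range(20)], k=3)
        assert emb.explained_variance_ratio[0] > 0.99
        assert np.all(np.diff(emb.explained_variance_ratio) <= 1e-12)

    def test_invariant_to_cell_order(self, two_lines):
        expr, _, panel = two_lines
        emb1 = pca_cells(expr, panel, k=2)
        perm = list(np.random.default_rng(6).permutation(expr.cells))
        expr2 = ExpressionMatrix(rpkm=expr.rpkm[perm],
                                 library_sizes=expr.library_sizes[perm])
        emb2 = pca_cells(expr2, panel, k=2)
        merged = emb1.coordinates.loc[perm]
        assert np.allclose(merged.to_numpy(), emb2.coordinates.to_numpy(),
                           atol=1e-6)

    def test_lines_separate_on_first_components(self, two_lines):
        expr, meta, panel = two_lines
        emb = pca_cells(expr, panel, k=2)
        score = silhouette_score(emb.coordinates.to_numpy(),
                                 meta.loc[emb.coordinates.index, "line"])
        assert score > 0

    def test_k_below_one_rejected(self, two_lines):
        expr, _, panel = two_lines
        with pytest.raises(ValueError):
            pca_cells(expr, panel, k=0)
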