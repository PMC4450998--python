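"""Cell-level clustering and PCA on configurable gene subsets.

Cells are embedded on log10(rpkm + epsilon)-transformed expression of a
gene subset.  Hierarchical clustering uses Euclidean distance on
per-gene-standardized values with complete linkage, cut at K clusters;
PCA centers each gene and fixes component signs (largest-magnitude
loading positive) so results are deterministic.  Cluster purity against
cell labels is reported with a label-permutation chance baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .quantify import ExpressionMatrix

__all__ = ["ClusterAssignment", "CellEmbedding", "cluster_cells",
           "cluster_purity", "pca_cells", "dendrogram_newick"]


@dataclass
class ClusterAssignment:
    """Cluster labels per cell from cutting a dendrogram at K clusters."""

    labels: pd.Series
    k: int
    linkage_matrix: np.ndarray
    distance: str = "euclidean"
    linkage: str = "complete"


@dataclass
class CellEmbedding:
    """Per-cell coordinates in k principal components.

    ``explained_variance_ratio`` is non-increasing and sums to <= 1.
    """

    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray
    gene_subset: list[str]


def _subset_log_matrix(
    expr: ExpressionMatrix, gene_subset, epsilon: float
) -> pd.DataFrame:
    subset = [g for g in gene_subset if g in expr.rpkm.index]
    if not subset:
        raise ValueError("gene subset is disjoint from the expression matrix")
    return np.log10(expr.rpkm.loc[subset] + epsilon)


def cluster_cells(
    expr: ExpressionMatrix,
    gene_subset,
    k: int,
    linkage: str = "complete",
    epsilon: float = 0.01,
) -> ClusterAssignment:
    """Agglomerative clustering of cells on a gene subset.

    Works on gene-standardized log expression (genes with zero variance
    are left centered only).  Deterministic given data and settings.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    logx = _subset_log_matrix(expr, gene_subset, epsilon)
    if k > logx.shape[1]:
        raise ValueError("k exceeds the number of cells")
    sd = logx.std(axis=1, ddof=1)
    z = logx.sub(logx.mean(axis=1), axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    # observations = cells
    Z = hierarchy.linkage(z.T.to_numpy(), method=linkage, metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels, index=expr.cells, name="cluster"),
        k=k, linkage_matrix=Z, linkage=linkage)


def cluster_purity(
    assignment: ClusterAssignment,
    labels: pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Purity of a clustering against cell labels, with a permutation baseline.

    purity = (1/n) * sum over clusters of the majority-label count.  The
    baseline is the mean purity over label permutations; a clustering that
    merely reflects chance sits at the baseline.
    """
    labels = labels.reindex(assignment.labels.index)
    if labels.isna().any():
        raise ValueError("labels missing for some cells")
    n = len(labels)

    def _purity(lbl: np.ndarray) -> float:
        total = 0
        for cl in np.unique(assignment.labels):
            members = lbl[assignment.labels.to_numpy() == cl]
            _, counts = np.unique(members, return_counts=True)
            total += counts.max()
        return total / n

    observed = _purity(labels.to_numpy())
    rng = np.random.default_rng(seed)
    arr = labels.to_numpy().copy()
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        rng.shuffle(arr)
        perm[i] = _purity(arr)
    degenerate = assignment.k == 1 and labels.nunique() == 1
    return {
        "purity": float(observed),
        "baseline_mean": float(perm.mean()),
        "baseline_sd": float(perm.std(ddof=1)),
        "degenerate": bool(degenerate),
    }


def pca_cells(
    expr: ExpressionMatrix,
    gene_subset,
    k: int,
    epsilon: float = 0.01,
) -> CellEmbedding:
    """PCA of cells on log-transformed, per-gene-centered expression.

    Component signs follow the largest-magnitude-loading-positive
    convention, so the embedding is invariant to cell order (up to that
    fixed rule).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    logx = _subset_log_matrix(expr, gene_subset, epsilon)
    X = logx.sub(logx.mean(axis=1), axis=0).T.to_numpy()  # cells x genes
    k_eff = min(k, min(X.shape))
    pca = PCA(n_components=k_eff, svd_solver="full")
    coords = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(k_eff):
        j = np.argmax(np.abs(pca.components_[i]))
        if pca.components_[i, j] < 0:
            pca.components_[i] *= -1
            coords[:, i] *= -1
    return CellEmbedding(
        coordinates=pd.DataFrame(
            coords, index=expr.cells,
            columns=[f"PC{i + 1}" for i in range(k_eff)]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        gene_subset=list(logx.index))


def dendrogram_newick(assignment: ClusterAssignment, leaf_names: list[str]) -> str:
    """Export the clustering dendrogram as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(assignment.linkage_matrix)

    def _recurse(node, parent_dist):
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{parent_dist - node.dist:.6g}"
        left = _recurse(node.left, node.dist)
        right = _recurse(node.right, node.dist)
        return f"({left},{right}):{parent_dist - node.dist:.6g}"

    return f"({_recurse(tree.left, tree.dist)},{_recurse(tree.right, tree.dist)});"
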