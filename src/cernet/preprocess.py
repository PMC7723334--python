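"""Normalization and exploratory structure: quantile normalization,
gene-wise median centering, average-linkage hierarchical clustering, PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .io import ExpressionMatrix


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the same value distribution.

    The shared distribution is the row-wise mean of the sorted columns;
    ties within a column receive the mean of the normalized values they
    would occupy.
    """
    values = matrix.values.to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("empty expression matrix")
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # tied inputs get the mean of the reference values they span
        _, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(matrix.species, df, dict(matrix.condition_of))


def median_center_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature's median so every row has median 0."""
    df = matrix.values.sub(matrix.values.median(axis=1), axis=0)
    return ExpressionMatrix(matrix.species, df, dict(matrix.condition_of))


@dataclass
class Dendrogram:
    """Average-linkage (UPGMA) agglomeration result.

    ``linkage`` is a scipy linkage matrix; ``labels`` name the leaves in
    original order.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> dict[str, int]:
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - (node.dist if not node.is_leaf() else 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def hierarchical_cluster(
    matrix: ExpressionMatrix, axis: str = "samples", distance: str = "euclidean"
) -> Dendrogram:
    """UPGMA clustering of samples or features.

    ``distance`` is ``euclidean`` or ``one_minus_pearson``.
    """
    if axis == "samples":
        data = matrix.values.to_numpy(dtype=float).T
        labels = list(matrix.values.columns)
    elif axis == "features":
        data = matrix.values.to_numpy(dtype=float)
        labels = list(matrix.values.index)
    else:
        raise ValueError(f"axis must be 'samples' or 'features', got {axis!r}")
    if len(labels) < 2:
        raise ValueError("need >= 2 items to cluster")
    if distance == "euclidean":
        dists = pdist(data, metric="euclidean")
    elif distance == "one_minus_pearson":
        dists = pdist(data, metric="correlation")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    link = hierarchy.linkage(dists, method="average")
    return Dendrogram(link, labels)


@dataclass
class PCAResult:
    scores: pd.DataFrame                # samples x components
    loadings: pd.DataFrame              # features x components
    explained_variance_ratio: np.ndarray


def pca(matrix: ExpressionMatrix, n_components: int = 2) -> PCAResult:
    """Column-centered SVD with samples as observations."""
    data = matrix.values.to_numpy(dtype=float).T  # samples x features
    bound = min(data.shape[0] - 1, data.shape[1])
    if not (1 <= n_components <= bound):
        raise ValueError(f"n_components must be in [1, {bound}]")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(data)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.values.columns, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=matrix.values.index, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )
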