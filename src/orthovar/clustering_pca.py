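"""Sample embedding conventions: hierarchical clustering and PCA.

Hierarchical clustering of samples uses complete linkage on one of two
distances: ``corr_vector`` — each sample is represented by its row of the
sample-correlation matrix and the distance between two samples is
1 − |r| between those correlation vectors — or plain ``euclidean`` on
log-expression. PCA standardizes each gene across samples (center and
scale) before the singular value decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_data import LogExpressionMatrix
from .network_modularity import sample_correlations


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge tree over samples."""

    labels: tuple[str, ...]
    linkage: np.ndarray          # scipy linkage matrix
    method: str
    distance: str

    def to_newick(self) -> str:
        """Newick with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height - 0.0:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:g}"

        root = tree
        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


@dataclass(frozen=True)
class PcaResult:
    """Scores (samples × components), loadings (genes × components), variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def hcluster_samples(
    mat: LogExpressionMatrix, mode: str = "corr_vector", absolute: bool = True
) -> Dendrogram:
    """Complete-linkage clustering of samples.

    ``corr_vector`` uses 1 − |r| (or 1 − r with ``absolute=False``) between
    samples' correlation-vector profiles; ``euclidean`` clusters the raw
    log-expression columns.
    """
    ids = mat.design.sample_ids()
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    if mode == "corr_vector":
        profiles = sample_correlations(mat).to_numpy()
        r = np.corrcoef(profiles)
        d = 1 - (np.abs(r) if absolute else r)
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2, 0.0, None)
        z = hierarchy.linkage(squareform(d, checks=False), method="complete")
        dist_label = "1-|r| on correlation vectors" if absolute else "1-r on correlation vectors"
    elif mode == "euclidean":
        z = hierarchy.linkage(mat.values.T, method="complete", metric="euclidean")
        dist_label = "euclidean on log expression"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Dendrogram(tuple(ids), z, "complete", dist_label)


def pca_samples(
    mat: LogExpressionMatrix,
    center: bool = True,
    scale: bool = True,
    n_components: int = 3,
) -> PcaResult:
    """PCA of samples in gene space with per-gene standardization.

    Constant genes are dropped (with a warning) when scaling. The sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    ids = mat.design.sample_ids()
    x = mat.values.astype(float)
    gene_ids = np.array(mat.gene_ids)
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    if scale:
        sd = x.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {(~keep).sum()} constant gene(s) before scaling")
        x = x[keep] / sd[keep, None]
        gene_ids = gene_ids[keep]
    n_max = min(len(ids), x.shape[0])
    if n_components > n_max:
        warnings.warn(f"truncating to {n_max} components")
        n_components = n_max
    # samples in rows for the SVD: X^T = U S V^T; scores = U S
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    k = n_components
    loadings = vt[:k].T                  # genes × k
    scores = u[:, :k] * s[:k]            # samples × k
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    ev = s**2
    ratio = ev[:k] / ev.sum() if ev.sum() > 0 else np.zeros(k)
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        pd.DataFrame(scores, index=ids, columns=comp_names),
        pd.DataFrame(loadings, index=gene_ids, columns=comp_names),
        ratio,
    )
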