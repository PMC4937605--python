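"""Newman modularity of thresholded sample-correlation networks.

Samples are nodes; an edge joins two samples whose Pearson correlation of
log-expression exceeds a threshold. Given a node labeling (organ or
species), the modularity

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / (2m)] * delta(c_i, c_j)

measures how preferentially edges fall within label groups relative to a
degree-preserving random null. Comparing Q under the organ labeling with Q
under the species labeling, across a grid of network densities, quantifies
which factor dominates transcriptome clustering without any dimensionality
reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import LogExpressionMatrix


@dataclass(frozen=True)
class SampleNetwork:
    """A binary, undirected, self-loop-free graph over samples."""

    nodes: tuple[str, ...]
    adjacency: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node count")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-connections must be 0")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        object.__setattr__(self, "adjacency", a.astype(float))

    @property
    def m(self) -> int:
        """Number of edges."""
        return int(self.adjacency.sum() / 2)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def density(self) -> float:
        n = len(self.nodes)
        return self.m / (n * (n - 1) / 2)

    def edge_list(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(np.triu(self.adjacency, k=1))
        return [(self.nodes[i], self.nodes[j]) for i, j in zip(rows, cols)]


def sample_correlations(mat: LogExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between every pair of samples over all genes."""
    v = mat.values
    sds = v.std(axis=0)
    if np.any(sds == 0):
        bad = [mat.design.sample_ids()[j] for j in np.where(sds == 0)[0]]
        raise ValueError(f"constant sample column(s): {bad}")
    corr = np.corrcoef(v, rowvar=False)
    ids = mat.design.sample_ids()
    return pd.DataFrame(corr, index=ids, columns=ids)


def build_network(
    corr: pd.DataFrame, threshold: float, strict: bool = True
) -> SampleNetwork:
    """Threshold a correlation matrix into a binary network.

    An edge joins i ≠ j when corr_ij > threshold (strict, the default) or
    corr_ij ≥ threshold.
    """
    c = corr.to_numpy()
    if not np.allclose(c, c.T):
        raise ValueError("correlation matrix must be symmetric")
    a = (c > threshold) if strict else (c >= threshold)
    a = a.astype(int)
    np.fill_diagonal(a, 0)
    return SampleNetwork(tuple(corr.index), a, threshold)


def modularity(net: SampleNetwork, grouping: dict[str, str] | list[str]) -> float:
    """Newman modularity of the network under the given node labeling.

    The double sum runs over all ordered node pairs including i = j (the
    diagonal contributes only the null-model term since A_ii = 0).
    """
    if isinstance(grouping, dict):
        labels = [grouping[n] for n in net.nodes]
    else:
        labels = list(grouping)
        if len(labels) != len(net.nodes):
            raise ValueError("grouping length does not match node count")
    m = net.m
    if m == 0:
        raise ValueError("modularity undefined for an edgeless network")
    k = net.degrees
    a = net.adjacency
    lab = np.asarray(labels)
    same = lab[:, None] == lab[None, :]
    q = ((a - np.outer(k, k) / (2 * m)) * same).sum() / (2 * m)
    return float(q)


def thresholds_for_edge_counts(
    corr: pd.DataFrame, edge_targets: list[int]
) -> list[tuple[float, int]]:
    """Map target edge counts to thresholds via correlation order statistics.

    The threshold for a target of e edges is placed midway between the e-th
    and (e+1)-th largest off-diagonal correlations, so exactly e pairs exceed
    it (ties can make some exact counts unattainable; the nearest achievable
    count is used). Returns (threshold, achieved_edges) per target.
    """
    c = corr.to_numpy()
    n = c.shape[0]
    offdiag = np.sort(c[np.triu_indices(n, k=1)])[::-1]
    total = offdiag.size
    out = []
    for e in edge_targets:
        e = int(min(max(e, 0), total))
        if e == 0:
            thr = float(offdiag[0]) + 1.0
        elif e == total:
            thr = float(offdiag[-1]) - 1.0
        else:
            thr = float((offdiag[e - 1] + offdiag[e]) / 2)
        achieved = int((offdiag > thr).sum())
        out.append((thr, achieved))
    return out


def modularity_curve(
    corr: pd.DataFrame,
    organ_labels: dict[str, str],
    species_labels: dict[str, str],
    edge_grid: list[int],
) -> pd.DataFrame:
    """Q under both labelings across a grid of target edge counts.

    Returns a DataFrame with columns threshold, edges, density, Q_organ,
    Q_species; rows follow the edge grid (nearest achievable edge counts
    under correlation ties).
    """
    n = corr.shape[0]
    rows = []
    for thr, edges in thresholds_for_edge_counts(corr, edge_grid):
        if edges == 0:
            continue
        net = build_network(corr, thr)
        rows.append(
            {
                "threshold": thr,
                "edges": net.m,
                "density": net.m / (n * (n - 1) / 2),
                "Q_organ": modularity(net, organ_labels),
                "Q_species": modularity(net, species_labels),
            }
        )
    return pd.DataFrame(rows)
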