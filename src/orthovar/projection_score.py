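"""Projection-score selection of the genes driving sample separation.

Gene subsets are formed by thresholding each gene's variance across samples
as a fraction of the maximum gene variance. For a subset, the alpha
statistic is the square root of the fraction of total variance captured by
the first d principal components of the (per-gene standardized) submatrix.
The projection score of a subset is alpha(observed) minus the mean alpha
over permuted datasets in which each gene's values are independently
shuffled across samples — destroying sample structure while preserving each
gene's marginal distribution. The subset with the highest score is the most
informative for a d-dimensional PCA view.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .core_data import LogExpressionMatrix, subset_genes


@dataclass(frozen=True)
class SubsetGrid:
    """Nested gene subsets from variance-ratio thresholds (high ⊆ low)."""

    ratios: tuple[float, ...]
    subsets: dict[float, tuple[str, ...]]


@dataclass(frozen=True)
class ProjectionScoreResult:
    """Scores per threshold plus the selected subset."""

    ratios: tuple[float, ...]
    subset_sizes: tuple[int, ...]
    alphas: tuple[float, ...]
    null_alphas: tuple[float, ...]
    null_sems: tuple[float, ...]
    scores: tuple[float, ...]
    selected_ratio: float
    selected_genes: tuple[str, ...]
    d: int
    n_perm: int
    seed: int


def variance_subsets(
    mat: LogExpressionMatrix, ratio_grid: list[float], min_size: int = 4
) -> SubsetGrid:
    """Gene subsets whose variance ≥ ratio × max gene variance.

    Thresholds yielding fewer than ``min_size`` genes are dropped with a
    warning (a PCA with d components needs more genes than components).
    """
    ratios = sorted(set(float(r) for r in ratio_grid))
    if any(r <= 0 or r > 1 for r in ratios):
        raise ValueError("ratios must lie in (0, 1]")
    variances = mat.values.var(axis=1, ddof=1)
    vmax = variances.max()
    if vmax == 0:
        raise ValueError("all genes are constant")
    gene_ids = np.array(mat.gene_ids)
    kept_ratios, subsets = [], {}
    for r in ratios:
        sel = tuple(gene_ids[variances >= r * vmax])
        if len(sel) < min_size:
            warnings.warn(f"ratio {r} keeps only {len(sel)} genes; dropped")
            continue
        kept_ratios.append(r)
        subsets[r] = sel
    if not kept_ratios:
        raise ValueError("no threshold leaves enough genes")
    return SubsetGrid(tuple(kept_ratios), subsets)


def _standardize_rows(x: np.ndarray, scale: bool) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    if scale:
        sd = x.std(axis=1, ddof=1, keepdims=True)
        keep = sd[:, 0] > 0
        x = x[keep] / sd[keep]
    return x


def alpha_statistic(values: np.ndarray, d: int = 3, scale: bool = True) -> float:
    """sqrt(variance fraction captured by the top d PCs) of a gene submatrix.

    Rows (genes) are centered and, by default, scaled before the
    decomposition. Returns 1 when the matrix rank is ≤ d.
    """
    if d < 1:
        raise ValueError("d must be ≥ 1")
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with ≥ 2 genes")
    x = _standardize_rows(x, scale)
    if x.shape[0] == 0 or not np.any(x):
        raise ValueError("all genes constant after centering")
    sv = np.linalg.svd(x, compute_uv=False)
    ev = sv**2
    total = ev.sum()
    return float(np.sqrt(ev[:d].sum() / total))


def compute_projection_score(
    mat: LogExpressionMatrix,
    subset: tuple[str, ...] | list[str],
    d: int = 3,
    n_perm: int = 100,
    seed: int = 0,
    scale: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float, float]:
    """Projection score of a gene subset.

    Returns (score, observed_alpha, mean_null_alpha, null_sem); score =
    observed − mean over ``n_perm`` within-gene permutations, and null_sem
    is the Monte-Carlo standard error of that mean. Deterministic for a
    fixed seed.
    """
    sub = subset_genes(mat, list(subset))
    obs = alpha_statistic(sub.values, d=d, scale=scale)
    if rng is None:
        rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for p in range(n_perm):
        perm = np.array([rng.permutation(row) for row in sub.values])
        nulls[p] = alpha_statistic(perm, d=d, scale=scale)
    null_mean = float(nulls.mean())
    null_sem = float(nulls.std(ddof=1) / np.sqrt(n_perm)) if n_perm > 1 else 0.0
    return obs - null_mean, obs, null_mean, null_sem


def select_informative_genes(
    mat: LogExpressionMatrix,
    ratio_grid: list[float] | None = None,
    d: int = 3,
    n_perm: int = 100,
    seed: int = 0,
    scale: bool = True,
) -> ProjectionScoreResult:
    """Evaluate the projection score across the grid; return the best subset.

    Default grid: 30 logarithmically spaced ratios from 1e-4 to 1. Score
    differences smaller than the permutation Monte-Carlo standard error are
    not resolvable, so every subset within one null standard error of the
    maximum counts as tied and the largest tied subset is returned.
    """
    if ratio_grid is None:
        ratio_grid = list(np.logspace(-4, 0, 30))
    grid = variance_subsets(mat, ratio_grid, min_size=d + 1)
    rng = np.random.default_rng(seed)
    ratios, sizes, alphas, null_means, sems, scores = [], [], [], [], [], []
    for r in grid.ratios:
        genes = grid.subsets[r]
        score, obs, null_mean, sem = compute_projection_score(
            mat, genes, d=d, n_perm=n_perm, scale=scale, rng=rng
        )
        ratios.append(r)
        sizes.append(len(genes))
        alphas.append(obs)
        null_means.append(null_mean)
        sems.append(sem)
        scores.append(score)
    best_i = int(np.argmax(scores))
    # two scores differ only through independent null-mean estimates, so the
    # resolvable difference is the SE of the difference
    candidates = [
        i for i, s in enumerate(scores)
        if s >= scores[best_i] - np.hypot(sems[i], sems[best_i])
    ]
    idx = min(candidates, key=lambda i: (-sizes[i], ratios[i]))
    sel_ratio = ratios[idx]
    return ProjectionScoreResult(
        tuple(ratios), tuple(sizes), tuple(alphas), tuple(null_means),
        tuple(sems), tuple(scores), sel_ratio, grid.subsets[sel_ratio], d, n_perm, seed,
    )
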