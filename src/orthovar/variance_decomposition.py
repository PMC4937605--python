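"""Per-gene two-factor variance decomposition and SVG/TVG classification.

For each gene, expression on log10 scale over a balanced organ × species grid
is modelled additively,

    y_ij = mu + org_i + spc_j + eps_ij ,

and the total sum of squares about the grand mean splits exactly into an
organ term, a species term, and a residual:

    SST = SSO + SSS + SSR
    SSO = n_s * sum_i (ybar_i. - ybar..)^2
    SSS = n_o * sum_j (ybar_.j - ybar..)^2
    SSR = sum_ij (y_ij - ybar_i. - ybar_.j + ybar..)^2

The proportions p_o = SSO/SST, p_s = SSS/SST, p_r = SSR/SST are the per-gene
relative contributions of organ, species, and noise. Balance makes the
split orthogonal, so no fitting or ordering choice is involved.

Classification: genes whose dynamic range (orders of magnitude between max
and min linear expression, with pseudocount) falls below ``dr_min`` are
*constrained*; among the rest, genes with p_o + p_s ≥ ``explained_min`` are
TVG when p_o ≥ fold·p_s, SVG when p_s ≥ fold·p_o, otherwise
*other_unconstrained*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import DEFAULT_PSEUDOCOUNT, LogExpressionMatrix, SampleDesign


@dataclass(frozen=True)
class GeneDecomposition:
    """Sums of squares and variance proportions for one gene.

    Proportions are NaN when the gene has zero total variance.
    """

    gene_id: str
    sst: float
    sso: float
    sss: float
    ssr: float
    p_o: float
    p_s: float
    p_r: float


@dataclass(frozen=True)
class ClassificationThresholds:
    """Thresholds for the constrained / TVG / SVG / other split.

    dr_min
        Minimum dynamic range in orders of magnitude (default 2).
    explained_min
        Minimum p_o + p_s for a gene to be factor-dominated (default 0.75).
    fold
        Minimum dominance ratio between the two proportions (default 2).
    inclusive
        Whether comparisons are ≥ (default) or strict.
    """

    dr_min: float = 2.0
    explained_min: float = 0.75
    fold: float = 2.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if min(self.dr_min, self.explained_min, self.fold) <= 0:
            raise ValueError("all thresholds must be positive")


def decompose_gene(grid: np.ndarray, gene_id: str = "") -> GeneDecomposition:
    """Decompose one gene's n_o × n_s grid (organs in rows, species in columns)."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-dimensional (organs × species)")
    if not np.all(np.isfinite(grid)):
        raise ValueError("non-finite value in grid")
    n_o, n_s = grid.shape
    grand = grid.mean()
    organ_means = grid.mean(axis=1)
    species_means = grid.mean(axis=0)
    sst = float(np.sum((grid - grand) ** 2))
    sso = float(n_s * np.sum((organ_means - grand) ** 2))
    sss = float(n_o * np.sum((species_means - grand) ** 2))
    resid = grid - organ_means[:, None] - species_means[None, :] + grand
    ssr = float(np.sum(resid**2))
    if sst > 0:
        p_o, p_s, p_r = sso / sst, sss / sst, ssr / sst
    else:
        p_o = p_s = p_r = float("nan")
    return GeneDecomposition(gene_id, sst, sso, sss, ssr, p_o, p_s, p_r)


def decompose_all(mat: LogExpressionMatrix) -> pd.DataFrame:
    """Decompose every gene; returns a DataFrame indexed by gene_id.

    Columns: sst, sso, sss, ssr, p_o, p_s, p_r. Vectorized over genes.
    """
    n_o, n_s = mat.design.n_o, mat.design.n_s
    # rows × (n_s, n_o) → (genes, organs, species)
    grids = mat.values.reshape(mat.n_genes, n_s, n_o).transpose(0, 2, 1)
    if not np.all(np.isfinite(grids)):
        raise ValueError("non-finite value in matrix")
    grand = grids.mean(axis=(1, 2), keepdims=True)
    om = grids.mean(axis=2, keepdims=True)
    sm = grids.mean(axis=1, keepdims=True)
    sst = ((grids - grand) ** 2).sum(axis=(1, 2))
    sso = n_s * ((om - grand) ** 2).sum(axis=(1, 2))
    sss = n_o * ((sm - grand) ** 2).sum(axis=(1, 2))
    ssr = ((grids - om - sm + grand) ** 2).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        p_o = np.where(sst > 0, sso / sst, np.nan)
        p_s = np.where(sst > 0, sss / sst, np.nan)
        p_r = np.where(sst > 0, ssr / sst, np.nan)
    return pd.DataFrame(
        {"sst": sst, "sso": sso, "sss": sss, "ssr": ssr,
         "p_o": p_o, "p_s": p_s, "p_r": p_r},
        index=pd.Index(list(mat.gene_ids), name="gene_id"),
    )


def mean_proportions(decomp: pd.DataFrame) -> dict[str, float]:
    """Mean p_o/p_s/p_r over genes with nonzero total variance."""
    ok = decomp["sst"] > 0
    return {
        "mean_p_o": float(decomp.loc[ok, "p_o"].mean()),
        "mean_p_s": float(decomp.loc[ok, "p_s"].mean()),
        "mean_p_r": float(decomp.loc[ok, "p_r"].mean()),
        "n_zero_variance": int((~ok).sum()),
    }


def residual_cdf(decomp: pd.DataFrame, bins: np.ndarray | None = None) -> pd.DataFrame:
    """Cumulative proportion of genes below each residual-variance bin edge."""
    ok = decomp["sst"] > 0
    p_r = decomp.loc[ok, "p_r"].to_numpy()
    if bins is None:
        bins = np.linspace(0.0, 1.0, 21)
    cum = [(p_r < b).mean() for b in bins]
    return pd.DataFrame({"p_r_bin": bins, "cumulative_fraction": cum})


def dynamic_range(
    linear_values: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Orders of magnitude between a gene's max and min linear expression.

    Computed as log10(max + pseudocount) − log10(min + pseudocount); the
    pseudocount bounds the range for genes that hit zero.
    """
    v = np.asarray(linear_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if np.any(v < 0):
        raise ValueError("linear expression must be non-negative")
    return float(np.log10(v.max() + pseudocount) - np.log10(v.min() + pseudocount))


def dynamic_ranges(values: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Row-wise dynamic range for a genes × samples linear matrix."""
    v = np.asarray(values, dtype=float)
    return np.log10(v.max(axis=1) + pseudocount) - np.log10(v.min(axis=1) + pseudocount)


def classify_genes(
    decomp: pd.DataFrame,
    dr: pd.Series | np.ndarray,
    thr: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Assign each gene a class: TVG, SVG, other_unconstrained, or constrained.

    Returns a DataFrame with the class plus intermediate masks:
    ``unconstrained`` (passed the dynamic-range filter), ``explained``
    (p_o + p_s over the threshold), and the pre-intersection dominance
    masks ``organ_dominated`` / ``species_dominated`` that ignore the
    dynamic-range filter (the counts reported before intersecting with
    unconstrained genes).
    """
    dr = np.asarray(dr, dtype=float)
    if dr.shape[0] != len(decomp):
        raise ValueError("decomposition table and dynamic ranges cover different gene sets")

    def ge(a, b):
        return a >= b if thr.inclusive else a > b

    p_o = decomp["p_o"].to_numpy()
    p_s = decomp["p_s"].to_numpy()
    defined = decomp["sst"].to_numpy() > 0
    unconstrained = ge(dr, thr.dr_min)
    with np.errstate(invalid="ignore"):
        explained = defined & ge(p_o + p_s, thr.explained_min)
        organ_dom = explained & ge(p_o, thr.fold * p_s)
        species_dom = explained & ge(p_s, thr.fold * p_o)

    cls = np.where(
        ~unconstrained,
        "constrained",
        np.where(
            organ_dom, "TVG", np.where(species_dom, "SVG", "other_unconstrained")
        ),
    )
    return pd.DataFrame(
        {
            "gene_class": cls,
            "unconstrained": unconstrained,
            "explained": explained,
            "organ_dominated": organ_dom,
            "species_dominated": species_dom,
        },
        index=decomp.index,
    )


def _group_scale(values: np.ndarray, design: SampleDesign, by: str) -> np.ndarray:
    """Center and scale each gene within each level of ``by`` (organ|species)."""
    labels = np.array(design.grouping(by))
    out = np.empty_like(values)
    for lev in (design.organs if by == "organ" else design.species):
        cols = labels == lev
        block = values[:, cols]
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        centered = block - mean
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(sd > 0, centered / sd, 0.0)
        out[:, cols] = scaled
    return out


def remove_factor_variance(mat: LogExpressionMatrix, factor: str) -> LogExpressionMatrix:
    """Cancel one factor's variance by per-level centering and scaling.

    ``factor='organ'``: for each gene and organ, center/scale the values
    across species, so a re-decomposition gives SSO = 0 for every gene.
    ``factor='species'``: symmetric, giving SSS = 0. Zero-variance groups
    map to zeros.
    """
    if factor not in ("organ", "species"):
        raise ValueError("factor must be 'organ' or 'species'")
    out = _group_scale(mat.values, mat.design, factor)
    return _build_centered(mat, out)


def _build_centered(mat: LogExpressionMatrix, values: np.ndarray) -> LogExpressionMatrix:
    # centered/scaled data can be negative without bound; bypass the
    # pseudocount floor check by constructing with a floor below the data
    floor = min(float(values.min()), 0.0)
    pseudo = 10.0 ** (floor - 1.0)
    return LogExpressionMatrix(mat.gene_ids, values, mat.design, pseudocount=pseudo)


def standardize_within_sample(mat: LogExpressionMatrix) -> LogExpressionMatrix:
    """Center and scale each sample (column) to mean 0, sd 1 across genes."""
    v = mat.values
    mean = v.mean(axis=0, keepdims=True)
    sd = v.std(axis=0, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = [mat.design.sample_ids()[j] for j in np.where(sd[0] == 0)[0]]
        raise ValueError(f"constant sample column(s): {bad}")
    return _build_centered(mat, (v - mean) / sd)


def pairwise_species_decomposition(
    mat: LogExpressionMatrix,
    reference: str,
    exclude_organs: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Human-vs-each-species style decomposition on 2-species submatrices.

    For each non-reference species, take the reference + that species
    submatrix (optionally dropping organs), standardize within each sample,
    and decompose every gene with n_s = 2. Returns a long DataFrame with
    columns (species, gene_id, p_o, p_s, p_r).
    """
    design = mat.design
    if reference not in design.species:
        raise ValueError(f"unknown reference species {reference!r}")
    organs = tuple(o for o in design.organs if o not in exclude_organs)
    if not organs:
        raise ValueError("all organs excluded")
    frames = []
    for other in design.species:
        if other == reference:
            continue
        index = {
            (sp, o): design.sample_index[(sp, o)]
            for sp in (reference, other)
            for o in organs
        }
        sub_design = SampleDesign(organs, (reference, other), index)
        cols = [design.sample_ids().index(s) for s in sub_design.sample_ids()]
        sub = LogExpressionMatrix(
            mat.gene_ids, mat.values[:, cols], sub_design, mat.pseudocount
        )
        std = standardize_within_sample(sub)
        dec = decompose_all(std)
        dec = dec[["p_o", "p_s", "p_r"]].copy()
        dec.insert(0, "species", other)
        frames.append(dec.reset_index())
    return pd.concat(frames, ignore_index=True)
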