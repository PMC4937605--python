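"""Data model and I/O for balanced multi-organ, multi-species expression matrices.

The central object is a genes × samples matrix of linear-scale expression
(cRPKM or any RPKM-like rate) whose columns are indexed by a complete
organ × species grid: every organ profiled in every species, exactly once.
Balance is a hard requirement — the closed-form two-factor variance
decomposition downstream is only exact on a complete grid.

All downstream analysis operates on ``log10(x + pseudocount)`` values
(default pseudocount 0.01), produced by :func:`log_transform`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PSEUDOCOUNT = 0.01


class UnbalancedDesignError(ValueError):
    """The sample table does not form a complete organ × species grid."""


@dataclass(frozen=True)
class SampleDesign:
    """A complete organ × species grid indexing every sample.

    Parameters
    ----------
    organs
        Ordered unique organ labels.
    species
        Ordered unique species labels.
    sample_index
        Mapping ``(species, organ) -> sample_id``; must cover the full grid.
    """

    organs: tuple[str, ...]
    species: tuple[str, ...]
    sample_index: dict[tuple[str, str], str] = field(compare=False)

    def __post_init__(self) -> None:
        if not self.organs or not self.species:
            raise ValueError("organs and species must be non-empty")
        if len(set(self.organs)) != len(self.organs):
            raise ValueError("duplicate organ labels")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        missing = [
            (sp, o)
            for sp in self.species
            for o in self.organs
            if (sp, o) not in self.sample_index
        ]
        if missing:
            raise UnbalancedDesignError(
                f"unbalanced design: missing sample(s) for cells {missing}"
            )
        ids = list(self.sample_index.values())
        if len(set(ids)) != len(ids):
            raise UnbalancedDesignError("duplicate sample id across grid cells")

    @property
    def n_o(self) -> int:
        return len(self.organs)

    @property
    def n_s(self) -> int:
        return len(self.species)

    @property
    def n_samples(self) -> int:
        return self.n_o * self.n_s

    def sample_ids(self) -> list[str]:
        """Sample ids in canonical species-major, organ-minor order."""
        return [self.sample_index[(sp, o)] for sp in self.species for o in self.organs]

    def organ_of(self) -> dict[str, str]:
        return {sid: o for (sp, o), sid in self.sample_index.items()}

    def species_of(self) -> dict[str, str]:
        return {sid: sp for (sp, o), sid in self.sample_index.items()}

    def grouping(self, factor: str) -> list[str]:
        """Per-sample labels (canonical column order) for ``factor``."""
        if factor == "organ":
            return [o for _ in self.species for o in self.organs]
        if factor == "species":
            return [sp for sp in self.species for _ in self.organs]
        raise ValueError(f"unknown factor {factor!r}; expected 'organ' or 'species'")


def _check_matrix(gene_ids, values, design, *, log_scale: bool, pseudocount=None):
    gene_ids = tuple(str(g) for g in gene_ids)
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if list(gene_ids).count(g) > 1})
        raise ValueError(f"duplicate gene id(s): {dupes}")
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be 2-dimensional (genes × samples)")
    if values.shape != (len(gene_ids), design.n_samples):
        raise ValueError(
            f"shape {values.shape} does not match {len(gene_ids)} genes × "
            f"{design.n_samples} samples"
        )
    if not np.all(np.isfinite(values)):
        i, j = map(int, np.argwhere(~np.isfinite(values))[0])
        raise ValueError(f"non-finite value at gene row {i}, sample column {j}")
    if log_scale:
        floor = math.log10(pseudocount)
        if np.any(values < floor - 1e-12):
            raise ValueError(f"log value below log10(pseudocount) = {floor}")
    else:
        if np.any(values < 0):
            i, j = map(int, np.argwhere(values < 0)[0])
            raise ValueError(f"negative value at gene row {i}, sample column {j}")
    return gene_ids, values


@dataclass(frozen=True)
class ExpressionMatrix:
    """Linear-scale (cRPKM) genes × samples expression matrix.

    Columns follow the design's canonical species-major, organ-minor order.
    Values are finite and non-negative.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray
    design: SampleDesign

    def __post_init__(self) -> None:
        gid, vals = _check_matrix(self.gene_ids, self.values, self.design, log_scale=False)
        object.__setattr__(self, "gene_ids", gid)
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=self.design.sample_ids()
        )


@dataclass(frozen=True)
class LogExpressionMatrix:
    """log10(x + pseudocount) expression matrix; floor is log10(pseudocount)."""

    gene_ids: tuple[str, ...]
    values: np.ndarray
    design: SampleDesign
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        gid, vals = _check_matrix(
            self.gene_ids, self.values, self.design,
            log_scale=True, pseudocount=self.pseudocount,
        )
        object.__setattr__(self, "gene_ids", gid)
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=self.design.sample_ids()
        )

    def gene_grid(self, gene: str | int) -> np.ndarray:
        """One gene's values reshaped to an n_o × n_s grid (organs × species)."""
        row = self.gene_ids.index(gene) if isinstance(gene, str) else gene
        # canonical order is species-major: reshape to (n_s, n_o) then transpose
        return self.values[row].reshape(self.design.n_s, self.design.n_o).T


def read_expression_matrix(matrix_path, sample_table_path) -> ExpressionMatrix:
    """Read a linear-scale expression matrix plus its sample table.

    The matrix TSV has a ``gene_id`` first column and one column per sample;
    the sample table TSV has columns ``sample_id``, ``species``, ``organ``
    (optionally ``individual``). Organ and species orders follow first
    appearance in the sample table. Columns are reordered to the canonical
    species-major layout.

    Raises
    ------
    UnbalancedDesignError
        If any (species, organ) cell is missing or duplicated.
    ValueError
        On duplicate gene ids, non-numeric or negative values.
    """
    samples = pd.read_csv(sample_table_path, sep="\t", dtype=str)
    required = {"sample_id", "species", "organ"}
    if not required.issubset(samples.columns):
        raise ValueError(f"sample table must have columns {sorted(required)}")
    organs = list(dict.fromkeys(samples["organ"]))
    species = list(dict.fromkeys(samples["species"]))
    index: dict[tuple[str, str], str] = {}
    for _, row in samples.iterrows():
        cell = (row["species"], row["organ"])
        if cell in index:
            raise UnbalancedDesignError(f"unbalanced design: duplicate sample for cell {cell}")
        index[cell] = row["sample_id"]
    design = SampleDesign(tuple(organs), tuple(species), index)

    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    if mat.index.has_duplicates:
        dupes = sorted(mat.index[mat.index.duplicated()].unique())
        raise ValueError(f"duplicate gene id(s): {dupes}")
    want = design.sample_ids()
    missing_cols = [s for s in want if s not in mat.columns]
    if missing_cols:
        raise UnbalancedDesignError(
            f"unbalanced design: sample column(s) {missing_cols} absent from matrix"
        )
    mat = mat[want]
    if mat.isna().any().any():
        r, c = np.argwhere(mat.isna().to_numpy())[0]
        raise ValueError(f"missing value at gene {mat.index[r]!r}, sample {want[c]!r}")
    try:
        values = mat.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric value in matrix: {exc}") from exc
    if np.any(values < 0):
        r, c = map(int, np.argwhere(values < 0)[0])
        raise ValueError(f"negative value at gene {mat.index[r]!r}, sample {want[c]!r}")
    return ExpressionMatrix(tuple(mat.index.astype(str)), values, design)


def write_expression_matrix(mat: ExpressionMatrix, matrix_path, sample_table_path) -> None:
    """Write matrix and sample table TSVs; round-trips bit-identically.

    Values use repr-style ``%r`` float formatting so that reading back
    reproduces every double exactly.
    """
    frame = mat.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(matrix_path, sep="\t", float_format=lambda v: repr(float(v)))
    rows = [
        {"sample_id": sid, "species": sp, "organ": o}
        for (sp, o), sid in mat.design.sample_index.items()
    ]
    pd.DataFrame(rows).to_csv(sample_table_path, sep="\t", index=False)


def log_transform(
    mat: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> LogExpressionMatrix:
    """Elementwise ``log10(value + pseudocount)``; shape and ids preserved."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return LogExpressionMatrix(
        mat.gene_ids, np.log10(mat.values + pseudocount), mat.design, pseudocount
    )


def subset_genes(mat, ids):
    """Rows for the requested gene ids, in the requested order.

    Works on either matrix type; unknown ids raise with the full missing list.
    """
    ids = [str(g) for g in ids]
    if len(set(ids)) != len(ids):
        raise ValueError("requested gene ids contain duplicates")
    pos = {g: i for i, g in enumerate(mat.gene_ids)}
    missing = [g for g in ids if g not in pos]
    if missing:
        raise KeyError(f"gene id(s) not in matrix: {missing}")
    rows = mat.values[[pos[g] for g in ids]]
    if isinstance(mat, LogExpressionMatrix):
        return LogExpressionMatrix(tuple(ids), rows, mat.design, mat.pseudocount)
    return ExpressionMatrix(tuple(ids), rows, mat.design)
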