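"""Synthetic expression matrices with known per-gene variance components.

Each gene follows the additive model on log10 scale

    y_ij = mu + org_i + spc_j + eps_ij

with organ effects org_i ~ N(0, sigma2_o) i.i.d., species effects spc_j
either i.i.d. N(0, sigma2_s) or Brownian motion along a phylogeny scaled so
every tip has marginal variance sigma2_s, and residuals eps_ij ~ N(0,
sigma2_e) i.i.d. Genes are drawn from a mixture of four intent classes —
TVG-like (organ-dominated), SVG-like (species-dominated), balanced, and
constrained (near-zero variance, failing the dynamic-range filter) — so the
classifier, the modularity analysis, and the projection score can all be
tested against ground truth.

Matrices are emitted on the linear cRPKM scale as max(0, 10**y − pseudocount)
so the standard log transform recovers y exactly wherever y ≥
log10(pseudocount); ``emit_log=True`` skips the round trip for
exact-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .core_data import (
    DEFAULT_PSEUDOCOUNT,
    ExpressionMatrix,
    LogExpressionMatrix,
    SampleDesign,
)

CLASSES = ("TVG-like", "SVG-like", "balanced", "constrained")

# (sigma2_o range, sigma2_s range, sigma2_e range) in log10 units^2.
# TVG/SVG ranges put genes cleanly past the 2-order dynamic-range and
# 75%-explained thresholds; constrained genes stay within noise.
DEFAULT_CLASS_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "TVG-like": {"sigma2_o": (1.0, 4.0), "sigma2_s": (0.0, 0.2), "sigma2_e": (0.01, 0.05)},
    "SVG-like": {"sigma2_o": (0.0, 0.2), "sigma2_s": (1.0, 4.0), "sigma2_e": (0.01, 0.05)},
    "balanced": {"sigma2_o": (0.5, 1.0), "sigma2_s": (0.5, 1.0), "sigma2_e": (0.01, 0.05)},
    "constrained": {"sigma2_o": (0.0, 0.01), "sigma2_s": (0.0, 0.01), "sigma2_e": (0.0, 0.01)},
}

# baseline log10 expression of expressed genes (10–10^4 cRPKM); keeps the
# linear-scale zero-clip fraction well under 1% given the class variances
DEFAULT_MU_RANGE = (1.0, 4.0)

# 7 vertebrates, ultrametric topology with branch lengths in My
# (approximate consensus divergence times).
DEFAULT_TREE_NEWICK = (
    "((((((human:6,chimpanzee:6):23,rhesus:29):61,mouse:90):70,"
    "opossum:160):20,platypus:180):120,chicken:300);"
)

DEFAULT_SPECIES = ("human", "chimpanzee", "rhesus", "mouse", "opossum", "platypus", "chicken")
DEFAULT_ORGANS = ("brain", "cerebellum", "heart", "liver", "kidney", "testis")


@dataclass(frozen=True)
class GeneParams:
    """True model parameters for one simulated gene."""

    mu: float
    sigma2_o: float
    sigma2_s: float
    sigma2_e: float
    intended_class: str

    def __post_init__(self) -> None:
        for name in ("sigma2_o", "sigma2_s", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.intended_class not in CLASSES:
            raise ValueError(f"unknown class {self.intended_class!r}")


class SpeciesTree:
    """A phylogeny over the design's species, used to correlate species effects.

    Wraps a Newick string; exposes the between-tip correlation implied by
    shared root-to-tip path length: R_ab = L_shared(a,b) / sqrt(L_a * L_b),
    so Brownian motion along the tree scaled by this correlation gives every
    tip the same marginal variance.
    """

    def __init__(self, newick: str):
        self.newick = newick
        self._tree = dendropy.Tree.get(data=newick, schema="newick")
        if any(
            e.length is not None and e.length < 0
            for e in self._tree.preorder_edge_iter()
        ):
            raise ValueError("negative branch length in species tree")

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self._tree.taxon_namespace)

    def correlation_matrix(self, species: tuple[str, ...]) -> np.ndarray:
        """Between-species correlation from shared branch lengths, in the given order."""
        labels = set(self.tip_labels)
        missing = [s for s in species if s not in labels]
        if missing or len(labels) != len(species):
            raise ValueError(
                f"tree tips {sorted(labels)} do not match design species "
                f"{sorted(species)} (missing from tree: {missing})"
            )
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        depth = {s: self._root_to_tip(taxa[s]) for s in species}
        n = len(species)
        corr = np.eye(n)
        for a in range(n):
            for b in range(a + 1, n):
                d_ab = pdm.distance(taxa[species[a]], taxa[species[b]])
                shared = (depth[species[a]] + depth[species[b]] - d_ab) / 2
                r = shared / np.sqrt(depth[species[a]] * depth[species[b]])
                corr[a, b] = corr[b, a] = r
        return corr

    def _root_to_tip(self, taxon) -> float:
        node = self._tree.find_node_for_taxon(taxon)
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    def tip_distances_from(self, reference: str) -> dict[str, float]:
        """Patristic tip-to-tip distance from ``reference`` to every other tip."""
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        if reference not in taxa:
            raise ValueError(f"reference species {reference!r} not a tree tip")
        return {
            s: pdm.distance(taxa[reference], taxa[s])
            for s in taxa
            if s != reference
        }


def default_species_tree() -> SpeciesTree:
    """The default 7-species vertebrate tree (branch lengths in My)."""
    return SpeciesTree(DEFAULT_TREE_NEWICK)


def default_design(
    organs: tuple[str, ...] = DEFAULT_ORGANS,
    species: tuple[str, ...] = DEFAULT_SPECIES,
) -> SampleDesign:
    """A complete organ × species design with ``{species}_{organ}`` sample ids."""
    index = {(sp, o): f"{sp}_{o}" for sp in species for o in organs}
    return SampleDesign(tuple(organs), tuple(species), index)


def sample_gene_params(
    n_genes: int,
    class_mixture: dict[str, float] | None = None,
    variance_ranges: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int = 0,
    mu_range: tuple[float, float] = DEFAULT_MU_RANGE,
) -> list[GeneParams]:
    """Draw per-gene true parameters from the class mixture.

    Class labels are assigned multinomially with the mixture proportions;
    each variance is then uniform within its class range. Deterministic for
    a fixed seed.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if class_mixture is None:
        class_mixture = {"TVG-like": 0.3, "SVG-like": 0.2, "balanced": 0.2, "constrained": 0.3}
    unknown = set(class_mixture) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown class(es) in mixture: {sorted(unknown)}")
    probs = np.array([class_mixture.get(c, 0.0) for c in CLASSES], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture proportions sum to {probs.sum()}, expected 1")
    ranges = variance_ranges or DEFAULT_CLASS_RANGES
    for cls, rng_map in ranges.items():
        for key, (lo, hi) in rng_map.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid {key} range {lo, hi} for class {cls}")

    rng = np.random.default_rng(seed)
    labels = rng.choice(len(CLASSES), size=n_genes, p=probs)
    params = []
    for lab in labels:
        cls = CLASSES[lab]
        r = ranges[cls]
        params.append(
            GeneParams(
                mu=float(rng.uniform(*mu_range)),
                sigma2_o=float(rng.uniform(*r["sigma2_o"])),
                sigma2_s=float(rng.uniform(*r["sigma2_s"])),
                sigma2_e=float(rng.uniform(*r["sigma2_e"])),
                intended_class=cls,
            )
        )
    return params


def simulate_expression(
    design: SampleDesign,
    params: list[GeneParams],
    tree: SpeciesTree | None = None,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    emit_log: bool = False,
) -> tuple[ExpressionMatrix | LogExpressionMatrix, pd.DataFrame]:
    """Simulate a matrix plus its truth table.

    Returns the matrix (linear scale unless ``emit_log``) and a DataFrame with
    one row per gene: class, true parameters, realized organ/species effect
    vectors, and the variance fractions implied by the *realized* effects
    (computed from the expected sums of squares given the sampled effect
    vectors, i.e., the quantity the decomposition estimates).
    """
    n_o, n_s = design.n_o, design.n_s
    rng = np.random.default_rng(seed)

    chol = None
    if tree is not None:
        corr = tree.correlation_matrix(design.species)
        # tiny jitter guards Cholesky against exactly singular correlation
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_s))

    n_genes = len(params)
    log_vals = np.empty((n_genes, n_o * n_s))
    truth_rows = []
    for g, p in enumerate(params):
        org = rng.normal(0.0, np.sqrt(p.sigma2_o), size=n_o)
        z = rng.normal(0.0, 1.0, size=n_s)
        if chol is not None:
            spc = np.sqrt(p.sigma2_s) * (chol @ z)
        else:
            spc = np.sqrt(p.sigma2_s) * z
        eps = rng.normal(0.0, np.sqrt(p.sigma2_e), size=(n_o, n_s))
        grid = p.mu + org[:, None] + spc[None, :] + eps  # organs × species
        # canonical column order is species-major, organ-minor
        log_vals[g] = grid.T.reshape(-1)

        # variance fractions from the realized effect vectors: expected SS
        # conditional on (org, spc), averaging only over the residual draw
        sso = n_s * np.sum((org - org.mean()) ** 2)
        sss = n_o * np.sum((spc - spc.mean()) ** 2)
        e_ssr = (n_o - 1) * (n_s - 1) * p.sigma2_e
        total = sso + sss + e_ssr
        if total > 0:
            fracs = (sso / total, sss / total, e_ssr / total)
        else:
            fracs = (np.nan, np.nan, np.nan)
        truth_rows.append(
            {
                "gene_id": f"g{g:05d}",
                "class": p.intended_class,
                "mu": p.mu,
                "sigma2_o": p.sigma2_o,
                "sigma2_s": p.sigma2_s,
                "sigma2_e": p.sigma2_e,
                "org_effects": org.copy(),
                "spc_effects": spc.copy(),
                "true_p_o": fracs[0],
                "true_p_s": fracs[1],
                "true_p_r": fracs[2],
            }
        )

    gene_ids = tuple(r["gene_id"] for r in truth_rows)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    if emit_log:
        floor = np.log10(pseudocount)
        mat = LogExpressionMatrix(
            gene_ids, np.maximum(log_vals, floor), design, pseudocount
        )
        return mat, truth
    linear = np.maximum(0.0, 10.0 ** log_vals - pseudocount)
    return ExpressionMatrix(gene_ids, linear, design), truth


def write_truth_table(truth: pd.DataFrame, path) -> None:
    """TSV truth table (effect vectors omitted; scalars only)."""
    cols = ["class", "mu", "sigma2_o", "sigma2_s", "sigma2_e",
            "true_p_o", "true_p_s", "true_p_r"]
    truth[cols].to_csv(path, sep="\t")
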