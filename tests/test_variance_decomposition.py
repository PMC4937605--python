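import numpy as np
import pandas as pd
import pytest

from orthovar.core_data import LogExpressionMatrix
from orthovar.synthetic_data import GeneParams, default_design, sample_gene_params, simulate_expression
from orthovar.variance_decomposition import (
    ClassificationThresholds,
    classify_genes,
    decompose_all,
    decompose_gene,
    dynamic_range,
    dynamic_ranges,
    mean_proportions,
    pairwise_species_decomposition,
    remove_factor_variance,
    standardize_within_sample,
)


def sequential_ss_oracle(grid, organ_first=True):
    """Sequential sums of squares from explicit least-squares projections.

    Fits the two-factor additive model by adding factor design matrices one
    at a time and measuring the drop in residual sum of squares — fully
    independent of the closed-form grid-mean implementation.
    """
    n_o, n_s = grid.shape
    y = grid.reshape(-1)
    organ = np.repeat(np.arange(n_o), n_s)
    species = np.tile(np.arange(n_s), n_o)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return np.sum((y - X @ beta) ** 2)

    intercept = np.ones((y.size, 1))
    organ_dm = np.eye(n_o)[organ]
    species_dm = np.eye(n_s)[species]
    rss0 = rss(intercept)
    if organ_first:
        rss1 = rss(np.hstack([intercept, organ_dm]))
        rss2 = rss(np.hstack([intercept, organ_dm, species_dm]))
        sso, sss = rss0 - rss1, rss1 - rss2
    else:
        rss1 = rss(np.hstack([intercept, species_dm]))
        rss2 = rss(np.hstack([intercept, species_dm, organ_dm]))
        sss, sso = rss0 - rss1, rss1 - rss2
    return rss0, sso, sss, rss2


class TestDecomposeGene:
    def test_worked_2x2_example(self):
        d = decompose_gene(np.array([[1.0, 2.0], [3.0, 5.0]]))
        assert d.sst == pytest.approx(8.75)
        assert d.sso == pytest.approx(6.25)
        assert d.sss == pytest.approx(2.25)
        assert d.ssr == pytest.approx(0.25)
        assert (d.p_o, d.p_s, d.p_r) == pytest.approx(
            (0.714286, 0.257143, 0.028571), abs=1e-6
        )

    def test_constant_grid_undefined_proportions(self):
        d = decompose_gene(np.full((3, 4), 2.5))
        assert d.sst == 0
        assert np.isnan(d.p_o) and np.isnan(d.p_s) and np.isnan(d.p_r)

    def test_row_constant_grid_is_pure_organ(self):
        grid = np.array([[1.0] * 5, [2.0] * 5, [4.0] * 5])
        d = decompose_gene(grid)
        assert d.p_o == pytest.approx(1.0)
        assert d.p_s == pytest.approx(0.0, abs=1e-12)
        assert d.p_r == pytest.approx(0.0, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            decompose_gene(np.array([[1.0, np.nan], [2.0, 3.0]]))

    def test_matches_least_squares_oracle_and_order_invariance(self, rng):
        # 500 random grids, sizes 2x2 .. 8x8
        for _ in range(500):
            n_o = rng.integers(2, 9)
            n_s = rng.integers(2, 9)
            grid = rng.normal(size=(n_o, n_s)) * rng.uniform(0.1, 10)
            d = decompose_gene(grid)
            sst, sso, sss, ssr = sequential_ss_oracle(grid, organ_first=True)
            np.testing.assert_allclose([d.sst, d.sso, d.sss, d.ssr],
                                       [sst, sso, sss, ssr], rtol=1e-8, atol=1e-10)
            # balanced design: order of factors is irrelevant
            _, sso2, sss2, _ = sequential_ss_oracle(grid, organ_first=False)
            np.testing.assert_allclose([sso, sss], [sso2, sss2], rtol=1e-8, atol=1e-10)


class TestDecomposeAll:
    def test_conservation_every_gene(self, design_6x7, rng):
        vals = rng.normal(1.0, 1.5, size=(300, design_6x7.n_samples))
        mat = LogExpressionMatrix(
            tuple(f"g{i}" for i in range(300)), vals, design_6x7, pseudocount=1e-9
        )
        dec = decompose_all(mat)
        np.testing.assert_allclose(
            dec["sst"], dec[["sso", "sss", "ssr"]].sum(axis=1), rtol=1e-9
        )

    def test_matches_per_gene_path(self, design_6x7, rng):
        vals = rng.normal(size=(20, design_6x7.n_samples))
        mat = LogExpressionMatrix(
            tuple(f"g{i}" for i in range(20)), vals, design_6x7, pseudocount=1e-9
        )
        dec = decompose_all(mat)
        for i in range(20):
            d = decompose_gene(mat.gene_grid(i))
            np.testing.assert_allclose(
                dec.iloc[i][["sst", "sso", "sss", "ssr"]].to_numpy(),
                [d.sst, d.sso, d.sss, d.ssr], rtol=1e-10,
            )

    def test_organ_only_simulation_gives_mean_p_o_one(self, design_6x7):
        params = [GeneParams(2.0, 2.0, 0.0, 0.0, "TVG-like") for _ in range(30)]
        mat, _ = simulate_expression(design_6x7, params, seed=1, emit_log=True)
        summary = mean_proportions(decompose_all(mat))
        assert summary["mean_p_o"] == pytest.approx(1.0, abs=1e-12)


class TestDynamicRange:
    @pytest.mark.parametrize(
        "values,expected",
        [([0.99, 99.99], 2.0), ([5.0, 5.0, 5.0], 0.0), ([0.0, 0.99], 2.0)],
    )
    def test_known_values(self, values, expected):
        assert dynamic_range(np.array(values)) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dynamic_range(np.array([]))

    def test_vectorized_matches_scalar(self, rng):
        vals = rng.uniform(0, 1000, size=(50, 10))
        rows = dynamic_ranges(vals)
        for i in range(50):
            assert rows[i] == pytest.approx(dynamic_range(vals[i]))


class TestClassifyGenes:
    @staticmethod
    def _table(p_o, p_s, sst=1.0):
        p_r = 1 - p_o - p_s
        return pd.DataFrame(
            {"sst": [sst], "sso": [p_o * sst], "sss": [p_s * sst],
             "ssr": [p_r * sst], "p_o": [p_o], "p_s": [p_s], "p_r": [p_r]},
            index=pd.Index(["g"], name="gene_id"),
        )

    @pytest.mark.parametrize(
        "p_o,p_s,dr,expected",
        [
            (0.6, 0.2, 3.0, "TVG"),
            (0.5, 0.25, 3.0, "TVG"),       # inclusive boundary: 0.5 >= 2*0.25
            (0.2, 0.6, 3.0, "SVG"),
            (0.45, 0.4, 3.0, "other_unconstrained"),
            (0.6, 0.2, 1.0, "constrained"),  # fails dynamic range
            (0.4, 0.2, 3.0, "other_unconstrained"),  # explained < 0.75
        ],
    )
    def test_threshold_arithmetic(self, p_o, p_s, dr, expected):
        cls = classify_genes(self._table(p_o, p_s), np.array([dr]))
        assert cls["gene_class"].iloc[0] == expected

    def test_zero_variance_gene_is_constrained(self):
        tab = self._table(0.0, 0.0, sst=0.0)
        tab.loc[:, ["p_o", "p_s", "p_r"]] = np.nan
        cls = classify_genes(tab, np.array([0.0]))
        assert cls["gene_class"].iloc[0] == "constrained"

    def test_raising_dr_min_is_monotone(self, design_6x7):
        params = sample_gene_params(800, seed=23)
        mat, _ = simulate_expression(design_6x7, params, seed=24)
        from orthovar.core_data import log_transform

        dec = decompose_all(log_transform(mat))
        dr = dynamic_ranges(mat.values)
        lo = classify_genes(dec, dr, ClassificationThresholds(dr_min=1.5))
        hi = classify_genes(dec, dr, ClassificationThresholds(dr_min=3.0))
        moved = (lo["gene_class"] == "constrained") & (hi["gene_class"] != "constrained")
        assert not moved.any()

    def test_pre_intersection_masks_ignore_dynamic_range(self):
        cls = classify_genes(self._table(0.8, 0.1), np.array([0.5]))
        assert cls["gene_class"].iloc[0] == "constrained"
        assert bool(cls["organ_dominated"].iloc[0])


class TestRemoveFactorVariance:
    def _sim(self, design, mixture, seed):
        params = sample_gene_params(200, class_mixture=mixture, seed=seed)
        mat, _ = simulate_expression(design, params, seed=seed + 1, emit_log=True)
        return mat

    def test_organ_scaling_cancels_organ_ss(self, design_6x7):
        mat = self._sim(design_6x7, None, 31)
        out = remove_factor_variance(mat, "organ")
        dec = decompose_all(out)
        assert dec["sso"].abs().max() < 1e-9
        ok = dec["sst"] > 0
        assert dec.loc[ok, "p_o"].abs().max() < 1e-9

    def test_species_scaling_cancels_species_ss(self, design_6x7):
        mat = self._sim(design_6x7, None, 33)
        dec = decompose_all(remove_factor_variance(mat, "species"))
        assert dec["sss"].abs().max() < 1e-9

    def test_species_scaling_raises_organ_share_of_svgs(self, design_6x7):
        mat = self._sim(design_6x7, {"SVG-like": 1.0}, 35)
        before = mean_proportions(decompose_all(mat))["mean_p_o"]
        after = mean_proportions(decompose_all(remove_factor_variance(mat, "species")))["mean_p_o"]
        assert after > before

    def test_gene_constant_within_every_organ_maps_to_zero(self, design_2x2):
        # values depend only on organ: constant across species in each organ
        vals = np.array([[1.0, 2.0, 1.0, 2.0]])
        mat = LogExpressionMatrix(("g",), vals, design_2x2, pseudocount=1e-9)
        out = remove_factor_variance(mat, "organ")
        np.testing.assert_array_equal(out.values, 0.0)


class TestStandardizeWithinSample:
    def test_hand_computed_column(self, design_2x2):
        vals = np.array([[1.0, 0, 0, 0], [2.0, 1, 1, 1], [3.0, 2, 2, 2]])
        out = standardize_within_sample(
            LogExpressionMatrix(("a", "b", "c"), vals, design_2x2, pseudocount=1e-9)
        )
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent(self, design_2x2, rng):
        vals = rng.normal(size=(6, 4))
        mat = LogExpressionMatrix(tuple("abcdef"), vals, design_2x2, pseudocount=1e-9)
        once = standardize_within_sample(mat)
        twice = standardize_within_sample(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_column_rejected(self, design_2x2):
        vals = np.array([[1.0, 1, 2, 3], [1.0, 2, 3, 4]])
        mat = LogExpressionMatrix(("a", "b"), vals, design_2x2, pseudocount=1e-9)
        with pytest.raises(ValueError, match="constant sample"):
            standardize_within_sample(mat)


class TestPairwiseSpeciesDecomposition:
    def test_reference_excluded_and_all_pairs_present(self, design_6x7):
        params = sample_gene_params(50, seed=41)
        mat, _ = simulate_expression(design_6x7, params, seed=42, emit_log=True)
        pw = pairwise_species_decomposition(mat, "human")
        assert set(pw["species"]) == set(design_6x7.species) - {"human"}

    def test_identical_species_blocks_give_zero_species_share(self, design_2x2, rng):
        block = rng.normal(size=(30, 2))
        vals = np.hstack([block, block])  # sp2 identical to sp1
        mat = LogExpressionMatrix(
            tuple(f"g{i}" for i in range(30)), vals, design_2x2, pseudocount=1e-9
        )
        pw = pairwise_species_decomposition(mat, "sp1")
        ok = pw["p_s"].notna()
        assert pw.loc[ok, "p_s"].abs().max() < 1e-12

    def test_unknown_reference(self, design_6x7):
        params = sample_gene_params(5, seed=1)
        mat, _ = simulate_expression(design_6x7, params, seed=2, emit_log=True)
        with pytest.raises(ValueError, match="unknown reference"):
            pairwise_species_decomposition(mat, "yeti")

    def test_organ_exclusion(self, design_6x7):
        params = sample_gene_params(20, seed=1)
        mat, _ = simulate_expression(design_6x7, params, seed=2, emit_log=True)
        pw = pairwise_species_decomposition(mat, "human", exclude_organs=("testis",))
        assert len(pw) == 20 * 6
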