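"""Tests of the pixel-level deprivation mapping."""

import numpy as np
import pandas as pd
import pytest

import deprimap as dm
from deprimap import reference
from deprimap.classes import LandCover
from deprimap.features import window_feature_stack
from deprimap.mapping import make_deprivation_grid, score_feature_rows

CO, PA, WATER = (int(LandCover.CORRUGATED), int(LandCover.PAVEMENT),
                 int(LandCover.WATER))


class TestDimension1:
    def test_pure_corrugated_pixel_scores_first_loading(self):
        lc = np.full((3, 3), CO, dtype=np.int16)
        stack = window_feature_stack(lc, np.zeros((3, 3)))
        # express features as proportions of 1 for the unit-feature check
        values = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        score = score_feature_rows(values, reference.SALVADOR_D1_LANDCOVER_LOADINGS,
                                   ["CO", "WP", "TR", "PA", "TX"], mode="raw")
        assert score == pytest.approx(0.559)
        d1 = dm.dimension1_grid(stack, reference.SALVADOR_D1_LANDCOVER_LOADINGS,
                                mode="raw")
        assert np.allclose(d1, 100.0 * 0.559)  # CO = 100 percent everywhere

    def test_zero_features_score_zero(self):
        values = np.zeros(5)
        assert score_feature_rows(values, reference.SALVADOR_D1_LANDCOVER_LOADINGS,
                                  ["CO", "WP", "TR", "PA", "TX"], mode="raw") == 0.0

    def test_reference_community_hand_arithmetic(self):
        """High-income reference community row, raw mode: -29.14."""
        row = reference.SALVADOR_COMMUNITIES["Barra"]["landcover"]
        values = np.array([row[k] for k in ("CO", "WP", "TR", "PA", "TX")])
        score = score_feature_rows(values, reference.SALVADOR_D1_LANDCOVER_LOADINGS,
                                   ["CO", "WP", "TR", "PA", "TX"], mode="raw")
        assert score == pytest.approx(-29.14, abs=0.01)

    def test_masked_pixels_are_nan(self):
        lc = np.full((3, 3), WATER, dtype=np.int16)
        stack = window_feature_stack(lc, np.zeros((3, 3)))
        d1 = dm.dimension1_grid(stack, np.ones(5), mode="raw")
        assert np.isnan(d1).all()

    def test_monotone_in_corrugated_share(self):
        """Swapping a pavement neighbour for corrugated raises d1 (CO+, PA-)."""
        base = np.full((3, 3), PA, dtype=np.int16)
        more = base.copy()
        more[0, 0] = CO
        load = reference.SALVADOR_D1_LANDCOVER_LOADINGS
        d_base = dm.dimension1_grid(window_feature_stack(base, np.zeros((3, 3))),
                                    load, mode="raw")
        d_more = dm.dimension1_grid(window_feature_stack(more, np.zeros((3, 3))),
                                    load, mode="raw")
        assert d_more[1, 1] > d_base[1, 1]

    def test_wrong_loading_length_rejected(self):
        lc = np.full((3, 3), CO, dtype=np.int16)
        stack = window_feature_stack(lc, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="5 entries"):
            dm.dimension1_grid(stack, np.ones(4), mode="raw")


class TestDimension2:
    def make_census(self, n=2):
        return pd.DataFrame({
            "tract_id": np.arange(1, n + 1),
            "BA": [1.0] * n, "WA": [0.0] * n, "GA": [0.0] * n,
            "IN": [0.0] * n, "CR": [0.0] * n,
        })

    def test_pure_bathroom_tract_scores_first_loading(self):
        census = self.make_census(1)
        tracts = np.ones((2, 2), dtype=int)
        d2 = dm.dimension2_grid(census, tracts,
                                reference.SALVADOR_D2_SOCIO_LOADINGS, mode="raw")
        assert np.allclose(d2, 0.944)

    def test_constant_census_broadcasts_constant_grid(self):
        census = self.make_census(3)
        tracts = np.array([[1, 2], [3, 1]])
        d2 = dm.dimension2_grid(census, tracts,
                                reference.SALVADOR_D2_SOCIO_LOADINGS, mode="raw")
        assert np.allclose(d2, d2[0, 0])

    def test_missing_tract_listed(self):
        census = self.make_census(1)
        tracts = np.array([[1, 2]])
        with pytest.raises(ValueError, match=r"\[2\]"):
            dm.dimension2_grid(census, tracts, np.ones(5), mode="raw")


class TestCombine:
    def test_reference_weights_on_unit_grids(self):
        ones = np.ones((2, 2))
        out = dm.combine_dimensions(ones, ones, *reference.SALVADOR_COMBINE_WEIGHTS)
        assert np.allclose(out, 0.933)

    def test_zero_grids(self):
        z = np.zeros((3, 3))
        assert np.allclose(dm.combine_dimensions(z, z, 0.5, 0.4), 0.0)

    def test_linearity_in_inputs(self, rng):
        d1, d2 = rng.normal(size=(2, 4, 4))
        a = float(rng.uniform(0.1, 5.0))
        left = dm.combine_dimensions(a * d1, a * d2, 0.586, 0.347)
        right = a * dm.combine_dimensions(d1, d2, 0.586, 0.347)
        assert np.allclose(left, right)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dm.combine_dimensions(np.ones((2, 2)), np.ones((3, 3)), 1.0, 1.0)


class TestMaskAndSummaries:
    def test_urban_mask_counts_impervious(self, strong_city):
        mask = dm.urban_mask(strong_city.landcover)
        expected = np.isin(strong_city.landcover, [CO, 2, 3, PA]).sum()
        assert mask.sum() == expected

    def test_all_water_false_all_pavement_true(self):
        assert not dm.urban_mask(np.full((2, 2), WATER)).any()
        assert dm.urban_mask(np.full((2, 2), PA)).all()

    def test_mask_conservation(self, strong_city):
        """Valid combined pixels == urban pixels with defined window features."""
        filtered = dm.high_pass_filter(strong_city.red_band)
        stack = window_feature_stack(strong_city.landcover, filtered)
        d1 = dm.dimension1_grid(stack, np.ones(5), mode="raw")
        d2 = dm.dimension2_grid(strong_city.census, strong_city.tracts,
                                np.ones(5), mode="raw")
        grid = make_deprivation_grid(d1, d2, 0.586, 0.347, strong_city.landcover)
        urban_defined = dm.urban_mask(strong_city.landcover) & stack.mask
        assert grid.mask.sum() == urban_defined.sum()
        assert np.isfinite(grid.combined[grid.mask]).all()
        assert np.isnan(grid.combined[~grid.mask]).all()

    def test_tract_means_match_hand_average(self):
        tracts = np.array([[1, 1], [2, 2]])
        lc = np.full((2, 2), PA)
        d1 = np.array([[1.0, 3.0], [5.0, 7.0]])
        d2 = np.zeros((2, 2))
        grid = make_deprivation_grid(d1, d2, 1.0, 1.0, lc)
        summary = dm.tract_mean_scores(grid, tracts)
        assert summary["mean_d1"].tolist() == [2.0, 6.0]
        assert summary["n_valid"].tolist() == [2, 2]

    def test_fully_masked_tract_flagged(self):
        tracts = np.array([[1, 2]])
        lc = np.array([[PA, WATER]])
        d = np.ones((1, 2))
        grid = make_deprivation_grid(d, d, 1.0, 0.0, lc)
        summary = dm.tract_mean_scores(grid, tracts)
        assert bool(summary.loc[summary.tract_id == 2, "defined"].iloc[0]) is False
        assert np.isnan(summary.loc[summary.tract_id == 2, "mean_d1"].iloc[0])

    def test_constant_combined_grid_constant_means(self):
        tracts = np.array([[1, 2], [2, 1]])
        lc = np.full((2, 2), CO)
        c = np.full((2, 2), 4.2)
        grid = make_deprivation_grid(c, np.zeros((2, 2)), 1.0, 0.0, lc)
        summary = dm.tract_mean_scores(grid, tracts)
        assert np.allclose(summary["mean_combined"], 4.2)


class TestTractPixelConsistency:
    def test_3x3_block_city(self):
        """Uniform-cover 3x3-block tracts: tract-mean d1 equals tract-level d1."""
        lc = np.full((9, 9), CO, dtype=np.int16)
        tracts = np.zeros((9, 9), dtype=int)
        for bi in range(3):
            for bj in range(3):
                tracts[3 * bi:3 * bi + 3, 3 * bj:3 * bj + 3] = 3 * bi + bj + 1
        filtered = np.zeros((9, 9))  # constant red band -> zero texture
        table = dm.tract_composition(lc, tracts, filtered)
        load = reference.SALVADOR_D1_LANDCOVER_LOADINGS
        tract_scores = score_feature_rows(
            table[["CO", "WP", "TR", "PA", "TX"]].to_numpy(), load,
            ["CO", "WP", "TR", "PA", "TX"], mode="raw")
        stack = window_feature_stack(lc, filtered)
        d1 = dm.dimension1_grid(stack, load, mode="raw")
        grid = make_deprivation_grid(d1, np.zeros((9, 9)), 1.0, 0.0, lc)
        summary = dm.tract_mean_scores(grid, tracts)
        assert np.allclose(summary["mean_d1"].to_numpy(), tract_scores)
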