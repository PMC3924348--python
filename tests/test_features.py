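"""Tests of land-cover feature extraction: classifier, texture, compositions."""

import numpy as np
import pytest
from scipy import stats

import deprimap as dm
from deprimap.classes import LandCover
from deprimap.features import ClassModel

CO, WP, TR, PA = (int(LandCover.CORRUGATED), int(LandCover.WHITE_PAINTED),
                  int(LandCover.TILE), int(LandCover.PAVEMENT))
WATER, VEG = int(LandCover.WATER), int(LandCover.VEGETATION)


class TestMaxLikelihoodClassifier:
    def test_separable_classes_recovered_exactly(self, rng):
        labels = rng.integers(0, 2, size=(20, 20))
        bands = np.where(labels == 0, rng.normal(0, 0.5, (20, 20)),
                         rng.normal(100, 0.5, (20, 20)))
        models = [ClassModel("low", [0.0], [[1.0]], 0.5),
                  ClassModel("high", [100.0], [[1.0]], 0.5)]
        out = dm.classify_max_likelihood(bands, models)
        assert np.array_equal(out - 1, labels)

    def test_decision_boundary_at_equal_likelihood(self):
        """N(0,1) vs N(10,1), equal priors: boundary sits at 5."""
        models = [ClassModel("A", [0.0], [[1.0]], 0.5),
                  ClassModel("B", [10.0], [[1.0]], 0.5)]
        grid = np.array([[4.9, 5.1]])
        assert dm.classify_max_likelihood(grid, models).tolist() == [[1, 2]]

    def test_tie_broken_by_declared_order(self):
        models = [ClassModel("first", [0.0], [[1.0]], 0.5),
                  ClassModel("second", [0.0], [[1.0]], 0.5)]
        out = dm.classify_max_likelihood(np.zeros((3, 3)), models)
        assert (out == 1).all()

    def test_matches_bruteforce_gaussian_argmax(self, rng):
        """Oracle: explicit per-pixel density evaluation on a small 2-band grid."""
        means = [np.array([0.0, 0.0]), np.array([2.0, -1.0]), np.array([-1.0, 3.0])]
        covs = [np.array([[1.0, 0.3], [0.3, 2.0]]),
                np.array([[0.5, 0.0], [0.0, 0.5]]),
                np.array([[2.0, -0.5], [-0.5, 1.0]])]
        priors = [0.5, 0.3, 0.2]
        models = [ClassModel(f"c{i}", means[i], covs[i], priors[i]) for i in range(3)]
        bands = rng.normal(0, 2, size=(8, 8, 2))
        out = dm.classify_max_likelihood(bands, models)
        for i in range(8):
            for j in range(8):
                dens = [np.log(priors[k]) +
                        stats.multivariate_normal(means[k], covs[k]).logpdf(bands[i, j])
                        for k in range(3)]
                assert out[i, j] == int(np.argmax(dens)) + 1

    def test_singular_covariance_names_class(self):
        models = [ClassModel("bad", [0.0, 0.0], [[1.0, 1.0], [1.0, 1.0]], 1.0)]
        with pytest.raises(ValueError, match="bad"):
            dm.classify_max_likelihood(np.zeros((2, 2, 2)), models)


class TestHighPassFilter:
    def test_constant_grid_maps_to_zero(self):
        assert np.allclose(dm.high_pass_filter(np.full((6, 6), 3.7)), 0.0)

    def test_linear_ramp_annihilated_at_interior(self):
        x, y = np.meshgrid(np.arange(8), np.arange(8))
        out = dm.high_pass_filter(2.0 * x - 3.0 * y + 1.0)
        assert np.allclose(out[1:-1, 1:-1], 0.0, atol=1e-9)

    def test_impulse_response(self):
        """Hand convolution: impulse of height a -> center 8a, neighbours -a."""
        grid = np.zeros((5, 5))
        grid[2, 2] = 3.0
        out = dm.high_pass_filter(grid)
        assert out[2, 2] == pytest.approx(24.0)
        neighbours = [out[i, j] for i in (1, 2, 3) for j in (1, 2, 3)
                      if (i, j) != (2, 2)]
        assert np.allclose(neighbours, -3.0)

    def test_border_uses_shrunken_window(self):
        """Corner cell has 3 neighbours: weight 3 on center, -1 each neighbour."""
        grid = np.arange(9, dtype=float).reshape(3, 3)
        out = dm.high_pass_filter(grid)
        assert out[0, 0] == pytest.approx(3 * grid[0, 0] -
                                          (grid[0, 1] + grid[1, 0] + grid[1, 1]))


class TestTextureSD:
    def test_constant_region_zero(self):
        assert dm.texture_sd(np.full((4, 4), 2.0)) == 0.0

    def test_two_point_population_sd(self):
        assert dm.texture_sd(np.array([[-1.0, 1.0]])) == pytest.approx(1.0)

    def test_shift_invariance(self, rng):
        grid = rng.normal(size=(10, 10))
        assert dm.texture_sd(grid + 100.0) == pytest.approx(dm.texture_sd(grid))

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            dm.texture_sd(np.ones((3, 3)), np.zeros((3, 3), dtype=bool))


class TestTractComposition:
    def test_counting_example(self):
        """7 corrugated + 3 pavement -> CO=70, PA=30."""
        lc = np.array([[CO] * 7 + [PA] * 3])
        tracts = np.ones((1, 10), dtype=int)
        table = dm.tract_composition(lc, tracts, np.zeros((1, 10)))
        row = table.iloc[0]
        assert row["CO"] == pytest.approx(70.0)
        assert row["PA"] == pytest.approx(30.0)
        assert row["WP"] == row["TR"] == 0.0
        assert row["defined"]

    def test_all_vegetation_tract_undefined(self):
        lc = np.full((2, 3), VEG)
        table = dm.tract_composition(lc, np.ones((2, 3), dtype=int), np.zeros((2, 3)))
        assert not table.iloc[0]["defined"]
        assert np.isnan(table.iloc[0]["CO"])

    def test_composition_sums_to_100(self, strong_city):
        filtered = dm.high_pass_filter(strong_city.red_band)
        table = dm.tract_composition(strong_city.landcover, strong_city.tracts, filtered)
        defined = table[table["defined"]]
        sums = defined[["CO", "WP", "TR", "PA"]].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)
        assert (defined["TX"] >= 0).all()


class TestWindowFeatures:
    def test_uniform_corrugated_grid(self):
        lc = np.full((5, 5), CO, dtype=np.int16)
        stack = dm.window_feature_stack(lc, np.zeros((5, 5)))
        assert np.allclose(stack.features["CO"], 100.0)
        for k in ("WP", "TR", "PA", "TX"):
            assert np.allclose(stack.features[k], 0.0)

    def test_mixed_window_counts_impervious_denominator(self):
        """4 corrugated + 4 pavement + 1 water around center -> CO=PA=50."""
        lc = np.array([[CO, CO, PA],
                       [CO, WATER, PA],
                       [CO, PA, PA]], dtype=np.int16)
        stack = dm.window_feature_stack(lc, np.zeros((3, 3)))
        assert stack.features["CO"][1, 1] == pytest.approx(50.0)
        assert stack.features["PA"][1, 1] == pytest.approx(50.0)

    def test_all_water_window_masked(self):
        lc = np.full((3, 3), WATER, dtype=np.int16)
        stack = dm.window_feature_stack(lc, np.zeros((3, 3)))
        assert not stack.mask.any()
        assert np.isnan(stack.features["CO"]).all()

    def test_all_pixels_denominator_mode(self):
        lc = np.full((3, 3), CO, dtype=np.int16)
        lc[0, 0] = WATER
        stack = dm.window_feature_stack(lc, np.zeros((3, 3)), denominator="all")
        # center window: 8 corrugated of 9 pixels
        assert stack.features["CO"][1, 1] == pytest.approx(100.0 * 8 / 9)

    def test_window_matches_tract_for_3x3_block(self, rng):
        """A tract that is exactly one 3x3 block: center window == tract features."""
        lc = rng.choice([CO, WP, TR, PA, WATER], size=(3, 3)).astype(np.int16)
        filtered = rng.normal(size=(3, 3))
        tracts = np.ones((3, 3), dtype=int)
        table = dm.tract_composition(lc, tracts, filtered)
        stack = dm.window_feature_stack(lc, filtered)
        row = table.iloc[0]
        for k in ("CO", "WP", "TR", "PA", "TX"):
            assert stack.features[k][1, 1] == pytest.approx(row[k])

    def test_composition_sums_to_100_where_defined(self, strong_city):
        filtered = dm.high_pass_filter(strong_city.red_band)
        stack = dm.window_feature_stack(strong_city.landcover, filtered)
        total = sum(stack.features[k] for k in ("CO", "WP", "TR", "PA"))
        assert np.allclose(total[stack.mask], 100.0, atol=1e-9)
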