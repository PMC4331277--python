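"""Raster preparation: grid templates, rasterization, distance layers,
aggregation and gap filling, checked against brute-force oracles."""

import numpy as np
import pytest
from shapely.geometry import Point, box

from popforest import (
    CovariateLayer,
    EmptyClassError,
    GridTemplate,
    LayerKind,
    align_covariate,
    class_and_distance_rasters,
    distance_from_mask,
    fill_nodata_nearest,
    make_grid_template,
    rasterize_units,
    split_built_class,
)
from popforest.raster_prep import rasterize_features

from conftest import make_census


def brute_force_distance(mask, ph, pw):
    """O(n^2) nearest-set-pixel search between pixel centres."""
    out = np.empty(mask.shape)
    set_px = np.argwhere(mask)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            d2 = ((set_px[:, 0] - r) * ph) ** 2 + ((set_px[:, 1] - c) * pw) ** 2
            out[r, c] = np.sqrt(d2.min())
    return out


class TestMakeGridTemplate:
    def test_exact_tiling_without_buffer(self):
        census = make_census([(0, 0, 1000, 1000)], [10])
        tmpl, boundary = make_grid_template(census, pixel_size=100, buffer_dist=0)
        assert tmpl.shape == (10, 10)
        assert tmpl.bounds == (0, 0, 1000, 1000)

    def test_ten_km_buffer_grows_extent(self):
        census = make_census([(0, 0, 1000, 1000)], [10])
        tmpl, boundary = make_grid_template(census, pixel_size=100, buffer_dist=10_000)
        # 1 km unit + 10 km buffer each side = 21 km extent = 210 pixels
        assert tmpl.shape == (210, 210)
        assert boundary.bounds == (-10_000, -10_000, 11_000, 11_000)

    def test_geographic_crs_with_buffer_rejected(self):
        census = make_census([(0, 0, 1, 1)], [10], crs_id="EPSG:4326")
        with pytest.raises(ValueError, match="project"):
            make_grid_template(census, pixel_size=0.001, buffer_dist=10_000)


class TestRasterizeUnits:
    def test_adjacent_squares_split_grid_evenly(self, two_square_census, unit_template):
        labels = rasterize_units(two_square_census, unit_template)
        assert (labels == 0).sum() == 50
        assert (labels == 1).sum() == 50
        assert (labels == -1).sum() == 0

    def test_partition_property(self, unit_template):
        # overlapping units: every in-boundary pixel assigned exactly once
        census = make_census([(0, 0, 7, 10), (5, 0, 10, 10)], [1, 1])
        labels = rasterize_units(census, unit_template)
        assert (labels >= 0).all()
        # shared strip goes to the earlier unit in table order
        assert (labels[:, 5:7] == 0).all()

    def test_sub_pixel_unit_captures_nothing(self, unit_template):
        census = make_census([(0.1, 0.1, 0.3, 0.3), (0, 0, 10, 10)], [1, 5])
        labels = rasterize_units(census, unit_template)
        assert (labels == 0).sum() == 0


class TestDistance:
    def test_three_four_five_triangle(self, unit_template):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0] = True
        d = distance_from_mask(mask, unit_template)
        assert d[3, 4] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_all_set_gives_zero(self, unit_template):
        d = distance_from_mask(np.ones((10, 10), bool), unit_template)
        assert (d == 0).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        tmpl = GridTemplate(0, 16, 1.0, 1.0, 16, 16)
        mask = rng.random((16, 16)) < 0.15
        mask[4, 7] = True  # never empty
        d = distance_from_mask(mask, tmpl)
        np.testing.assert_array_equal(d, brute_force_distance(mask, 1.0, 1.0))

    def test_lipschitz_in_pixel_steps(self):
        rng = np.random.default_rng(6)
        tmpl = GridTemplate(0, 32, 1.0, 1.0, 32, 32)
        mask = rng.random((32, 32)) < 0.05
        mask[0, 0] = True
        d = distance_from_mask(mask, tmpl)
        assert np.abs(np.diff(d, axis=0)).max() <= 1.0 + 1e-12
        assert np.abs(np.diff(d, axis=1)).max() <= 1.0 + 1e-12

    def test_empty_class_raises(self, unit_template):
        with pytest.raises(EmptyClassError):
            class_and_distance_rasters(
                np.zeros((10, 10)), unit_template, "wat", class_value=1
            )

    def test_vector_features_roundtrip(self, unit_template):
        cls, dst = class_and_distance_rasters(
            [Point(2.5, 7.5)], unit_template, "set"
        )
        assert cls.name == "set_cls" and dst.name == "set_dst"
        assert cls.values[2, 2] == 1.0
        assert dst.values[2, 2] == 0.0
        assert (dst.values == 0).sum() >= 1
        # d = 0 exactly where mask = 1
        np.testing.assert_array_equal(dst.values == 0, cls.values == 1)


class TestAlignCovariate:
    def test_majority_aggregate_mode_and_tie(self):
        src_tmpl = GridTemplate(0, 6, 1.0, 1.0, 6, 6)
        dst_tmpl = GridTemplate(0, 6, 3.0, 3.0, 2, 2)
        src = np.ones((6, 6))
        src[0, :4] = 2.0  # block (0,0): 5 twos... build explicit blocks
        src = np.array(
            [
                [1, 1, 1, 2, 2, 1],
                [1, 1, 2, 2, 1, 1],
                [2, 2, 2, 1, 2, 1],  # top-left block: 5x1 vs 4x2 -> 1
                [1, 1, 2, 3, 3, 3],
                [2, 1, 2, 3, 3, 3],
                [2, 3, 1, 3, 3, 3],  # bottom-left: 4x1, 4x2, 1x3 -> tie
            ],
            dtype=float,
        )
        out = align_covariate(src, src_tmpl, dst_tmpl, "majority_aggregate",
                              kind=LayerKind.CATEGORICAL)
        assert out.values[0, 0] == 1.0  # 5 ones > 4 twos
        assert out.values[1, 1] == 3.0
        # tie between classes 1 and 2 in block (1,0): smallest code wins
        left = src[3:, :3].ravel()
        assert (left == 1).sum() == (left == 2).sum() == 4
        assert out.values[1, 0] == 1.0

    def test_majority_matches_bincount_oracle(self):
        rng = np.random.default_rng(9)
        src_tmpl = GridTemplate(0, 32, 1.0, 1.0, 32, 32)
        dst_tmpl = GridTemplate(0, 32, 4.0, 4.0, 8, 8)
        src = rng.integers(1, 5, size=(32, 32)).astype(float)
        out = align_covariate(src, src_tmpl, dst_tmpl, "majority_aggregate",
                              kind=LayerKind.CATEGORICAL)
        for i in range(8):
            for j in range(8):
                block = src[4 * i : 4 * i + 4, 4 * j : 4 * j + 4].astype(int).ravel()
                counts = np.bincount(block)
                expected = counts.argmax()  # argmax returns smallest on ties
                assert out.values[i, j] == expected

    def test_nearest_upsampling_constant_blocks(self):
        src_tmpl = GridTemplate(0, 300, 300.0, 300.0, 1, 1)
        dst_tmpl = GridTemplate(0, 300, 100.0, 100.0, 3, 3)
        out = align_covariate(np.array([[7.0]]), src_tmpl, dst_tmpl, "nearest")
        assert (out.values == 7.0).all()

    def test_mean_aggregate(self):
        src_tmpl = GridTemplate(0, 4, 1.0, 1.0, 4, 4)
        dst_tmpl = GridTemplate(0, 4, 2.0, 2.0, 2, 2)
        src = np.arange(16, dtype=float).reshape(4, 4)
        out = align_covariate(src, src_tmpl, dst_tmpl, "mean_aggregate")
        assert out.values[0, 0] == pytest.approx(np.mean([0, 1, 4, 5]))

    def test_continuous_with_majority_rejected(self):
        tmpl = GridTemplate(0, 4, 1.0, 1.0, 4, 4)
        with pytest.raises(ValueError):
            align_covariate(np.zeros((4, 4)), tmpl, tmpl, "majority_aggregate",
                            kind=LayerKind.CONTINUOUS)


class TestFillNodata:
    def test_adjacent_value_fills(self, unit_template):
        vals = np.full((10, 10), 7.0)
        vals[5, 5] = np.nan
        layer = CovariateLayer("x", LayerKind.CONTINUOUS, vals, unit_template)
        filled = fill_nodata_nearest(layer)
        assert filled.values[5, 5] == 7.0

    def test_matches_brute_force_nearest_valid(self):
        rng = np.random.default_rng(3)
        tmpl = GridTemplate(0, 16, 1.0, 1.0, 16, 16)
        vals = rng.integers(0, 50, size=(16, 16)).astype(float)
        holes = rng.random((16, 16)) < 0.4
        holes[0, 0] = False
        vals[holes] = np.nan
        layer = CovariateLayer("x", LayerKind.CONTINUOUS, vals, tmpl)
        filled = fill_nodata_nearest(layer)
        valid = ~holes
        d_to_valid = brute_force_distance(valid, 1.0, 1.0)
        for r, c in np.argwhere(holes):
            # the filled value must come from a cell at minimal distance
            sources = np.argwhere(valid)
            d = np.sqrt(((sources - (r, c)) ** 2).sum(axis=1))
            nearest_vals = {vals[tuple(s)] for s in sources[d == d.min()]}
            assert filled.values[r, c] in nearest_vals
            assert d.min() == d_to_valid[r, c]

    def test_valid_cells_untouched_and_fill_region_respected(self, unit_template):
        vals = np.full((10, 10), 1.0)
        vals[0, :] = np.nan
        region = np.zeros((10, 10), bool)
        region[0, :5] = True
        layer = CovariateLayer("x", LayerKind.CONTINUOUS, vals, unit_template)
        filled = fill_nodata_nearest(layer, fill_region=region)
        assert np.isfinite(filled.values[0, :5]).all()
        assert np.isnan(filled.values[0, 5:]).all()
        assert (filled.values[1:] == 1.0).all()

    def test_all_nodata_rejected(self, unit_template):
        layer = CovariateLayer(
            "x", LayerKind.CONTINUOUS, np.full((10, 10), np.nan), unit_template
        )
        with pytest.raises(ValueError):
            fill_nodata_nearest(layer)


class TestSplitBuiltClass:
    def test_urban_rural_codes(self, unit_template):
        lc = np.full((10, 10), 40.0)
        lc[2, 2] = 190.0  # built, inside urban extent
        lc[7, 7] = 190.0  # built, outside
        urban = np.zeros((10, 10), bool)
        urban[:5, :5] = True
        layer = CovariateLayer("lan_cover", LayerKind.CATEGORICAL, lc, unit_template)
        recoded, blt = split_built_class(layer, urban)
        assert recoded.values[2, 2] == 190.0
        assert recoded.values[7, 7] == 240.0
        assert recoded.values[0, 0] == 40.0  # non-built unchanged
        assert blt.name == "lan_clsBLT"
        assert blt.values[2, 2] == 1.0 and blt.values[7, 7] == 1.0
        assert blt.values.sum() == 2.0

    def test_missing_built_class_is_noop(self, unit_template):
        lc = np.full((10, 10), 40.0)
        layer = CovariateLayer("lan_cover", LayerKind.CATEGORICAL, lc, unit_template)
        recoded, blt = split_built_class(layer, np.zeros((10, 10), bool))
        np.testing.assert_array_equal(recoded.values, lc)
        assert blt.values.sum() == 0


def test_stack_shares_template_bit_exactly(small_landscape):
    tmpl = small_landscape.template
    for layer in small_landscape.stack:
        assert layer.template.same_grid(tmpl)
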