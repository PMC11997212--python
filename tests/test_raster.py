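"""Vegetation index layers, aggregation and buffer extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birdscape import raster
from birdscape.raster import RasterInputError, RasterLayer

from conftest import constant_raster


def layer(values, res=10.0):
    values = np.asarray(values, dtype=float)
    return RasterLayer((0.0, values.shape[0] * res), res, values)


# ------------------------------------------------------------ index layers


class TestNdvi:
    def test_equal_bands_give_zero(self):
        out = raster.ndvi_from_bands(layer([[0.4]]), layer([[0.4]]))
        assert out.values[0, 0] == 0.0

    def test_forced_arithmetic(self):
        out = raster.ndvi_from_bands(layer([[0.2]]), layer([[0.8]]))
        assert out.values[0, 0] == pytest.approx(0.6)

    def test_zero_denominator_is_nodata(self):
        out = raster.ndvi_from_bands(layer([[0.0]]), layer([[0.0]]))
        assert np.isnan(out.values[0, 0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(RasterInputError):
            raster.ndvi_from_bands(layer(np.ones((2, 2))), layer(np.ones((3, 3))))

    def test_bounded(self, rng):
        red = layer(rng.uniform(0, 1, (30, 30)))
        nir = layer(rng.uniform(0, 1, (30, 30)))
        out = raster.ndvi_from_bands(red, nir).values
        assert np.nanmin(out) >= -1 and np.nanmax(out) <= 1


class TestEvi:
    def test_zero_numerator(self):
        out = raster.evi_from_bands(layer([[0.9]]), layer([[0.3]]), layer([[0.3]]))
        assert out.values[0, 0] == 0.0

    def test_direct_evaluation(self):
        out = raster.evi_from_bands(layer([[0.05]]), layer([[0.1]]), layer([[0.5]]))
        assert out.values[0, 0] == pytest.approx(1.0 / 1.725)

    def test_correlates_with_ndvi_on_shared_signal(self, rng):
        # Bands driven by one latent vegetation signal: both indices should
        # track it, so they should correlate strongly with each other.
        veg = rng.uniform(0, 1, (40, 40))
        red = layer(0.35 - 0.25 * veg + rng.normal(0, 0.01, veg.shape))
        nir = layer(0.2 + 0.5 * veg + rng.normal(0, 0.01, veg.shape))
        blue = layer(np.full(veg.shape, 0.08))
        ndvi = raster.ndvi_from_bands(red, nir).values.ravel()
        evi = raster.evi_from_bands(blue, red, nir).values.ravel()
        assert np.corrcoef(ndvi, evi)[0, 1] > 0.9


class TestVegVolume:
    def test_height_times_pixel_area(self):
        ndsm = RasterLayer((0, 0.5), 0.5, np.array([[10.0]]))
        mask = RasterLayer((0, 0.5), 0.5, np.array([[1.0]]))
        assert raster.veg_volume_layer(ndsm, mask).values[0, 0] == pytest.approx(2.5)

    def test_empty_mask_gives_no_volume(self):
        ndsm = layer(np.ones((4, 4)) * 5)
        mask = layer(np.zeros((4, 4)))
        out = raster.veg_volume_layer(ndsm, mask)
        assert np.isnan(out.values).all()
        assert np.nansum(out.values) == 0.0

    def test_total_matches_loop_oracle(self, rng):
        h = rng.uniform(0, 30, (8, 8))
        m = rng.integers(0, 2, (8, 8)).astype(float)
        out = raster.veg_volume_layer(layer(h), layer(m))
        expected = sum(
            h[i, j] * 100.0 for i in range(8) for j in range(8) if m[i, j] > 0
        )
        assert np.nansum(out.values) == pytest.approx(expected)

    def test_negative_heights_clipped_with_warning(self):
        ndsm = layer(np.array([[-2.0, 3.0], [1.0, 4.0]]))
        mask = layer(np.ones((2, 2)))
        with pytest.warns(UserWarning, match="negative"):
            out = raster.veg_volume_layer(ndsm, mask)
        assert out.values[0, 0] == 0.0


class TestAggregate:
    def test_constant_preserved(self):
        out = raster.aggregate(constant_raster(0.5), 50.0, "mean")
        assert np.allclose(out.values, 0.5)

    def test_block_mean(self):
        src = layer(np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = raster.aggregate(src, 20.0, "mean")
        assert out.values[0, 0] == pytest.approx(2.5)

    def test_sum_blocks_match_loop_oracle(self, rng):
        vals = rng.uniform(0, 1, (100, 100))
        out = raster.aggregate(layer(vals, res=1.0), 10.0, "sum")
        for bi in range(10):
            for bj in range(0, 10, 3):
                assert out.values[bi, bj] == pytest.approx(
                    vals[bi * 10 : bi * 10 + 10, bj * 10 : bj * 10 + 10].sum()
                )

    def test_sum_aggregation_conserves_total(self, rng):
        vals = rng.uniform(0, 1, (60, 60))
        vals[rng.random((60, 60)) < 0.2] = np.nan
        src = layer(vals)
        out = raster.aggregate(src, 60.0, "sum")
        assert np.nansum(out.values) == pytest.approx(np.nansum(vals))

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(RasterInputError):
            raster.aggregate(constant_raster(1.0), 15.0)

    def test_all_nodata_block_stays_nodata(self):
        vals = np.ones((4, 4))
        vals[:2, :2] = np.nan
        out = raster.aggregate(layer(vals), 20.0, "mean")
        assert np.isnan(out.values[0, 0]) and out.values[1, 1] == 1.0


# -------------------------------------------------------- buffer extraction


def brute_force_buffer(rl, point, radius):
    """Independent all-pixel scan used as the oracle."""
    X, Y = rl.pixel_centres()
    inside = (X - point[0]) ** 2 + (Y - point[1]) ** 2 <= radius**2
    vals = rl.values[inside]
    return vals


class TestBufferMean:
    def test_constant(self):
        rl = constant_raster(0.42)
        for radius in (15, 40, 95):
            assert raster.buffer_mean(rl, (100, 100), radius) == pytest.approx(0.42)

    def test_single_pixel_buffer(self, rng):
        vals = rng.uniform(0, 1, (20, 20))
        rl = layer(vals)
        # centre of pixel (row 5, col 3): x = 35, y = 200 - 55 = 145
        assert raster.buffer_mean(rl, (35.0, 145.0), 4.0) == pytest.approx(vals[5, 3])

    def test_matches_loop_oracle(self, rng):
        vals = rng.uniform(0, 1, (50, 50))
        rl = layer(vals)
        got = raster.buffer_mean(rl, (251.0, 247.0), 70.0)
        oracle = brute_force_buffer(rl, (251.0, 247.0), 70.0)
        assert got == pytest.approx(oracle.mean())

    def test_empty_buffer_errors(self):
        with pytest.raises(RasterInputError):
            raster.buffer_mean(constant_raster(1.0), (-500.0, -500.0), 10.0)

    def test_partial_coverage_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            raster.buffer_mean(constant_raster(1.0), (5.0, 100.0), 50.0)


class TestBufferVolumeDensity:
    def test_all_nodata_gives_zero(self):
        rl = layer(np.full((20, 20), np.nan))
        assert raster.buffer_volume_density(rl, (100, 100), 50.0) == 0.0

    def test_uniform_one_metre_vegetation(self):
        # 1 m of vegetation on every 10 m pixel: 100 m3 per 100 m2 pixel.
        rl = constant_raster(100.0)
        assert raster.buffer_volume_density(rl, (100, 100), 60.0) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        vals = rng.uniform(0, 500, (50, 50))
        vals[rng.random((50, 50)) < 0.3] = np.nan
        rl = layer(vals)
        got = raster.buffer_volume_density(rl, (260.0, 240.0), 85.0)
        sel = brute_force_buffer(rl, (260.0, 240.0), 85.0)
        assert got == pytest.approx(np.nansum(sel) / (sel.size * 100.0))


@settings(max_examples=25, deadline=None)
@given(
    px=st.floats(100, 400),
    py=st.floats(100, 400),
    radius=st.floats(12, 120),
    seed=st.integers(0, 2**16),
)
def test_buffer_ops_agree_with_naive_scan(px, py, radius, seed):
    """Property: both buffer statistics equal the all-pixel scan."""
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0, 10, (50, 50))
    vals[rng.random((50, 50)) < 0.1] = np.nan
    rl = RasterLayer((0.0, 500.0), 10.0, vals)
    sel = brute_force_buffer(rl, (px, py), radius)
    if sel.size == 0 or np.isnan(sel).all():
        return
    assert raster.buffer_mean(rl, (px, py), radius) == pytest.approx(
        np.nanmean(sel)
    )
    assert raster.buffer_volume_density(rl, (px, py), radius) == pytest.approx(
        np.nansum(sel) / (sel.size * 100.0)
    )


class TestSiteBufferTable:
    def test_constant_landscape_identical_rows(self, small_sites):
        ndvi = RasterLayer((0.0, 2000.0), 10.0, np.full((200, 200), 0.3))
        vol = RasterLayer((0.0, 2000.0), 10.0, np.full((200, 200), 50.0))
        table = raster.site_buffer_table(small_sites, ndvi, vol, (25, 50, 100))
        assert np.allclose(table["mean_ndvi"], 0.3)
        assert np.allclose(table["veg_volume_density"], 0.5)

    def test_wider_buffers_shrink_ndvi_range(self, small_landscape, small_sites):
        _, ndvi, ndsm, mask = small_landscape
        vol = raster.veg_volume_layer(ndsm, mask)
        table = raster.site_buffer_table(
            small_sites, ndvi, vol, (25, 100, 400)
        )
        ranges = table.groupby("radius_m")["mean_ndvi"].agg(np.ptp)
        assert ranges.loc[25] > ranges.loc[100] > ranges.loc[400]

    def test_hand_computed_values(self):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        ndvi = RasterLayer((0.0, 40.0), 10.0, vals / 16)
        vol = RasterLayer((0.0, 40.0), 10.0, vals * 10)
        import pandas as pd

        sites = pd.DataFrame({"site_id": ["s0"], "x": [15.0], "y": [25.0]})
        # centre of pixel (row 1, col 1) = value 5; radius 4 -> that pixel only
        table = raster.site_buffer_table(sites, ndvi, vol, (4.0, 11.0))
        r4 = table[table.radius_m == 4.0].iloc[0]
        assert r4.mean_ndvi == pytest.approx(5 / 16)
        assert r4.veg_volume_density == pytest.approx(50 / 100)
        # radius 11 adds the 4-neighbours (values 1, 4, 6, 9): mean of 5 pixels
        r11 = table[table.radius_m == 11.0].iloc[0]
        assert r11.mean_ndvi == pytest.approx((5 + 1 + 4 + 6 + 9) / 5 / 16)

    def test_zero_density_log_warns(self, small_sites):
        ndvi = RasterLayer((0.0, 2000.0), 10.0, np.full((200, 200), 0.3))
        vol = RasterLayer((0.0, 2000.0), 10.0, np.full((200, 200), np.nan))
        with pytest.warns(UserWarning, match="zero vegetation-volume"):
            table = raster.site_buffer_table(small_sites, ndvi, vol, (25.0,))
        assert np.isfinite(table["log_veg_volume"]).all()


class TestDistance:
    def test_centre_is_zero(self):
        assert raster.distance_to_centre([(3.0, 4.0)], (3.0, 4.0))[0] == 0.0

    def test_three_four_five(self):
        assert raster.distance_to_centre([(3000.0, 4000.0)], (0.0, 0.0))[0] == 5000.0

    def test_grid_matches_loop_oracle(self, rng):
        pts = rng.uniform(-100, 100, (30, 2))
        got = raster.distance_to_centre(pts, (10.0, -20.0))
        for i, (x, y) in enumerate(pts):
            assert got[i] == pytest.approx(((x - 10) ** 2 + (y + 20) ** 2) ** 0.5)


def test_ascii_grid_roundtrip(tmp_path, rng):
    vals = rng.uniform(-1, 1, (12, 9))
    vals[0, 0] = np.nan
    rl = RasterLayer((100.0, 900.0), 25.0, vals)
    rl.to_ascii_grid(tmp_path / "g.asc")
    back = raster.read_ascii_grid(tmp_path / "g.asc")
    assert back.resolution_m == 25.0
    assert back.origin_xy == (100.0, 900.0)
    assert np.isnan(back.values[0, 0])
    assert np.allclose(back.values[1:], vals[1:], atol=1e-4)
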