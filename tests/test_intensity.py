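"""Intensity partitioning, integrated density, ratios, correlation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from placodekit import (SceneConfig, area_intensity_correlation,
                        generate_scene, integrated_density,
                        junctional_apicomedial_ratio, measure_scene_partitions,
                        partition_cell, render_channels, rescale_intensity_0_100,
                        scene_cell_table)
from placodekit.intensity import IntensityPartition


def square_polygon(x0, y0, side):
    return np.array([[x0, y0], [x0 + side, y0],
                     [x0 + side, y0 + side], [x0, y0 + side]])


class TestPartitionCell:
    def test_square_cell_band_leaves_interior(self):
        # 10x10 px cell at 1 µm/px with a 2 px band -> ~8x8 interior
        poly = square_polygon(2.0, 2.0, 10.0)
        part = partition_cell(poly, junction_band_width=2.0, pixel_size=1.0,
                              shape=(16, 16))
        assert part.apicomedial_mask.sum() == pytest.approx(64, abs=8)
        assert not (part.junctional_mask & part.apicomedial_mask).any()
        total = part.junctional_mask.sum() + part.apicomedial_mask.sum()
        assert total == pytest.approx(100, abs=8)

    def test_band_wider_than_inradius_flags_empty_medial(self):
        poly = square_polygon(2.0, 2.0, 4.0)
        part = partition_cell(poly, junction_band_width=6.0, pixel_size=1.0,
                              shape=(10, 10))
        assert part.medial_empty

    def test_mask_areas_match_polygon_offset_oracle(self, clean_scene):
        import shapely
        sc = clean_scene
        px = sc.config.pixel_size
        band = 1.0
        for i in np.flatnonzero(~scene_cell_table(sc)["boundary_cell"])[:10]:
            poly = sc.polygons[i]
            part = partition_cell(poly, band, px, sc.shape_px)
            eroded = shapely.Polygon(poly).buffer(-band / 2)
            assert part.apicomedial_mask.sum() * px ** 2 == pytest.approx(
                eroded.area, rel=0.10)


class TestIntegratedDensity:
    def test_background_image_gives_zero(self):
        img = np.full((10, 10), 7.0)
        mask = np.ones_like(img, bool)
        assert integrated_density(img, mask, background_level=7.0) == 0.0

    def test_constant_image_closed_form(self):
        img = np.full((10, 10), 9.0)
        mask = np.zeros_like(img, bool)
        mask[:5, :5] = True
        assert integrated_density(img, mask, 4.0) == 25 * 5.0

    def test_background_shift_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(10, 50, (20, 20))
        mask = img > 20
        base = integrated_density(img, mask, 5.0)
        shifted = integrated_density(img + 3.0, mask, 8.0)
        assert shifted == pytest.approx(base)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            integrated_density(np.zeros((5, 5)), np.zeros((5, 5), bool))


class TestRatio:
    def test_equal_densities_give_unity(self):
        part = IntensityPartition(1, np.ones((2, 2), bool),
                                  np.ones((2, 2), bool), 1.0,
                                  junctional_integrated_density=50.0,
                                  apicomedial_integrated_density=50.0)
        assert junctional_apicomedial_ratio(part) == 1.0

    def test_zero_medial_flagged_not_infinite(self):
        part = IntensityPartition(1, np.ones((2, 2), bool),
                                  np.zeros((2, 2), bool), 1.0,
                                  junctional_integrated_density=50.0,
                                  apicomedial_integrated_density=0.0)
        assert np.isnan(junctional_apicomedial_ratio(part))

    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0, 4.0])
    def test_configured_ratio_recovered_with_noise(self, ratio):
        cfg = SceneConfig(n_cells=100, ja_ratio=ratio, seed=3)
        sc = render_channels(generate_scene(cfg))
        df = measure_scene_partitions(sc)
        interior = ~scene_cell_table(sc)["boundary_cell"].to_numpy()
        measured = np.nanmean(df["ratio"].to_numpy()[interior])
        assert measured == pytest.approx(ratio, rel=0.15)

    def test_recovered_ratios_monotone_in_configuration(self):
        measured = []
        for ratio in (0.5, 1.0, 2.0, 4.0):
            cfg = SceneConfig(n_cells=60, ja_ratio=ratio, seed=4)
            sc = render_channels(generate_scene(cfg))
            df = measure_scene_partitions(sc)
            interior = ~scene_cell_table(sc)["boundary_cell"].to_numpy()
            measured.append(np.nanmean(df["ratio"].to_numpy()[interior]))
        assert np.all(np.diff(measured) > 0)


class TestRescale:
    def test_affine_map_to_0_100(self):
        assert np.allclose(rescale_intensity_0_100([2, 4, 6]), [0, 50, 100])

    def test_extremes_map_exactly(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(3, 9, 50)
        r = rescale_intensity_0_100(v)
        assert r.min() == 0.0 and r.max() == 100.0

    @given(st.lists(st.floats(0, 1000), min_size=3, max_size=30,
                    unique=True).filter(
                        lambda v: np.diff(np.sort(v)).min() > 1e-9))
    def test_rank_order_preserved(self, values):
        r = rescale_intensity_0_100(values)
        rho = stats.spearmanr(values, r).statistic
        assert rho == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rescale_intensity_0_100([5.0, 5.0, 5.0])


class TestAreaIntensityCorrelation:
    def test_exact_negative_line_gives_minus_one(self):
        areas = np.array([10.0, 20.0, 30.0, 40.0])
        rep = area_intensity_correlation(areas, -areas + 100)
        assert rep["pearson_r"] == pytest.approx(-1.0)

    def test_independent_variables_near_zero(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            a = rng.uniform(10, 50, 1000)
            v = rng.uniform(0, 100, 1000)
            if abs(area_intensity_correlation(a, v)["pearson_r"]) < 0.1:
                hits += 1
        assert hits >= 19

    def test_medial_density_inverse_to_area_gives_negative_r(self):
        cfg = SceneConfig(n_cells=100, seed=6)
        sc = generate_scene(cfg)
        medial = 2e4 / sc.areas  # myosin pool inversely related to area
        render_channels(sc, medial_densities=medial)
        df = measure_scene_partitions(sc)
        means = (df["apicomedial_integrated_density"]
                 + df["junctional_integrated_density"]).to_numpy() / sc.areas
        rescaled = rescale_intensity_0_100(means)
        rep = area_intensity_correlation(sc.areas, rescaled)
        assert rep["pearson_r"] < -0.5
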