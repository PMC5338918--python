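"""Generator ground truth: geometry, intensity pools, pulse trains."""

import numpy as np
import pandas as pd
import pytest
import tifffile

from placodekit import (PulsationConfig, SceneConfig, export_ground_truth,
                        generate_pulse_traces, generate_scene,
                        render_channels, scene_cell_table)
from placodekit.geometry import shoelace_area


class TestSceneGeometry:
    def test_uniform_field_has_low_area_variation(self):
        sc = generate_scene(SceneConfig(n_cells=100, field_mode="uniform",
                                        seed=2))
        cv = sc.areas.std() / sc.areas.mean()
        assert cv < 0.15

    def test_clustered_and_random_share_target_multiset(self):
        a = generate_scene(SceneConfig(n_cells=120, field_mode="clustered",
                                       seed=5))
        b = generate_scene(SceneConfig(n_cells=120, field_mode="random",
                                       seed=5))
        assert np.allclose(np.sort(a.target_areas), np.sort(b.target_areas))
        gap = np.abs(np.sort(a.areas) - np.sort(b.areas)) / np.sort(a.areas)
        assert gap.max() < 0.10

    def test_constriction_gradient_around_pit(self):
        cfg = SceneConfig(n_cells=150, field_mode="clustered",
                          constriction_depth=0.5, seed=3)
        sc = generate_scene(cfg)
        d = np.hypot(*(sc.centroids - sc.pit_center).T)
        sigma = 0.35 * cfg.placode_radius
        near = sc.areas[d < sigma].mean()
        far = sc.areas[d > 2 * sigma].mean()
        assert near < far

    def test_realized_areas_close_to_targets(self):
        sc = generate_scene(SceneConfig(n_cells=150, seed=4))
        rel = np.abs(sc.areas - sc.target_areas) / sc.target_areas
        assert rel.max() < 0.15

    def test_area_conservation_matches_region_shoelace(self):
        sc = generate_scene(SceneConfig(n_cells=100, seed=6))
        assert sc.areas.sum() == pytest.approx(shoelace_area(sc.region),
                                               rel=1e-9)

    def test_fixed_seed_reproduces_scene_exactly(self):
        a = generate_scene(SceneConfig(n_cells=80, seed=9))
        b = generate_scene(SceneConfig(n_cells=80, seed=9))
        assert np.array_equal(a.areas, b.areas)
        assert all(np.array_equal(p, q)
                   for p, q in zip(a.polygons, b.polygons))

    def test_label_image_consistent_with_polygon_areas(self):
        cfg = SceneConfig(n_cells=80, seed=12)
        sc = generate_scene(cfg)
        counts = np.bincount(sc.label_image.ravel(),
                             minlength=len(sc.cell_ids) + 1)[1:]
        raster_areas = counts * cfg.pixel_size ** 2
        rel = np.abs(raster_areas - sc.areas) / sc.areas
        assert np.median(rel) < 0.02

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(n_cells=2)
        with pytest.raises(ValueError):
            SceneConfig(constriction_depth=1.0)
        with pytest.raises(ValueError):
            SceneConfig(pixel_size=0.0)
        with pytest.raises(ValueError):
            SceneConfig(base_area=2.0, pixel_size=0.5)  # unresolvable cells


class TestRendering:
    def test_identity_rendering_without_psf_or_noise(self):
        cfg = SceneConfig(n_cells=50, psf_sigma=0.0, noise_model="none",
                          seed=8)
        sc = render_channels(generate_scene(cfg))
        vals = np.unique(sc.junction_image)
        assert set(vals) == {0.0, cfg.junction_amplitude}

    def test_zero_medial_pool_leaves_interiors_dark(self, clean_scene):
        cfg = SceneConfig(n_cells=50, noise_model="none", seed=8)
        sc = render_channels(generate_scene(cfg),
                             medial_densities=np.zeros(50))
        from placodekit.intensity import measure_scene_partitions
        df = measure_scene_partitions(sc)
        med = df["apicomedial_integrated_density"].sum()
        assert med < 0.02 * df["junctional_integrated_density"].sum()

    def test_rendered_ratio_matches_configuration(self, clean_scene):
        from placodekit.intensity import measure_scene_partitions
        df = measure_scene_partitions(clean_scene)
        gt = scene_cell_table(clean_scene)
        interior = ~gt["boundary_cell"].to_numpy()
        measured = np.nanmean(df["ratio"].to_numpy()[interior])
        assert measured == pytest.approx(clean_scene.config.ja_ratio,
                                         rel=0.10)


class TestPulseTraces:
    def test_degenerate_sd_gives_exactly_periodic_events(self):
        pcfg = PulsationConfig(mean_interval=100.0, sd_interval=0.0,
                               noise_sd=0.0)
        traces = generate_pulse_traces(pcfg, 5, seed=1)
        for tr in traces:
            gaps = np.diff(tr.true_event_times)
            assert np.allclose(gaps, 100.0)

    def test_zero_amplitude_gives_flat_baseline(self):
        pcfg = PulsationConfig(amplitude=0.0, noise_sd=0.0)
        (tr,) = generate_pulse_traces(pcfg, 1, seed=2)
        assert np.allclose(tr.intensities, pcfg.baseline)

    def test_generating_gaps_recover_configured_statistics(self):
        pcfg = PulsationConfig(noise_sd=0.0)
        traces = generate_pulse_traces(pcfg, 60, seed=3)
        gaps = np.concatenate([np.diff(tr.true_event_times)
                               for tr in traces])
        assert gaps.size >= 500
        assert gaps.mean() == pytest.approx(131.7, rel=0.03)
        assert gaps.std(ddof=1) == pytest.approx(42.8, rel=0.10)
        assert gaps.min() > pcfg.pulse_width

    def test_short_trace_warns(self):
        with pytest.warns(UserWarning):
            generate_pulse_traces(PulsationConfig(n_frames=40), 1, seed=0)


class TestExport:
    def test_ground_truth_round_trip(self, tmp_path):
        cfg = SceneConfig(n_cells=40, seed=13)
        sc = render_channels(generate_scene(cfg))
        paths = export_ground_truth(sc, tmp_path)
        lab = tifffile.imread(paths["labels"])
        assert np.array_equal(lab, sc.label_image.astype(np.uint16))
        myo = tifffile.imread(paths["myosin"])
        assert np.array_equal(myo, sc.myosin_image.astype(np.float32))
        table = pd.read_csv(paths["cells"])
        assert len(table) == len(sc.cell_ids)

    def test_exported_areas_sum_to_placode_area(self, tmp_path):
        sc = generate_scene(SceneConfig(n_cells=40, seed=14))
        paths = export_ground_truth(sc, tmp_path)
        table = pd.read_csv(paths["cells"])
        assert table["area"].sum() == pytest.approx(
            shoelace_area(sc.region), rel=0.005)
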