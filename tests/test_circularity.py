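"""Boundary tracing, one-cell-layer shifts, and circularity closed forms."""

import numpy as np
import pytest
import shapely

from placodekit import (circularity, circularity_comparison, shift_boundary,
                        trace_placode_boundary)
from placodekit.geometry import regular_polygon


def clean_union(polys):
    u = shapely.unary_union([shapely.Polygon(p) for p in polys])
    return u.buffer(1e-6).buffer(-1e-6)


class TestCircularityFormula:
    def test_fine_circle_is_unity(self):
        c = circularity(regular_polygon((0, 0), 10.0, 2000))
        assert c == pytest.approx(1.0, rel=0.005)

    def test_square_closed_form(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert circularity(sq) == pytest.approx(np.pi / 4)

    def test_hexagon_closed_form(self):
        hexagon = regular_polygon((0, 0), 1.0, 6)
        assert circularity(hexagon) == pytest.approx(np.pi * np.sqrt(3) / 6)

    def test_ngon_circularity_increases_toward_unity(self):
        cs = [circularity(regular_polygon((0, 0), 1.0, n))
              for n in (4, 8, 16, 64, 256)]
        assert np.all(np.diff(cs) > 0)
        assert cs[-1] < 1.0 + 1e-9

    def test_scale_invariance(self):
        poly = regular_polygon((0, 0), 1.0, 7)
        assert circularity(poly * 37.5) == pytest.approx(circularity(poly))

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError):
            circularity(np.zeros((4, 2)))


class TestTracePlacodeBoundary:
    def test_disk_mask_traces_near_circular_contour(self):
        yy, xx = np.mgrid[0:200, 0:200]
        lab = (((xx - 100) ** 2 + (yy - 100) ** 2) <= 70 ** 2).astype(int)
        tr = trace_placode_boundary(lab, [1], pixel_size=0.5)
        assert tr.circularity == pytest.approx(1.0, abs=0.02)
        assert not tr.midline_chord

    def test_midline_chord_closes_half_disk(self):
        yy, xx = np.mgrid[0:200, 0:200]
        lab = (((xx - 100) ** 2 + (yy - 100) ** 2) <= 80 ** 2).astype(int)
        tr = trace_placode_boundary(lab, [1], pixel_size=0.2, midline_y=20.0)
        assert tr.midline_chord
        r = 16.0  # 80 px * 0.2 µm
        expected = 4 * np.pi * (np.pi * r ** 2 / 2) / (np.pi * r + 2 * r) ** 2
        assert tr.circularity == pytest.approx(expected, rel=0.02)

    def test_perimeter_and_area_match_polygon_union_oracle(self,
                                                           smooth_scene):
        sc = smooth_scene
        tr = trace_placode_boundary(sc.label_image, sc.placode_ids,
                                    sc.config.pixel_size)
        union = clean_union([sc.polygons[i - 1] for i in sc.placode_ids])
        assert tr.perimeter == pytest.approx(union.exterior.length, rel=0.03)
        assert tr.area == pytest.approx(union.area, rel=0.005)

    def test_disconnected_placode_rejected(self):
        lab = np.zeros((50, 50), int)
        lab[5:15, 5:15] = 1
        lab[30:40, 30:40] = 2
        with pytest.raises(ValueError, match="connected"):
            trace_placode_boundary(lab, [1, 2], 0.5)


class TestShiftBoundary:
    def grid_labels(self, n=5, cell_px=24):
        lab = np.zeros((n * cell_px, n * cell_px), int)
        for r in range(n):
            for c in range(n):
                lab[r * cell_px:(r + 1) * cell_px,
                    c * cell_px:(c + 1) * cell_px] = r * n + c + 1
        return lab

    def test_block_grid_inner_is_central_block(self):
        lab = self.grid_labels(5)
        placode = [r * 5 + c + 1 for r in range(1, 4) for c in range(1, 4)]
        inner = shift_boundary(lab, placode, "inner", pixel_size=1.0)
        # inner of the 3x3 placode block is the single central cell
        assert inner.area == pytest.approx(24 ** 2, rel=0.07)
        outer = shift_boundary(lab, placode, "outer", pixel_size=1.0)
        # outer adds the edge-adjacent cross neighbours of the 3x3 block
        assert outer.area == pytest.approx((9 + 12) * 24 ** 2, rel=0.03)

    def test_single_cell_placode_has_no_inner(self):
        lab = self.grid_labels(3)
        with pytest.raises(ValueError, match="one cell layer"):
            shift_boundary(lab, [5], "inner", pixel_size=1.0)

    def test_inclusion_ordering_of_areas(self, smooth_scene):
        sc = smooth_scene
        px = sc.config.pixel_size
        tr = trace_placode_boundary(sc.label_image, sc.placode_ids, px)
        outer = shift_boundary(sc.label_image, sc.placode_ids, "outer", px)
        inner = shift_boundary(sc.label_image, sc.placode_ids, "inner", px)
        assert inner.area < tr.area < outer.area

    def test_smooth_placode_rim_more_circular_than_shifts(self,
                                                          smooth_scene):
        sc = smooth_scene
        px = sc.config.pixel_size
        tr = trace_placode_boundary(sc.label_image, sc.placode_ids, px)
        outer = shift_boundary(sc.label_image, sc.placode_ids, "outer", px)
        inner = shift_boundary(sc.label_image, sc.placode_ids, "inner", px)
        assert tr.circularity > outer.circularity
        assert tr.circularity > inner.circularity
        assert tr.circularity <= 1.02  # isoperimetric bound + rasterization


class TestComparison:
    def test_identical_groups_have_zero_t(self):
        rep = circularity_comparison([0.9, 0.8, 0.85], outer=[0.9, 0.8, 0.85])
        assert rep["placode_vs_outer"]["t"] == pytest.approx(0.0)

    def test_means_match_direct_averaging(self):
        placode = [0.95, 0.93, 0.97]
        inner = [0.60, 0.70]
        rep = circularity_comparison(placode, inner=inner)
        assert rep["placode"]["mean"] == pytest.approx(np.mean(placode))
        assert rep["inner"]["mean"] == pytest.approx(np.mean(inner))
        assert "outer" not in rep  # missing group tolerated

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            circularity_comparison([0.9])
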