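"""Geometry primitives against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_disk, make_ellipse, sweep_bisect_angle
from fourcv import geometry as geo
from fourcv.exceptions import (
    DegenerateFitError,
    EmptyRegionError,
    NoHollowError,
    ParallelLinesError,
)
from fourcv.geometry import OrientedLine, PlanarPoint


def line_tilt_deg(line: OrientedLine) -> float:
    """Tilt from image-vertical in [-90, 90)."""
    dx, dy = line.direction
    tilt = np.degrees(np.arctan2(dx, -dy))
    return ((tilt + 90.0) % 180.0) - 90.0


class TestRegionCentroid:
    def test_single_pixel(self):
        raster = np.zeros((32, 32), dtype=bool)
        raster[20, 10] = True
        assert geo.region_centroid(raster) == PlanarPoint(10.0, 20.0)

    def test_two_by_two_block(self):
        raster = np.zeros((8, 8), dtype=bool)
        raster[0:2, 0:2] = True
        assert geo.region_centroid(raster) == PlanarPoint(0.5, 0.5)

    def test_disk_center_recovered(self):
        raster = make_disk((160, 160), 64.0, 80.0, 20)
        c = geo.region_centroid(raster)
        assert abs(c.x - 64.0) < 0.1 and abs(c.y - 80.0) < 0.1

    def test_empty_raises(self):
        with pytest.raises(EmptyRegionError):
            geo.region_centroid(np.zeros((4, 4), dtype=bool))


class TestOuterContour:
    def test_square_area(self):
        raster = np.zeros((20, 20), dtype=bool)
        raster[5:15, 5:15] = True
        contour = geo.extract_outer_contour(raster)
        assert contour.closed
        assert contour.enclosed_area() == pytest.approx(100, rel=0.05)

    def test_disk_circumference(self):
        raster = make_disk((100, 100), 50, 50, 30)
        contour = geo.extract_outer_contour(raster)
        assert contour.length() == pytest.approx(2 * np.pi * 30, rel=0.03)

    def test_largest_component_wins(self):
        raster = make_disk((100, 100), 30, 30, 13)  # ~530 px
        raster |= make_disk((100, 100), 80, 80, 2.5)  # ~20 px
        contour = geo.extract_outer_contour(raster)
        assert np.all(np.hypot(*(contour.vertices - [30, 30]).T) < 15)


class TestPrincipalAxis:
    def test_horizontal_strip(self):
        raster = np.zeros((100, 100), dtype=bool)
        raster[50, 10:91] = True
        line = geo.principal_axis_line(raster)
        assert line.direction == pytest.approx((1.0, 0.0), abs=1e-9)
        assert line.anchor == PlanarPoint(50.0, 50.0)

    def test_diagonal_strip(self):
        raster = np.zeros((100, 100), dtype=bool)
        idx = np.arange(10, 90)
        raster[idx, idx] = True
        line = geo.principal_axis_line(raster)
        angle = np.degrees(np.arctan2(line.direction[1], line.direction[0]))
        assert angle == pytest.approx(45.0, abs=0.5)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_rotation_by_quarter_turns(self, k):
        raster = np.zeros((120, 120), dtype=bool)
        idx = np.arange(20, 100)
        raster[(idx * 0.3 + 40).astype(int), idx] = True  # ~17 deg strip
        base = geo.principal_axis_line(raster)
        rotated = geo.principal_axis_line(np.rot90(raster, k))
        base_angle = np.degrees(np.arctan2(base.direction[1], base.direction[0]))
        rot_angle = np.degrees(
            np.arctan2(rotated.direction[1], rotated.direction[0])
        )
        assert (rot_angle - base_angle + 90 * k) % 180 == pytest.approx(
            0.0, abs=0.5
        ) or (rot_angle - base_angle + 90 * k) % 180 == pytest.approx(
            180.0, abs=0.5
        )

    def test_isotropic_square_raises(self):
        raster = np.zeros((30, 30), dtype=bool)
        raster[5:25, 5:25] = True
        with pytest.raises(DegenerateFitError):
            geo.principal_axis_line(raster)


class TestConvexHollowCentroid:
    def test_boundary_disk_recovered(self):
        ellipse = make_ellipse((256, 300), 150, 128, 100, 80)
        hole_center = (150.0, 128.0 + 69.0)  # interior, near posterior edge
        thorax = ellipse & ~make_disk((256, 300), *hole_center, 10)
        s = geo.convex_hollow_centroid(thorax)
        assert np.hypot(s.x - hole_center[0], s.y - hole_center[1]) < 1.5

    def test_convex_region_raises(self):
        with pytest.raises(NoHollowError):
            geo.convex_hollow_centroid(make_ellipse((256, 300), 150, 128, 100, 80))

    def test_largest_hollow_wins(self):
        ellipse = make_ellipse((256, 300), 150, 128, 100, 80)
        big, small = (150.0, 197.0), (100.0, 186.0)
        thorax = (
            ellipse
            & ~make_disk((256, 300), *big, 10)
            & ~make_disk((256, 300), *small, 4)
        )
        s = geo.convex_hollow_centroid(thorax)
        assert np.hypot(s.x - big[0], s.y - big[1]) < 1.5


class TestAreaBisectingLine:
    def test_disk_any_diameter_balances(self):
        raster = make_disk((200, 200), 100, 100, 60)
        line = geo.area_bisecting_line(raster, PlanarPoint(100.0, 100.0))
        rel = np.column_stack(np.nonzero(raster))[:, ::-1] - [100.0, 100.0]
        cross = line.direction[0] * rel[:, 1] - line.direction[1] * rel[:, 0]
        imbalance = abs((cross > 1e-7).sum() - (cross < -1e-7).sum()) / len(rel)
        assert imbalance <= 0.005

    def test_ellipse_minor_axis_anchor_gives_vertical(self):
        raster = make_ellipse((256, 300), 150, 128, 100, 80)
        line = geo.area_bisecting_line(raster, PlanarPoint(150.0, 128.0 + 79.0))
        assert abs(line_tilt_deg(line)) < 0.5

    def test_agrees_with_exhaustive_sweep(self):
        raster = make_disk((220, 220), 90, 100, 55) | make_disk(
            (220, 220), 150, 120, 35
        )
        anchor = (88.0, 44.9)  # near the boundary, asymmetric
        line = geo.area_bisecting_line(raster, PlanarPoint(*anchor))
        oracle = sweep_bisect_angle(raster, anchor)
        diff = abs(line_tilt_deg(line) - oracle)
        assert min(diff, 180 - diff) <= 0.2

    def test_empty_raster_raises(self):
        with pytest.raises(EmptyRegionError):
            geo.area_bisecting_line(
                np.zeros((16, 16), dtype=bool), PlanarPoint(8.0, 8.0)
            )


class TestLineContourIntersections:
    def test_diameter_chord(self):
        contour = geo.extract_outer_contour(make_disk((100, 100), 50, 50, 30))
        line = OrientedLine(PlanarPoint(50.0, 50.0), (1.0, 0.0))
        pts = geo.line_contour_intersections(line, contour)
        assert len(pts) == 2
        assert np.hypot(pts[1].x - pts[0].x, pts[1].y - pts[0].y) == pytest.approx(
            60, abs=1.5
        )

    def test_missing_line_returns_empty(self):
        contour = geo.extract_outer_contour(make_disk((100, 100), 50, 50, 30))
        line = OrientedLine(PlanarPoint(0.0, 90.0), (1.0, 0.0))
        assert geo.line_contour_intersections(line, contour) == []

    def test_near_tangent_deduplicates(self):
        contour = geo.extract_outer_contour(make_disk((100, 100), 50, 50, 30))
        line = OrientedLine(PlanarPoint(0.0, 50.0 + 29.999), (1.0, 0.0))
        pts = geo.line_contour_intersections(line, contour)
        assert len(pts) <= 1 or np.hypot(
            pts[-1].x - pts[0].x, pts[-1].y - pts[0].y
        ) >= 0.5


class TestLineLineIntersection:
    def test_axes_cross_at_origin(self):
        x_axis = OrientedLine(PlanarPoint(5.0, 0.0), (1.0, 0.0))
        y_axis = OrientedLine(PlanarPoint(0.0, -3.0), (0.0, 1.0))
        p = geo.line_line_intersection(x_axis, y_axis)
        assert (p.x, p.y) == pytest.approx((0.0, 0.0))

    def test_hand_solved_crossing(self):
        d = np.sqrt(0.5)
        l1 = OrientedLine(PlanarPoint(0.0, 0.0), (d, d))  # y = x
        l2 = OrientedLine(PlanarPoint(0.0, 2.0), (d, -d))  # y = -x + 2
        p = geo.line_line_intersection(l1, l2)
        assert (p.x, p.y) == pytest.approx((1.0, 1.0))

    def test_parallel_raises(self):
        l1 = OrientedLine(PlanarPoint(0.0, 0.0), (1.0, 0.0))
        l2 = OrientedLine(PlanarPoint(0.0, 5.0), (1.0, 0.0))
        with pytest.raises(ParallelLinesError):
            geo.line_line_intersection(l1, l2)


class TestAngleAtVertex:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            ((0, 1), (1, 0), 90.0),
            ((1, 0), (2, 0), 0.0),
            ((1, 0), (1, 1), 45.0),
        ],
    )
    def test_known_angles(self, p1, p2, expected):
        angle = geo.angle_at_vertex(
            PlanarPoint(0.0, 0.0), PlanarPoint(*map(float, p1)), PlanarPoint(*map(float, p2))
        )
        assert angle == pytest.approx(expected, abs=1e-9)

    @given(
        st.tuples(
            *[st.floats(-50, 50).filter(lambda v: abs(v) > 0.5) for _ in range(4)]
        )
    )
    def test_symmetry_and_mirror_invariance(self, coords):
        ax, ay, bx, by = coords
        v = PlanarPoint(0.0, 0.0)
        a, b = PlanarPoint(ax, ay), PlanarPoint(bx, by)
        forward = geo.angle_at_vertex(v, a, b)
        assert forward == pytest.approx(geo.angle_at_vertex(v, b, a), abs=1e-9)
        mirrored = geo.angle_at_vertex(
            v, PlanarPoint(-ax, ay), PlanarPoint(-bx, by)
        )
        assert forward == pytest.approx(mirrored, abs=1e-9)
        assert 0.0 <= forward <= 180.0
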