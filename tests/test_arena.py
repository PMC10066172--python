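import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from centerfind.arena import (
    ArenaConstructionError,
    CalibrationError,
    SHAPE_SPECS,
    ShapeSpec,
    arena_area,
    build_arena,
    calibrate_from_landmarks,
    canonical_landmarks,
    centroid,
    contains,
    distance_to_perimeter,
    polygon_area,
    polygon_centroid,
)

EXPECTED_AREAS = {
    "circle": np.pi * 15.0**2,  # 706.86
    "square": 27.0**2,  # 729
    "triangle": np.sqrt(3) / 4 * 40.0**2,  # 692.82
    "quadrilateral": 709.06,  # shoelace on the walked vertices
}


class TestConstruction:
    @pytest.mark.parametrize("name", sorted(SHAPE_SPECS))
    def test_areas_match_closed_forms(self, arenas, name):
        assert arena_area(arenas[name]) == pytest.approx(EXPECTED_AREAS[name], abs=0.01)

    @pytest.mark.parametrize("name", sorted(SHAPE_SPECS))
    def test_areas_within_design_band(self, arenas, name):
        assert 709 * 0.97 <= arena_area(arenas[name]) <= 709 * 1.03

    def test_quadrilateral_walk_matches_explicit_vertices(self, arenas):
        # independent construction: A=(0,0), B=(37,0), then edges b, c at the
        # printed interior angles
        b = np.array([37.0, 0.0])
        c = b + 24 * np.array([np.cos(np.radians(100)), np.sin(np.radians(100))])
        d = c + 23 * np.array([np.cos(np.radians(180)), np.sin(np.radians(180))])
        expected = np.array([[0, 0], b, c, d])
        assert c == pytest.approx([32.83, 23.64], abs=0.01)
        assert d == pytest.approx([9.83, 23.64], abs=0.01)
        got = arenas["quadrilateral"].vertices
        assert polygon_area(got) == pytest.approx(polygon_area(expected), abs=1e-6)
        assert arenas["quadrilateral"].closure_residual < 1.0

    def test_quadrilateral_centered_on_area_centroid(self, arenas):
        assert polygon_centroid(arenas["quadrilateral"].vertices) == pytest.approx(
            [0, 0], abs=1e-9
        )

    def test_bad_quadrilateral_fails_to_close(self):
        spec = ShapeSpec("quadrilateral", (37, 24, 23, 26), (97, 50, 100, 113))
        with pytest.raises(ArenaConstructionError, match="close"):
            build_arena(spec)

    def test_area_outside_band_rejected(self):
        with pytest.raises(ArenaConstructionError, match="area"):
            build_arena(ShapeSpec("square", (40.0,)))

    def test_angles_must_sum_to_360(self):
        with pytest.raises(ArenaConstructionError):
            ShapeSpec("quadrilateral", (37, 24, 23, 26), (67, 80, 100, 110))


class TestGeometryQueries:
    def test_circle_distance_closed_form(self, circle_arena):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-25, 25, size=(1000, 2))
        d = distance_to_perimeter(circle_arena, pts)
        expected = np.abs(15.0 - np.linalg.norm(pts, axis=1))
        assert np.max(np.abs(d - expected)) < 1e-9

    @pytest.mark.parametrize(
        "name,point,expected",
        [
            ("circle", (10, 0), 5.0),
            ("square", (0, 0), 13.5),
            ("triangle", (0, 0), 40 / (2 * np.sqrt(3))),  # inradius 11.547
        ],
    )
    def test_known_distances(self, arenas, name, point, expected):
        assert distance_to_perimeter(arenas[name], point) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("name", ["square", "triangle", "quadrilateral"])
    def test_polygon_distance_vs_dense_sampling(self, arenas, name):
        """Brute-force oracle: densely sample the boundary at 1e4 pts/edge."""
        arena = arenas[name]
        verts = arena.vertices
        samples = []
        for a, b in zip(verts, np.roll(verts, -1, axis=0)):
            t = np.linspace(0, 1, 10_000, endpoint=False)[:, None]
            samples.append(a + t * (b - a))
        boundary = np.vstack(samples)
        rng = np.random.default_rng(1)
        pts = rng.uniform(-30, 30, size=(1000, 2))
        d = distance_to_perimeter(arena, pts)
        oracle = np.min(
            np.linalg.norm(pts[:, None, :] - boundary[None, :, :], axis=2), axis=1
        )
        assert np.max(np.abs(d - oracle)) < 1e-3

    @pytest.mark.parametrize("name", ["square", "triangle", "quadrilateral"])
    def test_polygon_distance_vs_shapely(self, arenas, name):
        arena = arenas[name]
        ring = Polygon(arena.vertices).exterior
        rng = np.random.default_rng(2)
        pts = rng.uniform(-30, 30, size=(200, 2))
        d = distance_to_perimeter(arena, pts)
        ref = np.array([ring.distance(Point(*p)) for p in pts])
        assert np.allclose(d, ref, atol=1e-9)

    def test_degenerate_polygon_area_is_zero(self):
        assert polygon_area([[0, 0], [1, 1], [2, 2]]) == 0.0

    @pytest.mark.parametrize(
        "point,expected",
        [((14.9, 0), True), ((15.1, 0), False), ((15.0, 0), True)],
    )
    def test_circle_containment(self, circle_arena, point, expected):
        assert contains(circle_arena, point) is expected

    def test_square_vertex_counts_as_inside(self, square_arena):
        assert contains(square_arena, (13.5, 13.5))
        assert not contains(square_arena, (13.6, 13.5))

    def test_centroids(self, arenas):
        for name, arena in arenas.items():
            assert centroid(arena) == pytest.approx([0, 0], abs=1e-9), name


class TestCalibration:
    def test_exact_similarity_recovered(self, square_arena):
        lm = canonical_landmarks(square_arena) * 2.0 + np.array([100.0, 50.0])
        cal = calibrate_from_landmarks(lm, square_arena)
        assert cal.scale == pytest.approx(0.5, abs=1e-12)
        assert cal.rms_residual < 1e-9
        assert cal.apply(lm) == pytest.approx(canonical_landmarks(square_arena), abs=1e-9)

    def test_correspondence_resolved_under_cyclic_shift_and_flip(self, square_arena):
        canon = canonical_landmarks(square_arena)
        for shift in range(4):
            for flip in (1, -1):
                lm = np.roll(canon[::flip], shift, axis=0) * 3.0 + 5.0
                cal = calibrate_from_landmarks(lm, square_arena)
                assert cal.rms_residual < 1e-9

    def test_noisy_landmarks_scale_within_1pct(self, square_arena):
        rng = np.random.default_rng(3)
        true_scale_px_per_cm = 2.0
        lm = canonical_landmarks(square_arena) * true_scale_px_per_cm
        lm = lm + rng.normal(0, 0.1, size=lm.shape)
        cal = calibrate_from_landmarks(lm, square_arena)
        assert cal.rms_residual > 0
        assert cal.scale == pytest.approx(0.5, rel=0.01)

    def test_roundtrip_is_identity(self, square_arena):
        lm = canonical_landmarks(square_arena) * 1.7 + np.array([20.0, -4.0])
        cal = calibrate_from_landmarks(lm, square_arena)
        back = cal.invert().apply(cal.apply(lm))
        assert np.max(np.abs(back - lm)) < 1e-9

    def test_duplicated_landmark_rejected(self, square_arena):
        lm = canonical_landmarks(square_arena).copy()
        lm[3] = lm[0]
        with pytest.raises(CalibrationError, match="duplicated"):
            calibrate_from_landmarks(lm, square_arena)

    def test_collinear_landmarks_rejected(self, square_arena):
        lm = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        with pytest.raises(CalibrationError, match="collinear"):
            calibrate_from_landmarks(lm, square_arena)

    def test_residual_threshold_enforced(self, square_arena):
        rng = np.random.default_rng(4)
        lm = canonical_landmarks(square_arena) + rng.normal(0, 5, size=(4, 2))
        with pytest.raises(CalibrationError, match="residual"):
            calibrate_from_landmarks(lm, square_arena, max_rms_cm=0.01)
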