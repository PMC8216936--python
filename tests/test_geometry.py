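"""Grid construction and point-to-transect distance geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from openscr.geometry import (GeometryError, OutOfStateSpaceError, Segment,
                              build_grid, min_distance_to_transects,
                              pairwise_center_distances,
                              point_segment_distance, segment_point_distances)

coord = st.floats(-50, 50, allow_nan=False, allow_infinity=False)


def dense_sample_distance(px, py, seg, n=100_000):
    """Brute-force oracle: min distance to n uniformly spaced segment points."""
    ts = np.linspace(0.0, 1.0, n)
    xs = seg[0] + ts * (seg[2] - seg[0])
    ys = seg[1] + ts * (seg[3] - seg[1])
    return np.hypot(xs - px, ys - py).min()


class TestPointSegmentDistance:
    def test_point_on_line(self):
        assert point_segment_distance(1, 0, (0, 0, 2, 0)) == 0.0

    def test_nearest_endpoint(self):
        # foot of perpendicular outside the segment: Pythagoras to (1, 0)
        assert point_segment_distance(0, 5, (1, 0, 3, 0)) == pytest.approx(
            np.sqrt(26))

    def test_perpendicular_foot_inside(self):
        assert point_segment_distance(2, 3, (0, 0, 4, 0)) == pytest.approx(3.0)

    def test_vertical_segment_well_defined(self):
        # slope/intercept formulations break on north-south transects
        assert point_segment_distance(2, 1, (0, 0, 0, 2)) == pytest.approx(2.0)

    def test_zero_length_segment_rejected(self):
        with pytest.raises(GeometryError):
            point_segment_distance(0, 0, (1, 1, 1, 1))
        with pytest.raises(GeometryError):
            Segment(1, 1, 1, 1)

    def test_matches_dense_sampling_oracle(self, rng):
        for _ in range(300):
            px, py = rng.uniform(-5, 5, 2)
            seg = rng.uniform(-5, 5, 4)
            if np.allclose(seg[:2], seg[2:]):
                continue
            exact = point_segment_distance(px, py, seg)
            assert exact == pytest.approx(dense_sample_distance(px, py, seg),
                                          abs=1e-4)

    @given(px=coord, py=coord, x1=coord, y1=coord, x2=coord, y2=coord)
    @settings(max_examples=200, deadline=None)
    def test_endpoint_swap_symmetry_and_bounds(self, px, py, x1, y1, x2, y2):
        if (x2 - x1) ** 2 + (y2 - y1) ** 2 == 0.0:
            return  # degenerate (incl. underflowing subnormal lengths)
        d = point_segment_distance(px, py, (x1, y1, x2, y2))
        d_swapped = point_segment_distance(px, py, (x2, y2, x1, y1))
        assert d == pytest.approx(d_swapped, abs=1e-9)
        assert d <= np.hypot(px - x1, py - y1) + 1e-12
        assert d <= np.hypot(px - x2, py - y2) + 1e-12

    def test_translation_invariance(self, rng):
        for _ in range(100):
            px, py = rng.uniform(-5, 5, 2)
            seg = rng.uniform(-5, 5, 4)
            dx, dy = rng.uniform(-100, 100, 2)
            d0 = point_segment_distance(px, py, seg)
            d1 = point_segment_distance(px + dx, py + dy,
                                        seg + np.array([dx, dy, dx, dy]))
            assert d1 == pytest.approx(d0, abs=1e-9)


class TestMinDistanceToTransects:
    def test_single_segment(self):
        d, idx = min_distance_to_transects(0, 1, [Segment(0, 0, 2, 0)])
        assert (d, idx) == (1.0, 0)

    def test_two_parallel_picks_nearer(self):
        segs = [Segment(0, 2, 2, 2), Segment(0, 1, 2, 1)]
        d, idx = min_distance_to_transects(1, 0, segs)
        assert (d, idx) == (1.0, 1)

    def test_empty_is_no_effort(self):
        with pytest.raises(GeometryError):
            min_distance_to_transects(0, 0, [])

    def test_matches_per_segment_loop(self, rng):
        for _ in range(200):
            p = rng.uniform(-3, 3, 2)
            coords = rng.uniform(-3, 3, (5, 4))
            d, idx = min_distance_to_transects(p[0], p[1], coords)
            brute = [point_segment_distance(p[0], p[1], c) for c in coords]
            assert d == pytest.approx(min(brute))
            assert idx == int(np.argmin(brute))


class TestGrid:
    def test_centers_2x2(self):
        grid = build_grid(0, 0, 1.0, 2, 2)
        expect = {(0.5, 0.5), (1.5, 0.5), (0.5, 1.5), (1.5, 1.5)}
        assert set(map(tuple, grid.pixel_centers)) == expect
        assert grid.G == 4

    def test_mask_reduces_G(self):
        grid = build_grid(0, 0, 1.0, 2, 2, valid_mask=[True, True, True, False])
        assert grid.G == 3

    def test_invalid_dimensions(self):
        with pytest.raises(GeometryError):
            build_grid(0, 0, -1.0, 2, 2)
        with pytest.raises(GeometryError):
            build_grid(0, 0, 1.0, 0, 2)

    def test_center_roundtrip_identity(self):
        grid = build_grid(-3, 2, 0.7, 10, 10)
        cx, cy = grid.pixel_centers.T
        assert np.array_equal(grid.pixel_of_point(cx, cy), np.arange(grid.G))

    def test_half_open_edge_convention(self):
        grid = build_grid(0, 0, 1.0, 2, 2)
        # a point on the shared vertical edge belongs to the right pixel
        assert grid.pixel_of_point(1.0, 0.5) == 1
        assert grid.pixel_of_point(0.5, 1.0) == 2

    def test_out_of_bounds_and_masked(self):
        grid = build_grid(0, 0, 1.0, 2, 2, valid_mask=[True, True, True, False])
        with pytest.raises(OutOfStateSpaceError):
            grid.pixel_of_point(2.5, 0.5)
        with pytest.raises(OutOfStateSpaceError):
            grid.pixel_of_point(1.5, 1.5)  # masked pixel

    def test_random_points_vs_exhaustive_containment(self, rng):
        grid = build_grid(1.0, -2.0, 0.5, 7, 5)
        x0, y0, x1, y1 = grid.bounds
        px = rng.uniform(x0, x1 - 1e-9, 1000)
        py = rng.uniform(y0, y1 - 1e-9, 1000)
        g = grid.pixel_of_point(px, py)
        half = grid.side / 2
        centers = grid.pixel_centers[g]
        assert np.all(np.abs(px - centers[:, 0]) <= half)
        assert np.all(np.abs(py - centers[:, 1]) <= half)

    def test_pairwise_center_distances(self):
        grid = build_grid(0, 0, 1.0, 3, 1)
        d = pairwise_center_distances(grid)
        assert np.allclose(d, [[0, 1, 2], [1, 0, 1], [2, 1, 0]])


def test_vectorized_distances_match_scalar(rng):
    points = rng.uniform(-4, 4, (50, 2))
    segs = rng.uniform(-4, 4, (8, 4))
    D = segment_point_distances(points, segs)
    for i in range(50):
        for l in range(8):
            assert D[i, l] == pytest.approx(
                point_segment_distance(*points[i], segs[l]))
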