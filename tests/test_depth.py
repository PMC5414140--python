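"""Halfspace depth: exact oracle behavior, grid agreement, regions, median."""

import numpy as np
import pytest

import depthqc as dq
from depthqc.depth import build_depth_grid, depth_median, depth_region
from depthqc.errors import (
    DegenerateCloudWarning,
    DegenerateInputError,
    EmptyRegionError,
    InvalidInputError,
    InvalidParameterError,
)


class TestExactDepth:
    def test_square_center_has_depth_two(self, unit_square):
        assert dq.halfspace_depth_exact([0.5, 0.5], unit_square) == 2

    def test_hull_vertex_has_depth_one(self, unit_square):
        # the supporting halfplane contains only the vertex itself
        assert dq.halfspace_depth_exact([0.0, 0.0], unit_square) == 1

    def test_point_far_outside_has_depth_zero(self, unit_square):
        assert dq.halfspace_depth_exact([50.0, -30.0], unit_square) == 0

    def test_1d_depth_is_min_side_count(self, rng):
        x = rng.normal(size=(11, 1))
        theta = np.median(x)
        cloud = dq.PointCloud.from_array(x)
        le = np.sum(x[:, 0] <= theta)
        ge = np.sum(x[:, 0] >= theta)
        assert dq.halfspace_depth_exact([theta], cloud) == min(le, ge)

    def test_3d_simplex_centroid(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        cloud = dq.PointCloud.from_array(pts)
        assert dq.halfspace_depth_exact(pts.mean(axis=0), cloud) == 1
        assert dq.halfspace_depth_exact([5.0, 5.0, 5.0], cloud) == 0

    def test_data_point_depth_at_least_one(self, rng):
        for p in (2, 3):
            pts = rng.normal(size=(15, p))
            cloud = dq.PointCloud.from_array(pts)
            for i in range(len(pts)):
                assert dq.halfspace_depth_exact(pts[i], cloud) >= 1

    def test_depth_bounded_by_half(self, rng):
        for p in (1, 2, 3):
            pts = rng.normal(size=(21, p))
            cloud = dq.PointCloud.from_array(pts)
            for theta in (pts.mean(axis=0), pts[0], rng.normal(size=p)):
                d = dq.halfspace_depth_exact(theta, cloud)
                assert 0 <= d <= int(np.ceil(21 / 2))

    @pytest.mark.parametrize("p", [2, 3])
    def test_affine_invariance(self, rng, p):
        pts = rng.normal(size=(17, p))
        cloud = dq.PointCloud.from_array(pts)
        theta = pts.mean(axis=0) + rng.normal(size=p) * 0.3
        base = dq.halfspace_depth_exact(theta, cloud)
        for _ in range(5):
            A = rng.normal(size=(p, p))
            while abs(np.linalg.det(A)) < 0.1:
                A = rng.normal(size=(p, p))
            b = rng.normal(size=p)
            mapped = dq.PointCloud.from_array(pts @ A.T + b)
            assert dq.halfspace_depth_exact(A @ theta + b, mapped) == base

    def test_dimension_mismatch_rejected(self, unit_square):
        with pytest.raises(InvalidInputError):
            dq.halfspace_depth_exact([0.5, 0.5, 0.5], unit_square)

    def test_degenerate_rank_cases_3d(self, rng):
        # collinear cloud in 3D: depth along the line, zero off it
        t = np.linspace(0, 1, 9)
        pts = np.outer(t, [1.0, 2.0, 3.0])
        cloud = dq.PointCloud.from_array(pts)
        assert dq.halfspace_depth_exact(pts[4], cloud) == 5
        assert dq.halfspace_depth_exact([0.0, 0.0, 1.0], cloud) == 0
        # coplanar cloud: interior point of the plane has positive depth
        plane = np.column_stack([rng.normal(size=(20, 2)), np.zeros(20)])
        pc = dq.PointCloud.from_array(plane)
        assert dq.halfspace_depth_exact(np.zeros(3), pc) >= 1


class TestDepthGrid:
    def test_grid_matches_exact_oracle(self, rng):
        for p in (2, 3):
            for _ in range(3):
                n = int(rng.integers(6, 26))
                cloud = dq.PointCloud.from_array(rng.normal(size=(n, p)))
                grid = build_depth_grid(cloud, resolution=9)
                nodes = grid.nodes()
                depths = grid.depth.ravel()
                for i in range(nodes.shape[0]):
                    assert depths[i] == dq.halfspace_depth_exact(nodes[i], cloud)

    def test_outside_hull_nodes_have_depth_zero(self, gauss2d):
        grid = build_depth_grid(gauss2d, resolution=16, padding=0.5)
        nodes = grid.nodes()
        corners = [0, len(nodes) - 1]
        for i in corners:
            assert grid.depth.ravel()[i] == 0

    def test_max_depth_bounded(self, gauss2d):
        grid = build_depth_grid(gauss2d, resolution=20)
        assert grid.max_depth <= int(np.ceil(gauss2d.n / 2))

    def test_4d_grid_matches_exact_on_3d_embedding(self, rng):
        # embed a 3D cloud in 4D with a tiny 4th coordinate spread so that the
        # exact 3D oracle is unavailable but cross-dim consistency holds
        pts = rng.normal(size=(12, 4))
        cloud = dq.PointCloud.from_array(pts)
        grid = build_depth_grid(cloud, resolution=8)
        assert grid.max_depth >= 1
        assert grid.depth.max() <= 6

    def test_1d_unsupported(self, rng):
        cloud = dq.PointCloud.from_array(rng.normal(size=(10, 1)))
        with pytest.raises(InvalidInputError):
            build_depth_grid(cloud)

    def test_small_resolution_rejected(self, gauss2d):
        with pytest.raises(InvalidParameterError):
            build_depth_grid(gauss2d, resolution=4)

    def test_degenerate_cloud_warns_and_uses_span(self, rng):
        flat = np.column_stack([rng.normal(size=(30, 2)), np.zeros(30)])
        cloud = dq.PointCloud.from_array(flat)
        with pytest.warns(DegenerateCloudWarning):
            grid = build_depth_grid(cloud, resolution=12)
        assert grid.q == 2
        assert grid.max_depth >= 1
        # projection round-trips within the span
        back = grid.lift(grid.project(flat))
        np.testing.assert_allclose(back, flat, atol=1e-9)

    def test_rank_one_cloud_rejected(self):
        pts = np.outer(np.linspace(0, 1, 12), [1.0, 1.0])
        with pytest.raises(DegenerateInputError):
            build_depth_grid(dq.PointCloud.from_array(pts))


class TestDepthRegions:
    def test_nesting_and_monotone_membership(self, gauss2d):
        grid = build_depth_grid(gauss2d, resolution=20)
        prev = None
        for k in range(1, grid.max_depth + 1):
            reg = depth_region(grid, k, gauss2d)
            if prev is not None:
                assert reg.n_members <= prev.n_members
                # nesting: every vertex of D_{k} lies inside D_{k-1}
                assert prev.hull.contains(reg.vertices, 1e-7).all()
            prev = reg

    def test_k_above_max_depth_raises(self, gauss2d):
        grid = build_depth_grid(gauss2d, resolution=20)
        with pytest.raises(EmptyRegionError):
            depth_region(grid, grid.max_depth + 1, gauss2d)

    def test_max_region_contains_median(self, gauss2d):
        grid = build_depth_grid(gauss2d, resolution=20)
        reg = depth_region(grid, grid.max_depth, gauss2d)
        med = depth_median(grid)
        assert reg.hull.contains(med.location[None, :], 1e-7)[0]


class TestMedianGrid:
    def test_pruned_search_matches_full_grid(self, rng):
        """The bound-pruned median search returns exactly the full grid's
        maximal depth, maximizer set and median location."""
        from depthqc.depth import build_depth_grid as full
        from depthqc.depth import median_depth_grid as pruned

        for p, n in ((2, 40), (3, 35), (2, 12)):
            cloud = dq.PointCloud.from_array(rng.standard_normal((n, p)))
            g_full = full(cloud, resolution=12)
            g_fast = pruned(cloud, resolution=12)
            m_full = depth_median(g_full)
            m_fast = depth_median(g_fast)
            assert m_full.max_depth == m_fast.max_depth
            np.testing.assert_allclose(m_full.location, m_fast.location)

    def test_incomplete_grid_refuses_level_sets(self, gauss2d):
        from depthqc.depth import median_depth_grid

        grid = median_depth_grid(gauss2d, resolution=12)
        with pytest.raises(InvalidInputError):
            depth_region(grid, 1, gauss2d)


class TestDepthMedian:
    def test_square_symmetric_grid_median_at_center(self):
        cloud = dq.PointCloud.from_array(
            [[-1.0, -1.0], [1.0, -1.0], [-1.0, 1.0], [1.0, 1.0]]
        )
        grid = build_depth_grid(cloud, resolution=11, padding=0.0)
        med = depth_median(grid)
        np.testing.assert_allclose(med.location, [0.0, 0.0], atol=1e-9)

    def test_max_depth_equals_exact_max_over_nodes(self, rng):
        cloud = dq.PointCloud.from_array(rng.standard_normal((40, 2)))
        grid = build_depth_grid(cloud, resolution=14)
        med = depth_median(grid)
        exact = max(dq.halfspace_depth_exact(node, cloud)
                    for node in grid.nodes())
        assert med.max_depth == exact

    def test_single_maximizer_collapses_hull(self, rng):
        cloud = dq.PointCloud.from_array(rng.standard_normal((31, 2)))
        grid = build_depth_grid(cloud, resolution=15)
        med = depth_median(grid)
        sel = grid.nodes()[grid.depth.ravel() == med.max_depth]
        if len(sel) == 1:
            assert med.median_hull.vertices.shape[0] == 1
        np.testing.assert_allclose(med.location, sel.mean(axis=0))
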