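"""Bag/fence/loop construction and the outlier flag rule."""

import numpy as np
import pytest

import depthqc as dq
from depthqc._hull import Hull
from depthqc.depth import DepthMedian, build_depth_grid, depth_region
from depthqc.errors import GroupTooSmallError, InvalidParameterError
from depthqc.geometry import (
    ConvexRegion,
    bagplot,
    compute_fence,
    compute_loop,
    find_k_star,
    flag_outliers,
    interpolation_weight,
    point_in_region,
)


def _median_at(location):
    loc = np.asarray(location, dtype=float)
    return DepthMedian(location=loc, max_depth=1,
                       median_hull=Hull.from_points(loc[None, :]))


class TestKStar:
    def test_rule_on_gaussian_cloud(self, gauss2d):
        grid = build_depth_grid(gauss2d, resolution=24)
        k_star, inner, outer = find_k_star(grid, gauss2d)
        half = gauss2d.n // 2
        assert inner <= half < outer
        # independent oracle scan: exact brute-force depth of every point
        exact = np.array([dq.halfspace_depth_exact(p, gauss2d)
                          for p in gauss2d.coords])
        counts = {k: int((exact >= k).sum())
                  for k in range(1, int(exact.max()) + 1)}
        expected = min(k for k, c in counts.items() if c <= half)
        assert k_star == expected
        assert inner == counts[k_star]

    def test_interpolation_weight_endpoints(self):
        assert interpolation_weight(100, 50, 61) == 0.0
        assert interpolation_weight(100, 48, 48) == 0.0
        lam = interpolation_weight(100, 48, 61)
        assert lam == pytest.approx((50 - 48) / (61 - 48))


class TestFence:
    def test_square_bag_factor_three(self):
        bag = ConvexRegion.from_points(
            [[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]]
        )
        fence = compute_fence(bag, _median_at([0.0, 0.0]), 3.0)
        got = set(map(tuple, np.round(fence.vertices, 9)))
        assert got == {(3.0, 3.0), (-3.0, 3.0), (3.0, -3.0), (-3.0, -3.0)}

    def test_factor_one_is_identity(self):
        bag = ConvexRegion.from_points(
            [[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]]
        )
        fence = compute_fence(bag, _median_at([0.0, 0.0]), 1.0)
        assert set(map(tuple, np.round(fence.vertices, 9))) == \
            set(map(tuple, np.round(bag.vertices, 9)))

    def test_cube_bag_around_offset_median(self):
        T = np.array([1.0, 1.0, 1.0])
        corners = T + 0.5 * np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        bag = ConvexRegion.from_points(corners)
        fence = compute_fence(bag, _median_at(T), 3.0)
        expected = {tuple(np.round(T + 3.0 * (v - T), 9)) for v in corners}
        assert set(map(tuple, np.round(fence.vertices, 9))) == expected

    def test_factor_below_one_rejected(self):
        bag = ConvexRegion.from_points([[0, 0], [1, 0], [0, 1]])
        with pytest.raises(InvalidParameterError):
            compute_fence(bag, _median_at([0.3, 0.3]), 0.5)


class TestLoopAndFlags:
    def test_loop_excludes_point_outside_fence(self, rng):
        pts = rng.standard_normal((100, 3))
        pts[0] = (10.0, 10.0, 10.0)  # planted at 10 sigma
        cloud = dq.PointCloud.from_array(pts)
        res = bagplot(cloud, resolution=16)
        assert "s0" in res.outliers
        if res.outliers == frozenset({"s0"}):
            # loop hull equals hull of the remaining points
            rest = Hull.from_points(pts[1:])
            got = {tuple(np.round(v, 9)) for v in res.loop.vertices}
            want = {tuple(np.round(v, 9)) for v in rest.vertices}
            assert got == want
        # the planted point is never a loop vertex
        assert not any(np.allclose(v, pts[0]) for v in res.loop.vertices)

    def test_partition_into_bag_loop_outliers(self, gauss2d):
        res = bagplot(gauss2d, resolution=20)
        tol = 1e-7
        in_fence = res.fence.hull.contains(gauss2d.coords, tol)
        flagged = np.array([i in res.outliers for i in gauss2d.ids])
        assert np.all(in_fence == ~flagged)

    def test_no_outliers_when_all_in_bag(self):
        # tight cluster: everything within the bag, nothing flagged
        rng = np.random.default_rng(5)
        pts = rng.uniform(-0.5, 0.5, size=(40, 2))
        res = bagplot(dq.PointCloud.from_array(pts), resolution=16)
        members = res.bag.hull.contains(pts, 1e-7)
        assert res.outliers <= frozenset()  # empty
        assert members.sum() >= 20 - 2

    def test_outliers_non_increasing_in_factor(self, rng):
        pts = rng.standard_normal((80, 2))
        pts[:3] += 6.0
        cloud = dq.PointCloud.from_array(pts)
        grid = build_depth_grid(cloud, resolution=20)
        sizes = []
        for factor in (1.0, 2.0, 3.0, 5.0):
            res = bagplot(cloud, factor=factor, grid=grid)
            sizes.append(len(res.outliers))
        assert sizes == sorted(sizes, reverse=True)

    def test_translation_scale_equivariance(self, rng):
        pts = rng.standard_normal((60, 2))
        pts[0] = (7.0, -7.0)
        base = bagplot(dq.PointCloud.from_array(pts), resolution=18)
        moved = bagplot(dq.PointCloud.from_array(2.5 * pts + [10.0, -4.0]),
                        resolution=18)
        assert base.outliers == moved.outliers
        np.testing.assert_allclose(
            moved.median.location, 2.5 * base.median.location + [10.0, -4.0],
            atol=1e-6)

    def test_small_group_rejected(self, rng):
        cloud = dq.PointCloud.from_array(rng.standard_normal((6, 2)))
        with pytest.raises(GroupTooSmallError):
            bagplot(cloud)


class TestPointInRegion:
    def test_centroid_and_vertices_inside(self):
        region = ConvexRegion.from_points(
            [[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]]
        )
        assert point_in_region([1.0, 1.0], region)
        assert point_in_region([0.0, 0.0], region)   # boundary inclusive
        assert not point_in_region([5.0, 5.0], region)

    def test_dimension_mismatch(self):
        region = ConvexRegion.from_points([[0, 0], [1, 0], [0, 1]])
        with pytest.raises(dq.errors.InvalidInputError):
            point_in_region([0.1, 0.1, 0.1], region)


class TestBagCoverage:
    def test_bag_holds_half_the_points(self, rng):
        # the defining property: the interpolated bag contains ~floor(n/2)
        cloud = dq.PointCloud.from_array(rng.standard_normal((100, 2)))
        res = bagplot(cloud, resolution=30)
        members = res.bag.hull.contains(cloud.coords, 1e-7).sum()
        assert abs(int(members) - 50) <= 2

    def test_flag_set_matches_independent_facet_test(self, rng):
        pts = rng.standard_normal((60, 3))
        pts[:2] *= 5.0
        cloud = dq.PointCloud.from_array(pts)
        res = bagplot(cloud, resolution=16)
        eqs = res.fence.facets
        vals = pts @ eqs[:, :-1].T + eqs[:, -1]
        outside = np.any(vals > 1e-7, axis=1)
        assert res.outliers == frozenset(
            i for i, o in zip(cloud.ids, outside) if o)
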