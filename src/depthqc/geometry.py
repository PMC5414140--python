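"""Bag, fence and loop construction from depth grids (bagplot / gemplot).

The *bag* generalizes the boxplot's box: a convex region holding the central
~50% (floor(n/2)) of the observations, obtained by interpolating between the
two consecutive depth regions D_{k*} and D_{k*-1} that bracket that count.
The *fence* inflates the bag by a factor (default 3) relative to the depth
median T; the *loop* is the hull of all observations inside the fence, and
observations strictly outside the fence are flagged as outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._hull import Hull
from .depth import (
    DepthGrid,
    DepthMedian,
    PointCloud,
    _scale_tol,
    depth_median,
    median_depth_grid,
    point_depths,
)
from .errors import (
    DegenerateRegionWarning,
    GroupTooSmallError,
    InvalidInputError,
    InvalidParameterError,
    KStarFallbackWarning,
)

__all__ = [
    "ConvexRegion",
    "BagResult",
    "find_k_star",
    "compute_bag",
    "compute_fence",
    "compute_loop",
    "flag_outliers",
    "point_in_region",
    "bagplot",
]

#: default fence inflation factor relative to the depth median
DEFAULT_FENCE_FACTOR = 3.0
#: smallest group size for which the bag rule is stable
MIN_GROUP_SIZE = 10


@dataclass
class ConvexRegion:
    """A convex polytope given by its hull (vertices + facet inequalities)."""

    hull: Hull

    @property
    def vertices(self) -> np.ndarray:
        return self.hull.vertices

    @property
    def facets(self) -> np.ndarray | None:
        """qhull facet inequalities ``A x + b <= 0`` (None if degenerate)."""
        return self.hull.equations

    @property
    def dim(self) -> int:
        return self.hull.dim

    @classmethod
    def from_points(cls, pts) -> "ConvexRegion":
        return cls(Hull.from_points(pts))


@dataclass
class BagResult:
    """Full bagplot/gemplot decomposition of one point cloud."""

    median: DepthMedian
    bag: ConvexRegion
    fence: ConvexRegion
    loop: ConvexRegion
    k_star: int
    count_inner: int
    count_outer: int
    lam: float
    outliers: frozenset
    inflation: float
    grid: DepthGrid = field(repr=False, default=None)
    cloud: PointCloud = field(repr=False, default=None)


def find_k_star(grid: DepthGrid, cloud: PointCloud, depths=None):
    """Find the depth level k* with ``#D_{k*} <= floor(n/2) < #D_{k*-1}``.

    Returns ``(k_star, count_inner, count_outer)``.  The member counts #D_k
    are exact: a point belongs to D_k iff its own halfspace depth is >= k, so
    they are obtained from the exact depth of every observation rather than
    from the lattice (whose inscribed hulls undercount near the boundary).
    If even the deepest level holds more than half the points, k* falls back
    to that level with a warning.
    """
    n = cloud.n
    if n < 4:
        raise InvalidInputError("k* rule needs at least 4 observations")
    if depths is None:
        depths = point_depths(grid, cloud)
    half = n // 2
    kmax = int(depths.max())
    prev = n  # #D_1 == n: every observation has depth >= 1
    for k in range(2, kmax + 1):
        members = int(np.sum(depths >= k))
        if members <= half:
            return k, members, prev
        prev = members
    warnings.warn(
        "no depth level satisfies the bag rule; falling back to the maximal "
        "depth level",
        KStarFallbackWarning,
        stacklevel=2,
    )
    inner = int(np.sum(depths >= kmax))
    outer = int(np.sum(depths >= kmax - 1)) if kmax > 1 else n
    return kmax, inner, outer


def interpolation_weight(n: int, count_inner: int, count_outer: int) -> float:
    """Weight lambda placing the bag at floor(n/2) members between D_{k*} and
    D_{k*-1}; 0 when the two regions hold equally many points."""
    denom = count_outer - count_inner
    if denom <= 0:
        return 0.0
    return (n // 2 - count_inner) / denom


def compute_bag(grid: DepthGrid, cloud: PointCloud) -> ConvexRegion:
    """Interpolate the bag between D_{k*} and D_{k*-1}.

    Ray-wise blending anchored at the depth median T: for each vertex v of the
    outer region, the bag vertex sits at fraction ``(1 - lambda) * t_in +
    lambda`` along the ray T -> v, where t_in is where the ray exits D_{k*}.
    """
    region, _ = _bag_with_info(grid, cloud)
    return region


def _bag_with_info(grid: DepthGrid, cloud: PointCloud):
    work = grid.project(cloud.coords)
    depths = point_depths(grid, cloud)
    k_star, inner_n, outer_n = find_k_star(grid, cloud, depths=depths)
    T = depth_median(grid)
    # Region geometry: hull of the observations with depth >= k.  Halfspace
    # depth is quasi-concave, so this hull holds exactly the #D_k member
    # points and is a faithful inner approximation of the true region D_k —
    # unlike hulls of lattice nodes, whose one-spacing shortfall near the
    # region boundary spans several depth levels at practical resolutions.
    inner_hull = Hull.from_points(work[depths >= k_star])
    outer_hull = Hull.from_points(work[depths >= k_star - 1])
    tol = _scale_tol(cloud.coords)
    # star-shaped blend anchored at T: along every direction to a vertex of
    # either region, the bag boundary sits at (1-lam) * (exit of D_{k*}) +
    # lam * (exit of D_{k*-1}); using both vertex sets guarantees the bag
    # contains the inner region
    dirs, t_ins, t_outs = [], [], []
    for v in np.vstack([outer_hull.vertices, inner_hull.vertices]):
        d = v - T.location
        if np.linalg.norm(d) <= tol:
            continue
        t_in = inner_hull.ray_exit(T.location, d, tol)
        t_out = outer_hull.ray_exit(T.location, d, tol)
        if not np.isfinite(t_out):
            t_out = max(t_in if np.isfinite(t_in) else 0.0, 1.0)
        if not np.isfinite(t_in):
            t_in = t_out
        dirs.append(d)
        t_ins.append(min(t_in, t_out))
        t_outs.append(t_out)
    dirs = np.asarray(dirs)
    t_ins = np.asarray(t_ins)[:, None]
    t_outs = np.asarray(t_outs)[:, None]

    def _bag_at(lam):
        verts = T.location + ((1.0 - lam) * t_ins + lam * t_outs) * dirs
        hull = Hull.from_points(verts)
        return hull, int(hull.contains(work, tol).sum())

    # the bag's defining property is holding floor(n/2) observations; the
    # blended hull's membership is not linear in lam, so lam is calibrated by
    # bisection to the smallest weight reaching that count
    half = cloud.n // 2
    hull, members = _bag_at(0.0)
    if members < half:
        lo, h_lo, m_lo = 0.0, hull, members
        hi = 1.0
        h_hi, m_hi = _bag_at(hi)
        for _ in range(12):
            mid = 0.5 * (lo + hi)
            h_mid, m_mid = _bag_at(mid)
            if m_mid >= half:
                hi, h_hi, m_hi = mid, h_mid, m_mid
            else:
                lo, h_lo, m_lo = mid, h_mid, m_mid
        # membership jumps discretely at the bracketed weight; take the side
        # closer to floor(n/2), preferring inclusion on ties
        if half - m_lo < m_hi - half:
            lam, hull = lo, h_lo
        else:
            lam, hull = hi, h_hi
    else:
        lam = 0.0
    bag = ConvexRegion(hull)
    info = (T, k_star, inner_n, outer_n, lam)
    return bag, info


def compute_fence(bag: ConvexRegion, T: DepthMedian,
                  factor: float = DEFAULT_FENCE_FACTOR) -> ConvexRegion:
    """Inflate the bag relative to the depth median T by ``factor``.

    Purely geometric: each bag vertex v maps to ``T + factor * (v - T)``.
    """
    if factor < 1:
        raise InvalidParameterError("fence factor must be >= 1")
    verts = T.location + factor * (bag.vertices - T.location)
    return ConvexRegion.from_points(verts)


def compute_loop(cloud: PointCloud, bag: ConvexRegion,
                 fence: ConvexRegion) -> ConvexRegion:
    """Hull of all observations inside or on the fence (the whisker analogue)."""
    tol = _scale_tol(cloud.coords, fence.vertices)
    mask = fence.hull.contains(cloud.coords, tol)
    pts = cloud.coords[mask]
    if pts.shape[0] < cloud.p + 1:
        warnings.warn(
            f"only {pts.shape[0]} observations within the fence; the loop "
            "degenerates to their hull",
            DegenerateRegionWarning,
            stacklevel=2,
        )
    return ConvexRegion.from_points(pts)


def flag_outliers(cloud: PointCloud, fence: ConvexRegion) -> frozenset:
    """Identifiers of observations strictly outside the fence.

    Boundary points (within the relative tolerance) are not outliers.
    """
    tol = _scale_tol(cloud.coords, fence.vertices)
    mask = fence.hull.contains(cloud.coords, tol)
    return frozenset(i for i, ok in zip(cloud.ids, mask) if not ok)


def point_in_region(point, region: ConvexRegion, tol: float = 1e-9) -> bool:
    """True iff ``point`` satisfies every facet inequality within ``tol``."""
    point = np.atleast_1d(np.asarray(point, dtype=float)).ravel()
    if point.shape[0] != region.dim:
        raise InvalidInputError(
            f"point has dimension {point.shape[0]}, region has {region.dim}"
        )
    scale = max(1.0, float(np.max(np.abs(region.vertices))))
    return bool(region.hull.contains(point[None, :], tol * scale)[0])


def bagplot(cloud: PointCloud, resolution: int | None = None,
            padding: float = 0.1, factor: float = DEFAULT_FENCE_FACTOR,
            min_size: int = MIN_GROUP_SIZE, grid: DepthGrid | None = None) -> BagResult:
    """End-to-end bagplot/gemplot of one point cloud.

    Builds the depth grid, locates the depth median, interpolates the bag,
    inflates the fence, collects the loop and flags outliers.  Works in 2D
    (bagplot) and 3D/4D (gemplot).  Groups smaller than ``min_size`` raise
    :class:`GroupTooSmallError` (use the boxplot path for those).
    """
    if cloud.n < min_size:
        raise GroupTooSmallError(
            f"group of size {cloud.n} below the minimum {min_size} for bag "
            "construction; use the boxplot method instead"
        )
    if grid is None:
        grid = median_depth_grid(cloud, resolution=resolution, padding=padding)
    work = PointCloud(cloud.ids, grid.project(cloud.coords))
    bag, (T, k_star, inner_n, outer_n, lam) = _bag_with_info(grid, work)
    fence = compute_fence(bag, T, factor)
    loop = compute_loop(work, bag, fence)
    outliers = flag_outliers(work, fence)
    return BagResult(median=T, bag=bag, fence=fence, loop=loop, k_star=k_star,
                     count_inner=inner_n, count_outer=outer_n, lam=lam,
                     outliers=outliers, inflation=factor, grid=grid,
                     cloud=cloud)
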