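"""Halfspace location depth: exact queries, depth grids, regions and median.

The halfspace (Tukey) location depth of a point theta with respect to a point
cloud is the smallest number of cloud points contained in any closed halfspace
whose boundary hyperplane passes through theta.  High depth marks central
locations; depth 0 marks locations separable from the cloud.

Two routes are provided:

``halfspace_depth_exact``
    Brute-force enumeration of candidate boundary orientations (point-induced
    critical angles in 2D, point-pair cross products in 3D).  Exact for any
    configuration in general position; intended for small n and as the oracle
    against which the grid route is tested.

``build_depth_grid``
    The production path: a regular lattice over the (padded) bounding box of
    the cloud with the exact depth at every node, computed by a rotating
    interval sweep.  Nodes outside the convex hull of the cloud have depth 0
    and are short-circuited.  Supports 2, 3 and 4 dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from ._hull import Hull, _affine_rank
from ._kernels import (
    _depth2_point,
    _depth3_point,
    _depth4_point,
    _exact2_point,
    _exact2_vectors,
    _exact3_rank3,
    _grid_depth_2d,
    _grid_depth_3d,
    _grid_depth_4d,
)
from .errors import (
    DegenerateCloudWarning,
    DegenerateGridError,
    DegenerateInputError,
    EmptyRegionError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "PointCloud",
    "DepthGrid",
    "DepthRegion",
    "DepthMedian",
    "halfspace_depth_exact",
    "build_depth_grid",
    "median_depth_grid",
    "depth_region",
    "depth_median",
    "point_depths",
]

#: default lattice resolution (nodes per axis) by dimension
DEFAULT_RESOLUTION = {2: 30, 3: 30, 4: 15}
#: default fractional bounding-box extension per side
DEFAULT_PADDING = 0.1

_REL_TOL = 1e-9


def _scale_tol(*arrays) -> float:
    scale = 1.0
    for a in arrays:
        if a.size:
            scale = max(scale, float(np.max(np.abs(a))))
    return _REL_TOL * scale


@dataclass(frozen=True)
class PointCloud:
    """n observations in p-dimensional space with stable sample identifiers."""

    ids: tuple
    coords: np.ndarray

    def __init__(self, ids, coords):
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        ids = tuple(ids)
        if coords.shape[0] != len(ids):
            raise InvalidInputError(
                f"{len(ids)} ids for {coords.shape[0]} coordinate rows"
            )
        if len(set(ids)) != len(ids):
            raise InvalidInputError("sample identifiers must be unique")
        if coords.shape[0] < 1 or coords.shape[1] < 1:
            raise InvalidInputError("point cloud must be non-empty")
        if not np.all(np.isfinite(coords)):
            raise InvalidInputError("point cloud contains non-finite coordinates")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "coords", coords)

    @classmethod
    def from_array(cls, coords, prefix: str = "s") -> "PointCloud":
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return cls([f"{prefix}{i}" for i in range(coords.shape[0])], coords)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def p(self) -> int:
        return self.coords.shape[1]


@dataclass
class DepthGrid:
    """Regular lattice with the halfspace depth at every node.

    The grid lives in the *working space* of the cloud: for a full-rank cloud
    that is the data space itself; for a rank-deficient cloud it is the affine
    span (``origin`` + row span of ``basis``).

    ``complete`` distinguishes fully evaluated grids (every node carries its
    depth) from median-only grids produced by the pruned search, where nodes
    that provably cannot attain the maximal depth hold the sentinel -1.
    """

    axes: list
    depth: np.ndarray          # shape (resolution,) * q
    resolution: int
    padding: float
    origin: np.ndarray         # (p,) offset of the working space
    basis: np.ndarray          # (q, p) orthonormal rows
    complete: bool = True
    _nodes: np.ndarray = field(default=None, repr=False)

    @property
    def q(self) -> int:
        """Dimension of the working space."""
        return len(self.axes)

    @property
    def max_depth(self) -> int:
        return int(self.depth.max())

    def nodes(self) -> np.ndarray:
        """All lattice nodes as an (N, q) array, C-ordered like ``depth``."""
        if self._nodes is None:
            mesh = np.meshgrid(*self.axes, indexing="ij")
            self._nodes = np.column_stack([m.ravel() for m in mesh])
        return self._nodes

    def project(self, X: np.ndarray) -> np.ndarray:
        """Map ambient-space points into the working space."""
        return (np.atleast_2d(X) - self.origin) @ self.basis.T

    def lift(self, Y: np.ndarray) -> np.ndarray:
        """Map working-space points back to the ambient space."""
        return self.origin + np.atleast_2d(Y) @ self.basis


@dataclass
class DepthRegion:
    """Convex depth region D_k: hull of all grid nodes with depth >= k."""

    k: int
    hull: Hull
    n_members: int

    @property
    def vertices(self) -> np.ndarray:
        return self.hull.vertices


@dataclass
class DepthMedian:
    """Deepest location: center of gravity of the depth-maximizing nodes."""

    location: np.ndarray
    max_depth: int
    median_hull: Hull


def halfspace_depth_exact(theta, cloud: PointCloud) -> int:
    """Exact halfspace location depth of ``theta`` w.r.t. ``cloud``.

    Supports p in {1, 2, 3}.  In 1D this is ``min(#{x <= theta}, #{x >= theta})``;
    in 2D/3D candidate boundary orientations induced by point singles/pairs
    through theta are enumerated (brute force, O(n^2)/O(n^3)).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float)).ravel()
    pts = cloud.coords
    if theta.shape[0] != cloud.p:
        raise InvalidInputError(
            f"theta has dimension {theta.shape[0]}, cloud has {cloud.p}"
        )
    if cloud.p > 3:
        raise InvalidParameterError("exact depth supports p in {1, 2, 3}")
    tol = _scale_tol(pts, theta)
    if cloud.p == 1:
        x = pts[:, 0]
        return int(min(np.sum(x <= theta[0] + tol), np.sum(x >= theta[0] - tol)))
    if cloud.p == 2:
        return int(_exact2_point(theta, pts, tol))
    return _exact3(theta, pts, tol)


def _exact3(theta, pts, tol) -> int:
    v = pts - theta
    norms = np.linalg.norm(v, axis=1)
    zero = norms <= tol
    count0 = int(np.sum(zero))
    V = np.ascontiguousarray(v[~zero])
    if V.shape[0] == 0:
        return count0
    s = np.linalg.svd(V, compute_uv=False)
    rank = int(np.sum(s > _REL_TOL * s[0]))
    if rank == 1:
        e = V[np.argmax(np.linalg.norm(V, axis=1))]
        t = V @ (e / np.linalg.norm(e))
        return count0 + int(min(np.sum(t > 0), np.sum(t < 0)))
    if rank == 2:
        _, _, vt = np.linalg.svd(V, full_matrices=False)
        W = np.ascontiguousarray(V @ vt[:2].T)
        return count0 + int(_exact2_vectors(W, W.shape[0]))
    return count0 + int(_exact3_rank3(V, V.shape[0]))


def _make_lattice(cloud: PointCloud, resolution: int | None, padding: float):
    """Shared lattice construction: axes/nodes over the (padded) bounding box
    of the cloud in its working space, with rank-degeneracy handling."""
    if cloud.p == 1:
        raise InvalidInputError(
            "1D depth grids are unsupported; use the boxplot path instead"
        )
    if cloud.p > 4:
        raise InvalidParameterError("depth grids support p in {2, 3, 4}")
    if padding < 0:
        raise InvalidParameterError("padding must be >= 0")

    coords = cloud.coords
    rank = _affine_rank(coords)
    if rank < cloud.p:
        if rank < 2:
            raise DegenerateInputError(
                "cloud spans fewer than 2 dimensions; use the boxplot path"
            )
        warnings.warn(
            f"point cloud has affine rank {rank} < {cloud.p}; computing the "
            "depth grid in its affine span",
            DegenerateCloudWarning,
            stacklevel=3,
        )
        origin = coords.mean(axis=0)
        _, _, vt = np.linalg.svd(coords - origin, full_matrices=False)
        basis = vt[:rank]
    else:
        origin = np.zeros(cloud.p)
        basis = np.eye(cloud.p)

    work = np.ascontiguousarray((coords - origin) @ basis.T)
    q = work.shape[1]
    if resolution is None:
        resolution = DEFAULT_RESOLUTION[q]
    if resolution < 8:
        raise InvalidParameterError("resolution must be >= 8")

    axes = []
    for j in range(q):
        lo, hi = float(work[:, j].min()), float(work[:, j].max())
        pad = padding * (hi - lo)
        axes.append(np.linspace(lo - pad, hi + pad, resolution))

    mesh = np.meshgrid(*axes, indexing="ij")
    nodes = np.ascontiguousarray(np.column_stack([m.ravel() for m in mesh]))
    return axes, nodes, origin, basis, work, resolution


_POINT_KERNELS = {2: _depth2_point, 3: _depth3_point, 4: _depth4_point}


def build_depth_grid(cloud: PointCloud, resolution: int | None = None,
                     padding: float = DEFAULT_PADDING) -> DepthGrid:
    """Lay a regular grid across the cloud and compute the depth at each node.

    The lattice spans the bounding box of the cloud extended by ``padding``
    (fraction of the per-axis span) on each side, with ``resolution`` nodes
    per axis.  Rank-deficient clouds are detected and the grid is built inside
    their affine span (with a :class:`DegenerateCloudWarning`).
    """
    axes, nodes, origin, basis, work, resolution = _make_lattice(
        cloud, resolution, padding)
    q = work.shape[1]
    inside = _inside_hull_mask(nodes, work)
    tol = _scale_tol(work, nodes)
    kernel = {2: _grid_depth_2d, 3: _grid_depth_3d, 4: _grid_depth_4d}[q]
    depth = kernel(nodes, work, inside, tol)
    depth = depth.reshape(tuple(len(a) for a in axes))
    if depth.max() < 1:
        raise DegenerateGridError(
            "no grid node attains depth >= 1; increase the resolution"
        )
    return DepthGrid(axes=axes, depth=depth, resolution=resolution,
                     padding=padding, origin=origin, basis=basis, _nodes=nodes)


def median_depth_grid(cloud: PointCloud, resolution: int | None = None,
                      padding: float = DEFAULT_PADDING) -> DepthGrid:
    """Same lattice as :func:`build_depth_grid`, evaluated only where needed
    to locate the depth median exactly.

    For every node a cheap upper bound on its depth is computed from a fixed
    set of projection directions (the depth is at most the smaller side count
    of any halfspace split); exact depth is then evaluated in decreasing
    bound order until no remaining node can beat the best depth found.  The
    maximal depth and the full set of maximizing nodes — hence the depth
    median — are identical to the fully evaluated grid's.  Unevaluated nodes
    hold -1 and the grid is marked ``complete=False``; level-set operations
    require a full grid.
    """
    axes, nodes, origin, basis, work, resolution = _make_lattice(
        cloud, resolution, padding)
    q = work.shape[1]
    n = work.shape[0]
    tol = _scale_tol(work, nodes)

    rng = np.random.default_rng(1234567)  # fixed: bounds must be reproducible
    U = np.vstack([np.eye(q), rng.standard_normal((24 + 4 * q, q))])
    U /= np.linalg.norm(U, axis=1, keepdims=True)
    proj_data = np.sort(work @ U.T, axis=0)       # (n, D) per-direction sorted
    proj_nodes = nodes @ U.T                      # (N, D)
    bound = np.full(nodes.shape[0], n)
    for d in range(U.shape[0]):
        col = proj_data[:, d]
        ge = n - np.searchsorted(col, proj_nodes[:, d] - tol, side="left")
        le = np.searchsorted(col, proj_nodes[:, d] + tol, side="right")
        bound = np.minimum(bound, np.minimum(ge, le))

    kernel = _POINT_KERNELS[q]
    order = np.argsort(bound)[::-1]
    depth = np.full(nodes.shape[0], -1, dtype=np.int64)
    best = 0
    for idx in order:
        if bound[idx] < best:
            break
        depth[idx] = kernel(nodes[idx], work, tol)
        if depth[idx] > best:
            best = int(depth[idx])
    if best < 1:
        raise DegenerateGridError(
            "no grid node attains depth >= 1; increase the resolution"
        )
    depth = depth.reshape(tuple(len(a) for a in axes))
    return DepthGrid(axes=axes, depth=depth, resolution=resolution,
                     padding=padding, origin=origin, basis=basis,
                     complete=False, _nodes=nodes)


def _inside_hull_mask(nodes: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Nodes inside/on the convex hull of pts (outside ones have depth 0)."""
    q = pts.shape[1]
    if pts.shape[0] < q + 1:
        return np.ones(nodes.shape[0], dtype=bool)
    try:
        tri = Delaunay(pts)
    except QhullError:
        return np.ones(nodes.shape[0], dtype=bool)
    return tri.find_simplex(nodes) >= 0


def point_depths(grid: DepthGrid, cloud: PointCloud) -> np.ndarray:
    """Exact halfspace depth of every cloud point, in the grid's working space.

    By definition a point belongs to the depth region D_k iff its own depth is
    at least k, so these values give the exact region member counts #D_k
    independently of the lattice discretization.
    """
    work = np.ascontiguousarray(grid.project(cloud.coords))
    q = work.shape[1]
    tol = _scale_tol(work)
    kernel = {2: _depth2_point, 3: _depth3_point, 4: _depth4_point}[q]
    return np.array([kernel(work[i], work, tol) for i in range(work.shape[0])],
                    dtype=int)


def depth_region(grid: DepthGrid, k: int, cloud: PointCloud) -> DepthRegion:
    """Depth region D_k: convex hull of all grid nodes with depth >= k.

    ``n_members`` counts cloud points inside or on the region hull, boundary
    inclusive under the package tolerance.
    """
    if not grid.complete:
        raise InvalidInputError(
            "this grid holds only the depth-median neighborhood; rebuild it "
            "with build_depth_grid for level sets"
        )
    if k < 1:
        raise InvalidParameterError("depth level k must be >= 1")
    if k > grid.max_depth:
        raise EmptyRegionError(
            f"depth level {k} exceeds the maximal grid depth {grid.max_depth}"
        )
    sel = grid.nodes()[grid.depth.ravel() >= k]
    hull = Hull.from_points(sel)
    work = grid.project(cloud.coords)
    tol = _scale_tol(work, sel)
    n_members = int(np.sum(hull.contains(work, tol)))
    return DepthRegion(k=k, hull=hull, n_members=n_members)


def depth_median(grid: DepthGrid) -> DepthMedian:
    """Depth median T: centroid of the depth-maximizing grid nodes.

    When several nodes attain the maximal depth, T is their center of gravity
    and ``median_hull`` retains their convex hull (a further, innermost gem);
    a unique maximizer collapses the hull to that single node.
    """
    kmax = grid.max_depth
    if kmax < 1:
        raise DegenerateGridError("all-zero depth grid has no median")
    sel = grid.nodes()[grid.depth.ravel() == kmax]
    hull = Hull.from_points(sel)
    return DepthMedian(location=sel.mean(axis=0), max_depth=kmax,
                       median_hull=hull)
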