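"""Robust convex-hull wrapper with graceful rank degeneracy.

qhull refuses point sets whose affine span is lower-dimensional than the
ambient space.  Depth computations routinely produce such sets (e.g. the
maximal-depth nodes of a grid can be collinear), so every hull in the package
goes through :class:`Hull`, which falls back to a hull inside the affine span
and keeps membership tests well-defined via an orthogonal-distance tolerance.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

_RANK_RTOL = 1e-9


def _affine_rank(pts: np.ndarray, rtol: float = _RANK_RTOL) -> int:
    centered = pts - pts.mean(axis=0)
    if centered.shape[0] == 1:
        return 0
    s = np.linalg.svd(centered, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s > rtol * s[0]))


class Hull:
    """Convex hull of a finite point set, possibly rank-deficient.

    Attributes
    ----------
    vertices : (v, dim) array of hull vertex coordinates in the ambient space.
    dim : ambient dimension.
    rank : affine rank of the point set (``rank == dim`` for a proper hull).
    equations : (f, dim + 1) qhull facet inequalities ``A x + b <= 0`` when the
        hull has full rank, else ``None``.
    """

    def __init__(self, vertices, dim, rank, equations=None, origin=None,
                 basis=None, subhull=None, interval=None):
        self.vertices = np.asarray(vertices, dtype=float)
        self.dim = dim
        self.rank = rank
        self.equations = equations
        self._origin = origin
        self._basis = basis
        self._subhull = subhull
        self._interval = interval

    # -- construction -------------------------------------------------------

    @classmethod
    def from_points(cls, pts) -> "Hull":
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        dim = pts.shape[1]
        rank = _affine_rank(pts)
        if rank == dim:
            try:
                h = ConvexHull(pts)
                return cls(pts[h.vertices], dim, rank, equations=h.equations)
            except QhullError:
                rank = max(rank - 1, 0)  # borderline degeneracy: drop to span
        return cls._from_degenerate(pts, dim, rank)

    @classmethod
    def _from_degenerate(cls, pts, dim, rank) -> "Hull":
        origin = pts.mean(axis=0)
        if rank == 0:
            return cls(origin[None, :], dim, 0, origin=origin)
        _, _, vt = np.linalg.svd(pts - origin, full_matrices=False)
        basis = vt[:rank]
        proj = (pts - origin) @ basis.T
        if rank == 1:
            t = proj[:, 0]
            lo, hi = float(t.min()), float(t.max())
            verts = origin + np.array([[lo], [hi]]) @ basis
            return cls(verts, dim, 1, origin=origin, basis=basis,
                       interval=(lo, hi))
        sub = Hull.from_points(proj)
        verts = origin + sub.vertices @ basis
        return cls(verts, dim, rank, origin=origin, basis=basis, subhull=sub)

    @property
    def is_degenerate(self) -> bool:
        return self.rank < self.dim

    # -- queries ------------------------------------------------------------

    def contains(self, X, tol: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside or on the hull (within ``tol``)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.rank == self.dim and self.equations is not None:
            vals = X @ self.equations[:, :-1].T + self.equations[:, -1]
            return np.all(vals <= tol, axis=1)
        if self.rank == 0:
            return np.linalg.norm(X - self._origin, axis=1) <= tol
        local = (X - self._origin) @ self._basis.T
        back = self._origin + local @ self._basis
        off_span = np.linalg.norm(X - back, axis=1) <= tol
        if self.rank == 1:
            lo, hi = self._interval
            t = local[:, 0]
            return off_span & (t >= lo - tol) & (t <= hi + tol)
        return off_span & self._subhull.contains(local, tol)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def ray_exit(self, start, direction, tol: float = 0.0):
        """Largest t >= 0 with ``start + t * direction`` inside the hull.

        Requires a full-rank hull; returns 0.0 when the direction immediately
        leaves (start assumed inside or on the hull).
        """
        if self.equations is None:
            return 0.0
        A = self.equations[:, :-1]
        b = self.equations[:, -1]
        num = -(A @ np.asarray(start, dtype=float) + b)   # slack, >= 0 inside
        den = A @ np.asarray(direction, dtype=float)
        mask = den > tol
        if not np.any(mask):
            return np.inf
        t = num[mask] / den[mask]
        return float(max(np.min(t), 0.0))
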