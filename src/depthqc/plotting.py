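"""Static bagplot / gemplot rendering with matplotlib.

2D bagplots draw the bag, fence and loop as nested polygons; 3D gemplots draw
the inner and outer gems as transparent hulls so the depth median stays
visible.  Output is a static image (PNG/SVG); no interactive device is
provided.
"""

from __future__ import annotations

import numpy as np

from .geometry import BagResult

__all__ = ["plot_bagplot_2d", "plot_gemplot_3d", "save_plot"]


def _ordered_polygon(vertices: np.ndarray) -> np.ndarray:
    c = vertices.mean(axis=0)
    ang = np.arctan2(vertices[:, 1] - c[1], vertices[:, 0] - c[0])
    return vertices[np.argsort(ang)]


def plot_bagplot_2d(result: BagResult, ax=None, show_fence: bool = False):
    """Draw a 2D bagplot: bag, loop, depth median, points and outliers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    loop = _ordered_polygon(result.loop.vertices)
    bag = _ordered_polygon(result.bag.vertices)
    ax.fill(loop[:, 0], loop[:, 1], color="#9ecae1", alpha=0.5,
            label="loop", zorder=1)
    ax.fill(bag[:, 0], bag[:, 1], color="#3182bd", alpha=0.5,
            label="bag", zorder=2)
    if show_fence:
        fence = _ordered_polygon(result.fence.vertices)
        ax.plot(np.append(fence[:, 0], fence[0, 0]),
                np.append(fence[:, 1], fence[0, 1]),
                "--", color="grey", lw=0.8, label="fence")
    pts = result.grid.project(result.cloud.coords)
    flagged = np.array([i in result.outliers for i in result.cloud.ids])
    ax.plot(pts[~flagged, 0], pts[~flagged, 1], "k.", ms=4, zorder=3)
    if flagged.any():
        ax.plot(pts[flagged, 0], pts[flagged, 1], "r*", ms=10,
                label="outliers", zorder=4)
        for sid, (x, y) in zip(np.asarray(result.cloud.ids)[flagged],
                               pts[flagged]):
            ax.annotate(sid, (x, y), textcoords="offset points",
                        xytext=(4, 4), fontsize=8)
    T = result.median.location
    ax.plot(T[0], T[1], "o", color="orange", ms=8, label="depth median T",
            zorder=5)
    ax.legend(loc="best", fontsize=8)
    return ax


def _hull_faces(vertices: np.ndarray):
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(vertices)
    except QhullError:
        return []
    return [vertices[simplex] for simplex in hull.simplices]


def plot_gemplot_3d(result: BagResult, ax=None):
    """Draw a static 3D gemplot: transparent inner and outer gems."""
    import matplotlib.pyplot as plt
    from mpl_toolkits.mplot3d.art3d import Poly3DCollection

    if ax is None:
        fig = plt.figure(figsize=(7, 7))
        ax = fig.add_subplot(projection="3d")
    for verts, color, alpha in ((result.loop.vertices, "#9ecae1", 0.25),
                                (result.bag.vertices, "#3182bd", 0.35)):
        faces = _hull_faces(verts)
        if faces:
            ax.add_collection3d(
                Poly3DCollection(faces, facecolor=color, alpha=alpha,
                                 edgecolor="none"))
    pts = result.grid.project(result.cloud.coords)
    flagged = np.array([i in result.outliers for i in result.cloud.ids])
    ax.scatter(pts[~flagged, 0], pts[~flagged, 1], pts[~flagged, 2],
               c="k", s=8)
    if flagged.any():
        ax.scatter(pts[flagged, 0], pts[flagged, 1], pts[flagged, 2],
                   c="red", marker="*", s=60)
    T = result.median.location
    ax.scatter([T[0]], [T[1]], [T[2]], c="orange", s=50)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    pad = 0.1 * (hi - lo)
    ax.set_xlim(lo[0] - pad[0], hi[0] + pad[0])
    ax.set_ylim(lo[1] - pad[1], hi[1] + pad[1])
    ax.set_zlim(lo[2] - pad[2], hi[2] + pad[2])
    return ax


def save_plot(ax, path) -> None:
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
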