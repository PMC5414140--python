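"""Multigroup outlier detection in a shared principal-component space.

The headline procedure: PCA is fitted once on *all* samples jointly, and
outliers are then flagged separately within each experimental group in the
shared score space, using one of

* ``1D`` — boxplot (1.5 IQR rule) on each of the first components, union of
  the per-component flags;
* ``2D`` — bagplot on each unordered pair of the first components, union of
  the per-pair flags;
* ``3D``/``4D`` — a single gemplot in the 3- or 4-dimensional score subspace.

Every flag carries provenance: which component, pair or subspace triggered it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import DepthQCError, GroupSkippedWarning, InvalidInputError
from .geometry import DEFAULT_FENCE_FACTOR, bagplot
from .depth import PointCloud
from .pca import PCAResult, fit_pca, scree

__all__ = [
    "GroupLabels",
    "OutlierReport",
    "boxplot_outliers",
    "detect_1d",
    "detect_2d",
    "detect_nd",
    "detect",
]


class GroupLabels:
    """Sample-to-group assignment, ordered like the rows of the data matrix."""

    def __init__(self, mapping):
        items = list(mapping.items()) if hasattr(mapping, "items") else list(mapping)
        self._ids = tuple(s for s, _ in items)
        if len(set(self._ids)) != len(self._ids):
            raise InvalidInputError("duplicate sample identifiers in labels")
        self._groups = {s: str(g) for s, g in items}
        if not self._groups:
            raise InvalidInputError("at least one labeled sample is required")
        sizes = {}
        for g in self._groups.values():
            sizes[g] = sizes.get(g, 0) + 1
        small = [g for g, c in sizes.items() if c < 2]
        if small:
            raise InvalidInputError(f"groups with fewer than 2 samples: {small}")

    @property
    def ids(self) -> tuple:
        return self._ids

    @property
    def group_names(self) -> tuple:
        seen = []
        for s in self._ids:
            g = self._groups[s]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def group_of(self, sample) -> str:
        return self._groups[sample]

    def indices(self, group) -> np.ndarray:
        return np.array([i for i, s in enumerate(self._ids)
                         if self._groups[s] == group], dtype=int)

    def __len__(self) -> int:
        return len(self._ids)

    def items(self):
        return ((s, self._groups[s]) for s in self._ids)


@dataclass
class OutlierReport:
    """Per-group flags with provenance and the run's parameters."""

    method: str
    flags: dict                      # group -> frozenset of sample ids
    provenance: dict                 # sample id -> tuple of trigger strings
    parameters: dict = field(default_factory=dict)
    scree_values: list = field(default_factory=list)
    labels: GroupLabels | None = field(default=None, repr=False)

    def all_flagged(self) -> frozenset:
        out = set()
        for s in self.flags.values():
            out |= s
        return frozenset(out)

    def to_dict(self) -> dict:
        return {
            "schema": "depthqc-report/1",
            "method": self.method,
            "flags": {g: sorted(s) for g, s in self.flags.items()},
            "provenance": {s: list(p) for s, p in self.provenance.items()},
            "parameters": self.parameters,
            "scree": [[j, v] for j, v in self.scree_values],
        }


def boxplot_outliers(values) -> set:
    """Indices beyond the boxplot fences Q1 - 1.5 IQR / Q3 + 1.5 IQR.

    Quartiles use linear interpolation.  A constant sample has IQR 0 and
    yields no flags.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 4:
        raise InvalidInputError("boxplot rule needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {int(i) for i in np.nonzero((values < lo) | (values > hi))[0]}


def _score_matrix(scores) -> np.ndarray:
    if isinstance(scores, PCAResult):
        return scores.scores
    return np.atleast_2d(np.asarray(scores, dtype=float))


def _check_components(Z, labels, n_components):
    if Z.shape[0] != len(labels):
        raise InvalidInputError(
            f"{Z.shape[0]} score rows but {len(labels)} labeled samples"
        )
    if Z.shape[1] < n_components:
        raise InvalidInputError(
            f"need {n_components} score columns, have {Z.shape[1]}"
        )


def detect_1d(scores, labels: GroupLabels, n_components: int = 3) -> OutlierReport:
    """Boxplot rule on each of the first ``n_components`` score columns,
    per group; a sample is flagged if any component flags it."""
    Z = _score_matrix(scores)
    _check_components(Z, labels, n_components)
    flags, prov = {}, {}
    for g in labels.group_names:
        idx = labels.indices(g)
        gids = [labels.ids[i] for i in idx]
        if idx.size < 4:
            warnings.warn(f"group '{g}' has fewer than 4 samples; skipped by "
                          "the 1D method", GroupSkippedWarning, stacklevel=2)
            flags[g] = frozenset()
            continue
        hit = set()
        for j in range(n_components):
            for i in boxplot_outliers(Z[idx, j]):
                sid = gids[i]
                hit.add(sid)
                prov.setdefault(sid, []).append(f"PC{j + 1}")
        flags[g] = frozenset(hit)
    return OutlierReport(method="1D", flags=flags,
                         provenance={s: tuple(p) for s, p in prov.items()},
                         parameters={"n_components": n_components},
                         labels=labels)


def detect_2d(scores, labels: GroupLabels, n_components: int = 3,
              pairs=None, resolution: int | None = None,
              fence_factor: float = DEFAULT_FENCE_FACTOR,
              padding: float = 0.1) -> OutlierReport:
    """Bagplot on component pairs per group, union of per-pair flags.

    ``pairs`` defaults to all unordered pairs of the first ``n_components``
    (the union protocol); pass e.g. ``[(1, 2)]`` to restrict to PC1 x PC2.
    """
    Z = _score_matrix(scores)
    _check_components(Z, labels, n_components)
    if pairs is None:
        pairs = [(a + 1, b + 1) for a, b in combinations(range(n_components), 2)]
    flags, prov = {}, {}
    for g in labels.group_names:
        idx = labels.indices(g)
        gids = [labels.ids[i] for i in idx]
        hit = set()
        for a, b in pairs:
            cloud = PointCloud(gids, Z[idx][:, [a - 1, b - 1]])
            try:
                res = bagplot(cloud, resolution=resolution, padding=padding,
                              factor=fence_factor)
            except DepthQCError as exc:
                warnings.warn(f"group '{g}', pair PC{a}xPC{b} skipped: {exc}",
                              GroupSkippedWarning, stacklevel=2)
                continue
            for sid in res.outliers:
                hit.add(sid)
                prov.setdefault(sid, []).append(f"PC{a}xPC{b}")
        flags[g] = frozenset(hit)
    return OutlierReport(method="2D", flags=flags,
                         provenance={s: tuple(p) for s, p in prov.items()},
                         parameters={"n_components": n_components,
                                     "pairs": list(pairs),
                                     "resolution": resolution,
                                     "fence_factor": fence_factor,
                                     "padding": padding},
                         labels=labels)


def detect_nd(scores, labels: GroupLabels, n_components: int = 3,
              resolution: int | None = None,
              fence_factor: float = DEFAULT_FENCE_FACTOR,
              padding: float = 0.1) -> OutlierReport:
    """One gemplot per group in the ``n_components``-dimensional score space
    (3 or 4 components)."""
    if n_components not in (3, 4):
        raise InvalidInputError("the gemplot path supports 3 or 4 components")
    Z = _score_matrix(scores)
    _check_components(Z, labels, n_components)
    subspace = "x".join(f"PC{j + 1}" for j in range(n_components))
    flags, prov = {}, {}
    for g in labels.group_names:
        idx = labels.indices(g)
        gids = [labels.ids[i] for i in idx]
        cloud = PointCloud(gids, Z[idx][:, :n_components])
        try:
            res = bagplot(cloud, resolution=resolution, padding=padding,
                          factor=fence_factor)
        except DepthQCError as exc:
            warnings.warn(f"group '{g}' skipped: {exc}",
                          GroupSkippedWarning, stacklevel=2)
            flags[g] = frozenset()
            continue
        flags[g] = res.outliers
        for sid in res.outliers:
            prov.setdefault(sid, []).append(subspace)
    return OutlierReport(method=f"{n_components}D", flags=flags,
                         provenance={s: tuple(p) for s, p in prov.items()},
                         parameters={"n_components": n_components,
                                     "resolution": resolution,
                                     "fence_factor": fence_factor,
                                     "padding": padding},
                         labels=labels)


def detect(X, labels: GroupLabels, method: str = "3d", n_components: int = 3,
           resolution: int | None = None,
           fence_factor: float = DEFAULT_FENCE_FACTOR,
           padding: float = 0.1) -> OutlierReport:
    """End-to-end detection on an expression matrix (samples x features).

    PCA is fitted on all samples jointly (never per group); the requested
    method then flags outliers within each group in the shared score space.
    Scree values are attached so that users can judge whether the leading
    components carry enough variance for the flags to be trusted.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(labels):
        raise InvalidInputError(
            f"matrix has {X.shape[0]} samples but labels cover {len(labels)}"
        )
    method = method.lower()
    if method == "4d":
        n_components = max(n_components, 4)
    rmax = min(X.shape[0] - 1, X.shape[1])
    r = min(rmax, max(n_components, 10))
    pca = fit_pca(X, r=r)
    if method == "1d":
        rep = detect_1d(pca, labels, n_components)
    elif method == "2d":
        rep = detect_2d(pca, labels, n_components, resolution=resolution,
                        fence_factor=fence_factor, padding=padding)
    elif method in ("3d", "4d"):
        nc = 4 if method == "4d" else n_components
        rep = detect_nd(pca, labels, nc, resolution=resolution,
                        fence_factor=fence_factor, padding=padding)
    else:
        raise InvalidInputError(f"unknown method '{method}'")
    rep.scree_values = scree(pca)
    rep.parameters["method"] = rep.method
    return rep
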