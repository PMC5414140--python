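"""Numba kernels for halfspace location depth.

Two independent computational routes are kept on purpose:

* the *sweep* route (`_depth2_point`, `_depth3_point`, `_depth4_point` and the
  grid drivers) is the production path.  For a query location theta it scans,
  for every data direction, the circle of halfspace normals orthogonal to that
  direction.  On such a circle the count of points in the closed halfspace is a
  sum of half-circle indicator intervals, so its minimum over the open arcs of
  the induced arrangement can be found by an event sweep.  Cells of the full
  normal arrangement adjacent to the circle differ from the on-circle count
  only by the points exactly (anti)parallel to the scanned direction, which is
  corrected via the parallel/antiparallel multiplicities.  The global minimum
  over all cells — the halfspace depth — is the minimum over all circles.

* the *brute-force* route (`_exact2_point`, `_exact3_rank3`) enumerates
  candidate boundary orientations induced by single points (2D) or point pairs
  (3D) through theta, evaluating perturbed normals directly.  It is used as the
  test oracle and for small exact queries.

All depth counts use closed halfspaces: a point on the boundary hyperplane is
counted on both sides.
"""

import numpy as np
from numba import njit

__all__ = [
    "_depth2_point",
    "_depth3_point",
    "_depth4_point",
    "_grid_depth_2d",
    "_grid_depth_3d",
    "_grid_depth_4d",
    "_exact2_point",
    "_exact2_vectors",
    "_exact3_rank3",
]

# relative tolerance below which a projected vector counts as parallel to the
# scan direction (matches the package-wide boundary tolerance)
_PAR_TOL = 1e-9


@njit(cache=True)
def _pseudoangle(a, b):
    # monotone surrogate for atan2(b, a), increasing counter-clockwise from
    # angle 0 (value 0) to 2*pi (value 4); avoids trig in the inner loop
    r = a / (abs(a) + abs(b))
    if b >= 0.0:
        return 1.0 - r
    return 3.0 + r


@njit(cache=True)
def _bucket_argsort(keys, order, n, counts, tmp):
    """order[0:n] = indices sorting keys[0:n]; keys must lie in [0, 4).

    Counting sort into 256 buckets followed by an insertion pass that fixes
    the (rare) within-bucket inversions; effectively O(n) for our key sizes.
    """
    B = counts.shape[0]
    for b in range(B):
        counts[b] = 0
    scale = B / 4.0000001
    for i in range(n):
        b = int(keys[i] * scale)
        if b >= B:
            b = B - 1
        tmp[i] = b
        counts[b] += 1
    s = 0
    for b in range(B):
        c = counts[b]
        counts[b] = s
        s += c
    for i in range(n):
        b = tmp[i]
        order[counts[b]] = i
        counts[b] += 1
    for i in range(1, n):
        t = order[i]
        kt = keys[t]
        j = i - 1
        while j >= 0 and keys[order[j]] > kt:
            order[j + 1] = order[j]
            j -= 1
        order[j + 1] = t


@njit(cache=True)
def _arc_min_buf(aa, bb, m, ev_a, ev_b, enter, pa, order, counts, tmp):
    """Minimum over open normal arcs of #{j < m : u . w_j >= 0}.

    w_j = (aa[j], bb[j]) are nonzero 2D vectors; u runs over the unit circle.
    Each point contributes a closed half-circle indicator; arcs are delimited
    by the interval endpoints (events).  The returned value is the minimum of
    the count strictly inside the arcs, i.e. over the cells of the 1D
    arrangement.  The ev_*/enter/pa/order buffers must hold >= 2 m entries.
    """
    if m == 0:
        return 0
    tot = 2 * m
    for j in range(m):
        # interval for w_j is [gamma_j - pi/2, gamma_j + pi/2]
        ev_a[2 * j] = bb[j]          # enter event at gamma_j - pi/2
        ev_b[2 * j] = -aa[j]
        enter[2 * j] = True
        ev_a[2 * j + 1] = -bb[j]     # leave event at gamma_j + pi/2
        ev_b[2 * j + 1] = aa[j]
        enter[2 * j + 1] = False
        pa[2 * j] = _pseudoangle(ev_a[2 * j], ev_b[2 * j])
        pa[2 * j + 1] = _pseudoangle(ev_a[2 * j + 1], ev_b[2 * j + 1])
    _bucket_argsort(pa, order, tot, counts, tmp)

    # start the sweep after the widest angular gap, so that the initial arc
    # (whose count is evaluated directly) is never a numerical sliver
    widest = 0
    gap = 4.0 - pa[order[tot - 1]] + pa[order[0]]
    for k in range(tot - 1):
        g = pa[order[k + 1]] - pa[order[k]]
        if g > gap:
            gap = g
            widest = k + 1
    last = order[(widest + tot - 1) % tot]
    first = order[widest]

    # midpoint of that arc (from the last event ccw to the first), found
    # from the two event vectors without trigonometry
    la = ev_a[last]
    lb = ev_b[last]
    fa = ev_a[first]
    fb = ev_b[first]
    ln = np.sqrt(la * la + lb * lb)
    la /= ln
    lb /= ln
    fn = np.sqrt(fa * fa + fb * fb)
    fa /= fn
    fb /= fn
    cr = la * fb - lb * fa
    sa = la + fa
    sb = lb + fb
    if cr > 0.0:
        sn = np.sqrt(sa * sa + sb * sb)
        mid_a = sa / sn
        mid_b = sb / sn
    elif cr < 0.0:
        sn = np.sqrt(sa * sa + sb * sb)
        mid_a = -sa / sn
        mid_b = -sb / sn
    else:
        dt = la * fa + lb * fb
        if dt > 0.0:
            # single event direction: wrap arc is (almost) the full circle
            mid_a = -la
            mid_b = -lb
        else:
            # antipodal events: wrap arc spans exactly pi, take its bisector
            mid_a = -lb
            mid_b = la

    cur = 0
    for j in range(m):
        if aa[j] * mid_a + bb[j] * mid_b >= 0.0:
            cur += 1
    best = cur

    # walk the arcs in ccw order from the start; events closer together than
    # the boundary tolerance are one crossing (recording between them would
    # resurrect sliver arcs created by rounding, e.g. for a query point
    # almost exactly between two observations)
    i = 0
    while i < tot:
        p0 = pa[order[(widest + i) % tot]]
        delta = 0
        while i < tot:
            idx = order[(widest + i) % tot]
            d = pa[idx] - p0
            if d < 0.0:
                d += 4.0  # crossing the pseudoangle wrap
            if d > 1e-9:
                break
            if enter[idx]:
                delta += 1
            else:
                delta -= 1
            i += 1
        cur += delta
        if cur < best:
            best = cur
    return best


@njit(cache=True)
def _depth2_point(theta, pts, eps):
    """Halfspace depth of theta w.r.t. 2D points (sweep route)."""
    n = pts.shape[0]
    aa = np.empty(n)
    bb = np.empty(n)
    m = 0
    count0 = 0
    for j in range(n):
        vx = pts[j, 0] - theta[0]
        vy = pts[j, 1] - theta[1]
        if np.sqrt(vx * vx + vy * vy) <= eps:
            count0 += 1
        else:
            aa[m] = vx
            bb[m] = vy
            m += 1
    ev_a = np.empty(2 * n)
    ev_b = np.empty(2 * n)
    enter = np.empty(2 * n, np.bool_)
    pa = np.empty(2 * n)
    order = np.empty(2 * n, np.int64)
    counts = np.empty(256, np.int64)
    tmp = np.empty(2 * n, np.int64)
    return count0 + _arc_min_buf(aa, bb, m, ev_a, ev_b, enter, pa, order,
                                 counts, tmp)


@njit(cache=True)
def _cellmin3(V, m):
    """Min over cells of the great-circle arrangement of #{u . V_j >= 0}.

    V[:m] are nonzero 3D vectors; u runs over the unit sphere.  Every cell of
    the arrangement is adjacent to some circle {u : u . V_i = 0}; the on-circle
    arc minimum corrected by the (anti)parallel multiplicities yields the
    adjacent cell counts exactly.
    """
    if m == 0:
        return 0
    best = m
    norms = np.empty(m)
    for j in range(m):
        norms[j] = np.sqrt(V[j, 0] ** 2 + V[j, 1] ** 2 + V[j, 2] ** 2)
    aa = np.empty(m)
    bb = np.empty(m)
    ev_a = np.empty(2 * m)
    ev_b = np.empty(2 * m)
    enter = np.empty(2 * m, np.bool_)
    pa = np.empty(2 * m)
    order = np.empty(2 * m, np.int64)
    counts = np.empty(256, np.int64)
    tmp = np.empty(2 * m, np.int64)
    for i in range(m):
        v0 = V[i, 0] / norms[i]
        v1 = V[i, 1] / norms[i]
        v2 = V[i, 2] / norms[i]
        # orthonormal basis (e1, e2) of the plane orthogonal to vhat
        a0 = abs(v0)
        a1 = abs(v1)
        a2 = abs(v2)
        if a0 <= a1 and a0 <= a2:
            e1x, e1y, e1z = 1.0 - v0 * v0, -v0 * v1, -v0 * v2
        elif a1 <= a2:
            e1x, e1y, e1z = -v1 * v0, 1.0 - v1 * v1, -v1 * v2
        else:
            e1x, e1y, e1z = -v2 * v0, -v2 * v1, 1.0 - v2 * v2
        en = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        e1x /= en
        e1y /= en
        e1z /= en
        e2x = v1 * e1z - v2 * e1y
        e2y = v2 * e1x - v0 * e1z
        e2z = v0 * e1y - v1 * e1x

        p = 0
        q = 0
        mm = 0
        for j in range(m):
            wa = V[j, 0] * e1x + V[j, 1] * e1y + V[j, 2] * e1z
            wb = V[j, 0] * e2x + V[j, 1] * e2y + V[j, 2] * e2z
            if wa * wa + wb * wb <= (_PAR_TOL * norms[j]) ** 2:
                if V[j, 0] * v0 + V[j, 1] * v1 + V[j, 2] * v2 > 0.0:
                    p += 1
                else:
                    q += 1
            else:
                aa[mm] = wa
                bb[mm] = wb
                mm += 1
        if p < q:
            cand = _arc_min_buf(aa, bb, mm, ev_a, ev_b, enter, pa, order,
                                counts, tmp) + p
        else:
            cand = _arc_min_buf(aa, bb, mm, ev_a, ev_b, enter, pa, order,
                                counts, tmp) + q
        if cand < best:
            best = cand
        if best == 0:
            return 0
    return best


@njit(cache=True)
def _depth3_point(theta, pts, eps):
    """Halfspace depth of theta w.r.t. 3D points (sweep route)."""
    n = pts.shape[0]
    V = np.empty((n, 3))
    m = 0
    count0 = 0
    for j in range(n):
        vx = pts[j, 0] - theta[0]
        vy = pts[j, 1] - theta[1]
        vz = pts[j, 2] - theta[2]
        if np.sqrt(vx * vx + vy * vy + vz * vz) <= eps:
            count0 += 1
        else:
            V[m, 0] = vx
            V[m, 1] = vy
            V[m, 2] = vz
            m += 1
    return count0 + _cellmin3(V, m)


@njit(cache=True)
def _depth4_point(theta, pts, eps):
    """Halfspace depth of theta w.r.t. 4D points.

    Recursive reduction: for each data direction, project the remaining
    vectors onto its 3D orthogonal complement and take the cell minimum there,
    corrected by (anti)parallel multiplicities.
    """
    n = pts.shape[0]
    V = np.empty((n, 4))
    m = 0
    count0 = 0
    for j in range(n):
        nv = 0.0
        for c in range(4):
            d = pts[j, c] - theta[c]
            V[m, c] = d
            nv += d * d
        if np.sqrt(nv) <= eps:
            count0 += 1
        else:
            m += 1
    if m == 0:
        return count0

    norms = np.empty(m)
    for j in range(m):
        norms[j] = np.sqrt(V[j, 0] ** 2 + V[j, 1] ** 2 + V[j, 2] ** 2 + V[j, 3] ** 2)
    W = np.empty((m, 3))
    vhat = np.empty(4)
    B = np.empty((3, 4))
    g = np.empty(4)
    best = m
    for i in range(m):
        for c in range(4):
            vhat[c] = V[i, c] / norms[i]
        # orthonormal basis of the complement: project out vhat from the three
        # coordinate axes other than the dominant one, Gram-Schmidt as we go
        dom = 0
        for c in range(1, 4):
            if abs(vhat[c]) > abs(vhat[dom]):
                dom = c
        nb = 0
        for ax in range(4):
            if ax == dom:
                continue
            for c in range(4):
                g[c] = -vhat[ax] * vhat[c]
            g[ax] += 1.0
            for r in range(nb):
                d = 0.0
                for c in range(4):
                    d += g[c] * B[r, c]
                for c in range(4):
                    g[c] -= d * B[r, c]
            gn = 0.0
            for c in range(4):
                gn += g[c] * g[c]
            gn = np.sqrt(gn)
            for c in range(4):
                B[nb, c] = g[c] / gn
            nb += 1

        p = 0
        q = 0
        mm = 0
        for j in range(m):
            wn = 0.0
            for r in range(3):
                d = 0.0
                for c in range(4):
                    d += V[j, c] * B[r, c]
                W[mm, r] = d
                wn += d * d
            if np.sqrt(wn) <= _PAR_TOL * norms[j]:
                d = 0.0
                for c in range(4):
                    d += V[j, c] * vhat[c]
                if d > 0.0:
                    p += 1
                else:
                    q += 1
            else:
                mm += 1
        cand = _cellmin3(W, mm) + min(p, q)
        if cand < best:
            best = cand
    return count0 + best


@njit(cache=True)
def _grid_depth_2d(nodes, pts, inside, eps):
    N = nodes.shape[0]
    out = np.zeros(N, np.int64)
    for t in range(N):
        if inside[t]:
            out[t] = _depth2_point(nodes[t], pts, eps)
    return out


@njit(cache=True)
def _grid_depth_3d(nodes, pts, inside, eps):
    N = nodes.shape[0]
    out = np.zeros(N, np.int64)
    for t in range(N):
        if inside[t]:
            out[t] = _depth3_point(nodes[t], pts, eps)
    return out


@njit(cache=True)
def _grid_depth_4d(nodes, pts, inside, eps):
    N = nodes.shape[0]
    out = np.zeros(N, np.int64)
    for t in range(N):
        if inside[t]:
            out[t] = _depth4_point(nodes[t], pts, eps)
    return out


# ---------------------------------------------------------------------------
# brute-force oracle route
# ---------------------------------------------------------------------------

@njit(cache=True)
def _exact2_vectors(W, m):
    """Brute-force min over directions of #{u . W_j >= 0} for nonzero 2D W.

    Enumerates the critical normal angles gamma_j +/- pi/2 induced by each
    vector and evaluates the closed count at every critical angle and at the
    midpoints of consecutive criticals (one per cell of the arrangement).
    Points within the relative boundary tolerance of the halfplane margin
    count as contained (closed-halfspace convention).
    """
    if m == 0:
        return 0
    norms = np.empty(m)
    for j in range(m):
        norms[j] = np.sqrt(W[j, 0] ** 2 + W[j, 1] ** 2)
    crit = np.empty(2 * m)
    for j in range(m):
        g = np.arctan2(W[j, 1], W[j, 0])
        crit[2 * j] = g - np.pi / 2.0
        crit[2 * j + 1] = g + np.pi / 2.0
    for j in range(2 * m):
        # wrap into [-pi, pi)
        a = crit[j]
        while a < -np.pi:
            a += 2.0 * np.pi
        while a >= np.pi:
            a -= 2.0 * np.pi
        crit[j] = a
    crit = np.sort(crit)
    best = m
    for s in range(4 * m):
        if s < 2 * m:
            phi = crit[s]
        elif s < 4 * m - 1:
            phi = 0.5 * (crit[s - 2 * m] + crit[s - 2 * m + 1])
        else:
            phi = 0.5 * (crit[2 * m - 1] + crit[0] + 2.0 * np.pi)
        ux = np.cos(phi)
        uy = np.sin(phi)
        cnt = 0
        for j in range(m):
            if ux * W[j, 0] + uy * W[j, 1] >= -_PAR_TOL * norms[j]:
                cnt += 1
        if cnt < best:
            best = cnt
    return best


@njit(cache=True)
def _exact2_point(theta, pts, eps):
    n = pts.shape[0]
    W = np.empty((n, 2))
    m = 0
    count0 = 0
    for j in range(n):
        vx = pts[j, 0] - theta[0]
        vy = pts[j, 1] - theta[1]
        if np.sqrt(vx * vx + vy * vy) <= eps:
            count0 += 1
        else:
            W[m, 0] = vx
            W[m, 1] = vy
            m += 1
    return count0 + _exact2_vectors(W, m)


@njit(cache=True)
def _exact3_rank3(V, m):
    """Brute-force depth for nonzero 3D vectors of full rank.

    Candidate boundary normals are cross products of vector pairs (the
    vertices of the great-circle arrangement); the four cells incident to each
    vertex are reached by small perturbations along the two defining vectors.
    """
    eps = 1e-6
    best = m
    norms = np.empty(m)
    for k in range(m):
        norms[k] = np.sqrt(V[k, 0] ** 2 + V[k, 1] ** 2 + V[k, 2] ** 2)
    for i in range(m):
        ni = np.sqrt(V[i, 0] ** 2 + V[i, 1] ** 2 + V[i, 2] ** 2)
        for j in range(i + 1, m):
            nj = np.sqrt(V[j, 0] ** 2 + V[j, 1] ** 2 + V[j, 2] ** 2)
            cx = V[i, 1] * V[j, 2] - V[i, 2] * V[j, 1]
            cy = V[i, 2] * V[j, 0] - V[i, 0] * V[j, 2]
            cz = V[i, 0] * V[j, 1] - V[i, 1] * V[j, 0]
            cn = np.sqrt(cx * cx + cy * cy + cz * cz)
            if cn <= 1e-12 * ni * nj:
                continue
            cx /= cn
            cy /= cn
            cz /= cn
            for sgn in (-1.0, 1.0):
                bx = sgn * cx
                by = sgn * cy
                bz = sgn * cz
                for s1 in (-1.0, 0.0, 1.0):
                    for s2 in (-1.0, 0.0, 1.0):
                        ux = bx + eps * (s1 * V[i, 0] / ni + s2 * V[j, 0] / nj)
                        uy = by + eps * (s1 * V[i, 1] / ni + s2 * V[j, 1] / nj)
                        uz = bz + eps * (s1 * V[i, 2] / ni + s2 * V[j, 2] / nj)
                        un = np.sqrt(ux * ux + uy * uy + uz * uz)
                        cnt = 0
                        for k in range(m):
                            d = ux * V[k, 0] + uy * V[k, 1] + uz * V[k, 2]
                            if d >= -_PAR_TOL * un * norms[k]:
                                cnt += 1
                        if cnt < best:
                            best = cnt
    return best
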