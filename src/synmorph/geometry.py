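"""Low-level geometric primitives shared across the pipeline.

Everything here works in nanometres on plain numpy arrays.  The routines are
deliberately dependency-light: point-to-triangle and point-to-segment
distances are vectorised numpy implementations (no spatial index needed at
the problem sizes of a single bouton), and cross-section segment chaining
turns the raw segment soup returned by ``trimesh.intersections.mesh_plane``
into ordered contours.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "point_triangle_distance",
    "point_segment_distance_2d",
    "point_segment_distance_3d",
    "polyline_length",
    "chain_segments",
    "resample_closed",
    "triangle_areas",
]

_EPS = 1e-12


def triangle_areas(tris: np.ndarray) -> np.ndarray:
    """Areas of triangles given as an (m, 3, 3) array."""
    e0 = tris[:, 1] - tris[:, 0]
    e1 = tris[:, 2] - tris[:, 0]
    return 0.5 * np.linalg.norm(np.cross(e0, e1), axis=1)


def point_triangle_distance(
    points: np.ndarray, tris: np.ndarray, chunk: int = 2048
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum Euclidean distance from each point to a set of triangles.

    Parameters
    ----------
    points : (n, 3) array
    tris : (m, 3, 3) array of triangle vertices

    Returns
    -------
    dist : (n,) distances to the nearest triangle
    index : (n,) index of the nearest triangle
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tris = np.asarray(tris, dtype=float)
    n = len(points)
    dist = np.empty(n)
    index = np.empty(n, dtype=np.intp)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = _point_triangle_sqdist(points[lo:hi], tris)
        index[lo:hi] = np.argmin(d2, axis=1)
        dist[lo:hi] = np.sqrt(d2[np.arange(hi - lo), index[lo:hi]])
    return dist, index


def _point_triangle_sqdist(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Squared distances, (n, m), via the Eberly region decomposition."""
    base = tris[:, 0]                      # (m, 3)
    e0 = tris[:, 1] - base                 # (m, 3)
    e1 = tris[:, 2] - base
    a = np.einsum("ij,ij->j", e0.T, e0.T)  # (m,)
    b = np.einsum("ij,ij->j", e0.T, e1.T)
    c = np.einsum("ij,ij->j", e1.T, e1.T)
    diff = base[None, :, :] - points[:, None, :]           # (n, m, 3)
    d = np.einsum("nmk,mk->nm", diff, e0)
    e = np.einsum("nmk,mk->nm", diff, e1)

    det = np.maximum(a * c - b * b, _EPS)                  # (m,)
    s = b * d - c * e + (c * e - b * d)  # placeholder shape
    s = b[None, :] * e - c[None, :] * d
    t = b[None, :] * d - a[None, :] * e

    s_out = np.empty_like(s)
    t_out = np.empty_like(t)

    inside = (s + t) <= det[None, :]
    r0 = inside & (s >= 0) & (t >= 0)
    # region 0: interior
    s_out[r0] = (s / det[None, :])[r0]
    t_out[r0] = (t / det[None, :])[r0]

    # region 3/5-ish: edges through the base vertex
    r3 = inside & (s < 0) & (t >= 0)      # edge e1 (s = 0)
    tt = np.clip(-e / np.maximum(c[None, :], _EPS), 0.0, 1.0)
    s_out[r3] = 0.0
    t_out[r3] = tt[r3]

    r5 = inside & (s >= 0) & (t < 0)      # edge e0 (t = 0)
    ss = np.clip(-d / np.maximum(a[None, :], _EPS), 0.0, 1.0)
    s_out[r5] = ss[r5]
    t_out[r5] = 0.0

    r4 = inside & (s < 0) & (t < 0)       # corner at base
    use_e0 = d < 0
    s_out[r4 & use_e0] = ss[r4 & use_e0]
    t_out[r4 & use_e0] = 0.0
    s_out[r4 & ~use_e0] = 0.0
    t_out[r4 & ~use_e0] = tt[r4 & ~use_e0]

    outside = ~inside
    denom = np.maximum(a - 2 * b + c, _EPS)[None, :]
    # region 1: hypotenuse edge
    r1 = outside & (s >= 0) & (t >= 0)
    s_hyp = np.clip((c[None, :] + e - b[None, :] - d) / denom, 0.0, 1.0)
    s_out[r1] = s_hyp[r1]
    t_out[r1] = 1.0 - s_hyp[r1]

    # region 2: top corner
    r2 = outside & (s < 0)
    tmp0 = b[None, :] + d
    tmp1 = c[None, :] + e
    hyp2 = tmp1 > tmp0
    m = r2 & hyp2
    s_out[m] = s_hyp[m]
    t_out[m] = 1.0 - s_hyp[m]
    m = r2 & ~hyp2
    s_out[m] = 0.0
    t_out[m] = np.clip(-e / np.maximum(c[None, :], _EPS), 0.0, 1.0)[m]

    # region 6: right corner
    r6 = outside & (s >= 0) & (t < 0)
    tmp0 = b[None, :] + e
    tmp1 = a[None, :] + d
    hyp6 = tmp1 > tmp0
    t_hyp = np.clip((a[None, :] + d - b[None, :] - e) / denom, 0.0, 1.0)
    m = r6 & hyp6
    t_out[m] = t_hyp[m]
    s_out[m] = 1.0 - t_hyp[m]
    m = r6 & ~hyp6
    t_out[m] = 0.0
    s_out[m] = np.clip(-d / np.maximum(a[None, :], _EPS), 0.0, 1.0)[m]

    closest = (
        base[None, :, :]
        + s_out[:, :, None] * e0[None, :, :]
        + t_out[:, :, None] * e1[None, :, :]
    )
    delta = closest - points[:, None, :]
    return np.einsum("nmk,nmk->nm", delta, delta)


def _point_segment_sqdist(points: np.ndarray, segs: np.ndarray) -> np.ndarray:
    """Squared distances (n, m) from points (n, d) to segments (m, 2, d)."""
    p0 = segs[:, 0]
    dvec = segs[:, 1] - segs[:, 0]                     # (m, d)
    len2 = np.maximum(np.einsum("md,md->m", dvec, dvec), _EPS)
    w = points[:, None, :] - p0[None, :, :]            # (n, m, d)
    t = np.clip(np.einsum("nmd,md->nm", w, dvec) / len2[None, :], 0.0, 1.0)
    proj = p0[None, :, :] + t[:, :, None] * dvec[None, :, :]
    delta = points[:, None, :] - proj
    return np.einsum("nmd,nmd->nm", delta, delta)


def point_segment_distance_2d(points: np.ndarray, segs: np.ndarray) -> np.ndarray:
    """Minimum distance from each 2D point to a set of 2D segments."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    segs = np.asarray(segs, dtype=float)
    if len(segs) == 0:
        return np.full(len(points), np.inf)
    return np.sqrt(_point_segment_sqdist(points, segs).min(axis=1))


def point_segment_distance_3d(points: np.ndarray, segs: np.ndarray) -> np.ndarray:
    """Minimum distance from each 3D point to a set of 3D segments."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    segs = np.asarray(segs, dtype=float)
    if len(segs) == 0:
        return np.full(len(points), np.inf)
    return np.sqrt(_point_segment_sqdist(points, segs).min(axis=1))


def polyline_segments(vertices: np.ndarray) -> np.ndarray:
    """(k-1, 2, d) consecutive-vertex segments of a polyline."""
    v = np.asarray(vertices, dtype=float)
    return np.stack([v[:-1], v[1:]], axis=1)


def polyline_length(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    if len(v) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())


def chain_segments(
    segments: np.ndarray, tol: float = 1e-4
) -> list[tuple[np.ndarray, bool]]:
    """Chain an unordered segment soup into polylines / polygons.

    Endpoints closer than ``tol`` are considered coincident.  Returns a list
    of ``(vertices, closed)`` where closed chains do *not* repeat the first
    vertex.
    """
    segments = np.asarray(segments, dtype=float)
    if len(segments) == 0:
        return []
    pts = segments.reshape(-1, segments.shape[-1])
    key = np.round(pts / tol).astype(np.int64)
    _, inverse = np.unique(key, axis=0, return_inverse=True)
    n_seg = len(segments)
    edges = inverse.reshape(n_seg, 2)

    adjacency: dict[int, list[tuple[int, int]]] = {}
    for i, (u, v) in enumerate(edges):
        if u == v:
            continue  # degenerate sliver
        adjacency.setdefault(u, []).append((i, v))
        adjacency.setdefault(v, []).append((i, u))

    coord: dict[int, np.ndarray] = {}
    for node, p in zip(inverse, pts):
        coord.setdefault(int(node), p)

    used = np.zeros(n_seg, dtype=bool)
    chains: list[tuple[np.ndarray, bool]] = []

    def walk(start: int) -> list[int]:
        path = [start]
        current = start
        while True:
            nxt = None
            for seg_i, other in adjacency.get(current, []):
                if not used[seg_i]:
                    used[seg_i] = True
                    nxt = other
                    break
            if nxt is None:
                return path
            path.append(nxt)
            current = nxt

    # open chains first, starting from odd-degree endpoints
    degree = {node: sum(1 for s, _ in adj if not used[s]) for node, adj in adjacency.items()}
    for node in sorted(adjacency, key=lambda k: (degree.get(k, 0) % 2 == 0, k)):
        remaining = [s for s, _ in adjacency[node] if not used[s]]
        if not remaining:
            continue
        if sum(1 for s, _ in adjacency[node] if not used[s]) % 2 == 1:
            path = walk(node)
            verts = np.array([coord[p] for p in path])
            chains.append((verts, False))
    # closed loops from whatever is left
    for i in range(n_seg):
        if used[i]:
            continue
        start = int(edges[i][0])
        path = walk(start)
        closed = len(path) > 2 and path[-1] == path[0]
        verts = np.array([coord[p] for p in (path[:-1] if closed else path)])
        chains.append((verts, closed))
    return [c for c in chains if len(c[0]) >= 2]


def resample_closed(vertices: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed contour (no repeated endpoint) to n arc-length-uniform
    vertices, preserving orientation and the location of vertex 0."""
    v = np.asarray(vertices, dtype=float)
    loop = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return np.repeat(v[:1], n, axis=0)
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, v.shape[1]))
    for k in range(v.shape[1]):
        out[:, k] = np.interp(targets, s, loop[:, k])
    return out
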