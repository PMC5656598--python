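"""Low-level triangle-mesh utilities.

Meshes are plain :class:`trimesh.Trimesh` objects created with
``process=False`` so that vertex order and count are preserved exactly;
several operations (TPS warping, ground-truth comparison) rely on stable
vertex indexing.
"""
from __future__ import annotations

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .errors import MeshInputError

__all__ = [
    "make_mesh",
    "validate_mesh",
    "closest_point_on_surface",
    "closest_point_triangles",
    "chain_segments",
    "geodesic_distances",
    "boundary_loops",
]


def make_mesh(vertices: np.ndarray, faces: np.ndarray, **kwargs) -> trimesh.Trimesh:
    """Build a :class:`trimesh.Trimesh` without any vertex merging/reordering."""
    return trimesh.Trimesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
        **kwargs,
    )


def validate_mesh(mesh: trimesh.Trimesh) -> None:
    """Check structural invariants: indices in range, no degenerate face labels."""
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise MeshInputError("mesh is empty")
    f = np.asarray(mesh.faces)
    if f.min() < 0 or f.max() >= len(mesh.vertices):
        raise MeshInputError("face index out of range")
    if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
        raise MeshInputError("face with repeated vertex index")
    if not np.all(np.isfinite(mesh.vertices)):
        raise MeshInputError("non-finite vertex coordinate")


def closest_point_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle ``tri[i]`` to each ``points[i]``.

    Vectorised version of the standard region-based algorithm
    (Ericson, *Real-Time Collision Detection*). ``tri`` has shape (n, 3, 3).
    """
    p = np.asarray(points, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = np.where(d1 - d3 != 0, d1 - d3, 1.0)
    v = (d1 / denom)[:, None]
    out[m] = (a + v * ab)[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = np.where(d2 - d6 != 0, d2 - d6, 1.0)
    w = (d2 / denom)[:, None]
    out[m] = (a + w * ac)[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    denom = np.where(denom != 0, denom, 1.0)
    w = ((d4 - d3) / denom)[:, None]
    out[m] = (b + w * (c - b))[m]
    done |= m
    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom != 0, denom, 1.0)
    v = (vb / denom)[:, None]
    w = (vc / denom)[:, None]
    out[m] = (a + v * ab + w * ac)[m]
    return out


def closest_point_on_surface(
    mesh: trimesh.Trimesh, points: np.ndarray, k: int = 32
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest surface point, distance and triangle index for each query point.

    Candidate faces come from the ``k`` nearest face centroids plus all faces
    incident to the nearest mesh vertex; exact point-triangle minimisation is
    then run over the candidates. Exact whenever the true nearest face is in
    the candidate set, which holds for k well below face count on meshes with
    reasonably uniform triangle size.
    """
    validate_mesh(mesh)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centroids = mesh.triangles_center
    k = min(k, len(centroids))
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = np.atleast_2d(cand.reshape(len(points), -1))

    # add faces around the nearest vertex to be safe near slivers
    _, nv = cKDTree(mesh.vertices).query(points)
    vf = mesh.vertex_faces  # (n_v, max_deg), padded with -1
    extra = vf[nv]
    cand = np.hstack([cand, extra])

    tris = np.asarray(mesh.triangles)
    best_d2 = np.full(len(points), np.inf)
    best_pt = np.zeros_like(points)
    best_tid = np.zeros(len(points), dtype=np.int64)
    for j in range(cand.shape[1]):
        tid = cand[:, j]
        valid = tid >= 0
        if not np.any(valid):
            continue
        tid_v = np.where(valid, tid, 0)
        cp = closest_point_triangles(points, tris[tid_v])
        d2 = np.einsum("ij,ij->i", points - cp, points - cp)
        better = valid & (d2 < best_d2)
        best_d2[better] = d2[better]
        best_pt[better] = cp[better]
        best_tid[better] = tid_v[better]
    return best_pt, np.sqrt(best_d2), best_tid


def chain_segments(segments: np.ndarray, tol: float | None = None) -> list[np.ndarray]:
    """Chain an unordered set of line segments into polylines.

    ``segments`` has shape (n, 2, d). Endpoints closer than ``tol`` are
    considered identical. Closed loops are returned with the first point
    repeated at the end.
    """
    segments = np.asarray(segments, dtype=float)
    if len(segments) == 0:
        return []
    if tol is None:
        lengths = np.linalg.norm(segments[:, 1] - segments[:, 0], axis=1)
        tol = max(1e-12, 1e-6 * float(lengths.max()))

    pts = segments.reshape(-1, segments.shape[-1])
    tree = cKDTree(pts)
    # union endpoints into nodes
    groups = tree.query_ball_point(pts, r=tol)
    node_of = np.full(len(pts), -1, dtype=np.int64)
    nodes: list[np.ndarray] = []
    for i in range(len(pts)):
        if node_of[i] >= 0:
            continue
        nid = len(nodes)
        stack = [i]
        members = []
        while stack:
            j = stack.pop()
            if node_of[j] >= 0:
                continue
            node_of[j] = nid
            members.append(j)
            stack.extend(g for g in groups[j] if node_of[g] < 0)
        nodes.append(pts[members].mean(axis=0))

    n_seg = len(segments)
    ends = node_of.reshape(n_seg, 2)
    adj: dict[int, list[tuple[int, int]]] = {}
    for s, (u, v) in enumerate(ends):
        adj.setdefault(u, []).append((s, v))
        adj.setdefault(v, []).append((s, u))

    used = np.zeros(n_seg, dtype=bool)
    polylines = []
    # open chains first (start at odd-degree nodes), then loops
    starts = [n for n, e in adj.items() if len(e) % 2 == 1]
    order = starts + list(adj.keys())
    for start in order:
        for s0, v0 in adj[start]:
            if used[s0]:
                continue
            chain = [start, v0]
            used[s0] = True
            cur = v0
            while True:
                nxt = next(((s, v) for s, v in adj.get(cur, []) if not used[s]), None)
                if nxt is None:
                    break
                used[nxt[0]] = True
                chain.append(nxt[1])
                cur = nxt[1]
            polylines.append(np.array([nodes[n] for n in chain]))
    return polylines


def _vertex_graph(mesh: trimesh.Trimesh):
    e = mesh.edges_unique
    w = mesh.edges_unique_length
    n = len(mesh.vertices)
    g = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                  np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    )
    return g.tocsr()


def geodesic_distances(
    mesh: trimesh.Trimesh, source_point: np.ndarray, n_sweeps: int = 50, tol: float = 1e-9
) -> np.ndarray:
    """Approximate geodesic distance from a surface point to every vertex.

    Dijkstra on the edge graph gives an upper bound which is then tightened by
    iterative planar-unfolding updates over the triangles (a sweep version of
    the fast-marching local solver). Accuracy is typically well below one
    edge length.
    """
    validate_mesh(mesh)
    src = np.asarray(source_point, dtype=float)
    cp, _, tid = closest_point_on_surface(mesh, src[None])
    cp, tid = cp[0], tid[0]
    n = len(mesh.vertices)
    d0 = np.full(n, np.inf)
    for v in mesh.faces[tid]:
        d0[v] = np.linalg.norm(mesh.vertices[v] - cp)
    seeds = mesh.faces[tid]
    g = _vertex_graph(mesh)
    dist_all = dijkstra(g, indices=seeds)
    dist = np.min(dist_all + d0[seeds][:, None], axis=0)
    dist[seeds] = d0[seeds]

    faces = mesh.faces
    tri = np.asarray(mesh.triangles)
    # precompute edge lengths for each rotation (A,B -> update C)
    rots = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
    geom = []
    for ia, ib, ic in rots:
        A, B, C = tri[:, ia], tri[:, ib], tri[:, ic]
        c_len = np.linalg.norm(B - A, axis=1)
        b_len = np.linalg.norm(C - A, axis=1)
        a_len = np.linalg.norm(C - B, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cx = (c_len**2 + b_len**2 - a_len**2) / (2 * np.where(c_len > 0, c_len, 1.0))
        cy = np.sqrt(np.maximum(b_len**2 - cx**2, 0.0))
        geom.append((faces[:, ia], faces[:, ib], faces[:, ic], c_len, cx, cy, b_len, a_len))

    for _ in range(n_sweeps):
        changed = 0.0
        for va, vb, vc, c_len, cx, cy, b_len, a_len in geom:
            da, db = dist[va], dist[vb]
            with np.errstate(invalid="ignore", divide="ignore"):
                sx = (c_len**2 + da**2 - db**2) / (2 * np.where(c_len > 0, c_len, 1.0))
                sy2 = da**2 - sx**2
            ok = np.isfinite(da) & np.isfinite(db) & (sy2 >= 0) & (cy > 0) & (c_len > 0)
            sy = -np.sqrt(np.maximum(sy2, 0.0))
            # crossing of segment (source virtual point)-(C) with the edge AB
            denom = cy - sy
            t = np.where(denom > 0, -sy / np.where(denom > 0, denom, 1.0), np.nan)
            x0 = sx + (cx - sx) * t
            inside = ok & (t > 0) & (t < 1) & (x0 >= 0) & (x0 <= c_len)
            cand = np.where(
                inside,
                np.sqrt((cx - sx) ** 2 + (cy - sy) ** 2),
                np.minimum(da + b_len, db + a_len),
            )
            cand = np.where(np.isfinite(cand), cand, np.inf)
            upd = np.minimum(dist[vc], cand)
            delta = dist[vc] - upd
            if np.any(delta > 0):
                np.minimum.at(dist, vc, cand)
                changed = max(changed, float(np.nanmax(delta)))
        if changed < tol:
            break
    return dist


def boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Ordered vertex-index loops of all boundary edges (edges used once)."""
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    bedges = unique[counts == 1]
    if len(bedges) == 0:
        return []
    adj: dict[int, list[int]] = {}
    for u, v in bedges:
        adj.setdefault(int(u), []).append(int(v))
        adj.setdefault(int(v), []).append(int(u))
    visited = set()
    loops = []
    for start in adj:
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = start
        prev = -1
        while True:
            nxts = [w for w in adj[cur] if w != prev and w not in visited]
            if not nxts:
                # may close the loop
                break
            prev, cur = cur, nxts[0]
            visited.add(cur)
            loop.append(cur)
        loops.append(np.array(loop, dtype=np.int64))
    return loops
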