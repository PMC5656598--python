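"""Missing-surface completion with a Bezier curve network.

A lost region of the cranial wall is spanned by polynomial (Bezier) curves
whose anchors all lie on preserved bone, with the first and last anchor on
opposite sides of the hole. Points are sampled at equal arc-length
intervals along every curve, the pooled cloud (plus the hole rim) is
projected to a reference domain, Delaunay-triangulated, and the
connectivity lifted back to 3D to form the replacement patch, which is then
stitched into the mesh along the rim.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import Delaunay, cKDTree
from scipy.special import comb
from shapely.geometry import Point, Polygon

from ._mesh import boundary_loops, closest_point_on_surface, make_mesh, validate_mesh
from .errors import (
    DegenerateInputError,
    MeshInputError,
    ProjectionError,
    RankDeficientError,
    SpanningError,
)
from .geometry import Plane, best_fit_plane

__all__ = [
    "BezierCurve",
    "CurveNetwork",
    "SurfacePatch",
    "fit_bezier_curve",
    "bezier_through_points",
    "sample_curve_evenly",
    "build_curve_network",
    "delaunay_surface",
    "complete_surface",
]


@dataclass(frozen=True)
class BezierCurve:
    """A polynomial curve in Bernstein form, degree = #control points - 1.

    The curve interpolates its first and last control points exactly and
    lies in the convex hull of all control points.
    """

    control_points: np.ndarray

    def __post_init__(self):
        cp = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        if len(cp) < 1:
            raise DegenerateInputError("need at least 1 control point")
        if not np.all(np.isfinite(cp)):
            raise DegenerateInputError("non-finite control point")
        object.__setattr__(self, "control_points", cp)

    @property
    def degree(self) -> int:
        return len(self.control_points) - 1

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate at parameter values t in [0, 1] (Bernstein form)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        n = self.degree
        k = np.arange(n + 1)
        basis = comb(n, k)[None, :] * t[:, None] ** k * (1.0 - t[:, None]) ** (n - k)
        out = basis @ self.control_points
        exact0 = t == 0.0
        exact1 = t == 1.0
        out[exact0] = self.control_points[0]
        out[exact1] = self.control_points[-1]
        return out

    def derivative(self) -> "BezierCurve":
        cp = self.control_points
        return BezierCurve(self.degree * (cp[1:] - cp[:-1]))

    def speed(self, t: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.derivative().evaluate(t), axis=-1)


def fit_bezier_curve(control_points: np.ndarray) -> BezierCurve:
    """Build a Bezier curve from its control polygon (>= 3 points)."""
    cp = np.atleast_2d(np.asarray(control_points, dtype=float))
    if len(cp) < 3:
        raise DegenerateInputError("need at least 3 control points")
    if np.max(np.linalg.norm(cp - cp[0], axis=1)) < 1e-300:
        raise DegenerateInputError("all control points coincide")
    return BezierCurve(cp)


def bezier_through_points(points: np.ndarray, max_degree: int = 6) -> BezierCurve:
    """Bezier curve passing through the given points (anchors).

    Anchors are assigned chord-length parameters; the curve of degree
    min(n-1, max_degree) with fixed endpoints is solved for the interior
    control points. With n-1 <= max_degree the fit interpolates every anchor
    exactly; more anchors are fitted in the least-squares sense (high-degree
    Bernstein bases oscillate, hence the cap).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise DegenerateInputError("need at least 3 anchor points")
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = chord.sum()
    if total <= 0:
        raise DegenerateInputError("anchors are coincident")
    u = np.concatenate([[0.0], np.cumsum(chord)]) / total
    deg = min(len(pts) - 1, max_degree)
    basis = BezierCurve(np.eye(deg + 1)).evaluate(u)  # (m, deg+1) Bernstein basis
    b = pts - np.outer(basis[:, 0], pts[0]) - np.outer(basis[:, deg], pts[-1])
    interior, *_ = np.linalg.lstsq(basis[:, 1:deg], b, rcond=None)
    cp = np.vstack([pts[0], interior, pts[-1]])
    return BezierCurve(cp)


class _ArcLength:
    """Composite Gauss-Legendre arc-length table for a Bezier curve."""

    def __init__(self, curve: BezierCurve, n_intervals: int = 256, order: int = 8):
        self.curve = curve
        nodes, weights = np.polynomial.legendre.leggauss(order)
        edges = np.linspace(0.0, 1.0, n_intervals + 1)
        h = edges[1] - edges[0]
        mid = 0.5 * (edges[:-1] + edges[1:])
        t = (mid[:, None] + 0.5 * h * nodes[None, :]).ravel()
        sp = curve.speed(t).reshape(n_intervals, order)
        self.interval_lengths = 0.5 * h * sp @ weights
        self.cum = np.concatenate([[0.0], np.cumsum(self.interval_lengths)])
        self.edges = edges
        self._nodes, self._weights = nodes, weights

    @property
    def total(self) -> float:
        return float(self.cum[-1])

    def _partial(self, t0: float, t1: float) -> float:
        if t1 <= t0:
            return 0.0
        mid, half = 0.5 * (t0 + t1), 0.5 * (t1 - t0)
        t = mid + half * self._nodes
        return float(half * (self.curve.speed(t) @ self._weights))

    def t_at(self, s: float) -> float:
        s = min(max(s, 0.0), self.total)
        i = int(np.searchsorted(self.cum, s, side="right") - 1)
        i = min(i, len(self.interval_lengths) - 1)
        t0, t1 = self.edges[i], self.edges[i + 1]
        rem = s - self.cum[i]
        t = t0 + (t1 - t0) * (rem / max(self.interval_lengths[i], 1e-300))
        for _ in range(20):
            g = self._partial(t0, t) - rem
            sp = float(self.curve.speed(np.array([t]))[0])
            if sp <= 0:
                break
            step = g / sp
            t -= step
            t = min(max(t, t0), t1)
            if abs(step) < 1e-14:
                break
        return t


def sample_curve_evenly(curve: BezierCurve, n: int) -> np.ndarray:
    """n points at equal arc-length intervals along the curve, endpoints included."""
    if n < 2:
        raise DegenerateInputError("need at least 2 sample points")
    arc = _ArcLength(curve)
    if arc.total <= 1e-300:
        raise DegenerateInputError("degenerate zero-length curve")
    targets = np.linspace(0.0, arc.total, n)
    ts = np.array([arc.t_at(s) for s in targets])
    ts[0], ts[-1] = 0.0, 1.0
    return curve.evaluate(ts)


@dataclass(frozen=True)
class CurveNetwork:
    """Fitted curves plus the pooled, provenance-annotated sample cloud."""

    curves: tuple[BezierCurve, ...]
    anchor_sets: tuple[np.ndarray, ...]
    samples: tuple[np.ndarray, ...]

    @property
    def points(self) -> np.ndarray:
        return np.vstack(self.samples)

    @property
    def provenance(self) -> np.ndarray:
        return np.concatenate(
            [np.full(len(s), i, dtype=np.int64) for i, s in enumerate(self.samples)]
        )


def build_curve_network(
    mesh_with_hole: trimesh.Trimesh,
    anchor_sets,
    n_per_curve: int = 15,
    surface_tol: float | None = None,
    require_spanning: bool = True,
    max_degree: int = 6,
) -> CurveNetwork:
    """Fit one evenly sampled Bezier curve per anchor set.

    Every anchor must lie on the preserved surface (within ``surface_tol``,
    default 0.5% of the mesh extent); each fitted curve must cross the
    missing region, detected as at least one interior sample farther than
    the tolerance from the preserved surface.
    """
    validate_mesh(mesh_with_hole)
    if surface_tol is None:
        surface_tol = 0.005 * float(np.linalg.norm(mesh_with_hole.extents))
    curves = []
    samples = []
    kept_anchors = []
    for i, anchors in enumerate(anchor_sets):
        anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
        _, dist, _ = closest_point_on_surface(mesh_with_hole, anchors)
        if float(dist.max()) > surface_tol:
            raise ProjectionError(
                f"anchor set {i}: anchor {float(dist.max()):.3g} mm off the preserved "
                f"surface (tolerance {surface_tol:.3g} mm)"
            )
        curve = bezier_through_points(anchors, max_degree=max_degree)
        pts = sample_curve_evenly(curve, n_per_curve)
        if require_spanning:
            _, d_int, _ = closest_point_on_surface(mesh_with_hole, pts[1:-1])
            if float(d_int.max()) <= surface_tol:
                raise SpanningError(f"anchor set {i} does not cross the missing region")
        curves.append(curve)
        samples.append(pts)
        kept_anchors.append(anchors)
    return CurveNetwork(
        curves=tuple(curves), anchor_sets=tuple(kept_anchors), samples=tuple(samples)
    )


@dataclass(frozen=True)
class SurfacePatch:
    """Triangulated filling of a hole, with its projected-domain coordinates."""

    mesh: trimesh.Trimesh
    uv: np.ndarray
    boundary_vertices: np.ndarray


def _project(points: np.ndarray, projection, plane: Plane | None) -> np.ndarray:
    if projection == "plane":
        pl = plane if plane is not None else best_fit_plane(points)
        return pl.to_2d(points)
    if projection == "cylinder":
        c = points.mean(axis=0)
        cov = (points - c).T @ (points - c)
        _, V = np.linalg.eigh(cov)
        axis = V[:, -1]
        rel = points - c
        z = rel @ axis
        radial = rel - np.outer(z, axis)
        rmean = np.linalg.norm(radial, axis=1).mean()
        ref = V[:, 1]
        ref2 = np.cross(axis, ref)
        theta = np.arctan2(radial @ ref2, radial @ ref)
        return np.column_stack([theta * rmean, z])
    raise DegenerateInputError(f"unknown projection {projection!r}")


def delaunay_surface(
    points: np.ndarray, projection="plane", plane: Plane | None = None
) -> SurfacePatch:
    """Delaunay-triangulate a point cloud in a projected 2D domain.

    Points are projected (best-fit plane by default, cylindrical
    parameterization for strongly curved holes), triangulated in 2D, and the
    connectivity lifted back to the 3D points. The empty-circumcircle
    property holds in the projected domain.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise RankDeficientError("need at least 3 points")
    uv = _project(pts, projection, plane)
    spread = uv - uv.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-9 * max(1.0, np.abs(spread).max())) < 2:
        raise RankDeficientError("projected points are collinear")
    tri = Delaunay(uv)
    faces = tri.simplices.copy()
    # consistent orientation: counter-clockwise in the projected domain
    e1 = uv[faces[:, 1]] - uv[faces[:, 0]]
    e2 = uv[faces[:, 2]] - uv[faces[:, 0]]
    flip = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0] < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    # drop degenerate slivers
    area2 = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    scale2 = float(np.ptp(uv, axis=0).max()) ** 2
    faces = faces[area2 > 1e-12 * max(scale2, 1e-300)]
    hull = np.unique(tri.convex_hull)
    return SurfacePatch(mesh=make_mesh(pts, faces), uv=uv, boundary_vertices=hull)


def _hole_rim(mesh: trimesh.Trimesh, near: np.ndarray) -> np.ndarray:
    loops = boundary_loops(mesh)
    if not loops:
        raise MeshInputError("mesh has no boundary: no hole to complete")
    target = near.mean(axis=0)
    dists = [np.linalg.norm(mesh.vertices[l].mean(axis=0) - target) for l in loops]
    return loops[int(np.argmin(dists))]


def complete_surface(
    mesh_with_hole: trimesh.Trimesh,
    anchor_sets,
    n_per_curve: int = 15,
    rim_vertices: np.ndarray | None = None,
    surface_tol: float | None = None,
    projection="plane",
) -> trimesh.Trimesh:
    """Fill a hole with a Bezier-network patch and stitch it to the rim.

    The patch is triangulated from the curve samples plus the rim vertices
    themselves, so its boundary coincides with the rim exactly. Original
    vertices are never moved; reconstructed faces are flagged in
    ``metadata['reconstructed_faces']``.
    """
    validate_mesh(mesh_with_hole)
    anchor_sets = list(anchor_sets)
    if len(anchor_sets) == 0:
        out = make_mesh(mesh_with_hole.vertices.copy(), mesh_with_hole.faces.copy())
        out.metadata["reconstructed_faces"] = np.zeros(len(out.faces), dtype=bool)
        return out
    network = build_curve_network(
        mesh_with_hole, anchor_sets, n_per_curve=n_per_curve, surface_tol=surface_tol
    )
    cloud = network.points
    if rim_vertices is None:
        rim_vertices = _hole_rim(mesh_with_hole, cloud)
    rim_vertices = np.asarray(rim_vertices, dtype=np.int64)
    rim_xyz = mesh_with_hole.vertices[rim_vertices]

    all_pts = np.vstack([rim_xyz, cloud])
    plane = best_fit_plane(all_pts)
    uv_all = _project(all_pts, projection, plane)
    rim_uv = uv_all[: len(rim_xyz)]
    cloud_uv = uv_all[len(rim_xyz):]
    rim_edge = np.linalg.norm(np.diff(np.vstack([rim_uv, rim_uv[:1]]), axis=0), axis=1)
    med_edge = float(np.median(rim_edge))
    poly = Polygon(rim_uv)
    if not poly.is_valid:
        poly = poly.buffer(0.0)

    # keep cloud points strictly interior (margin avoids rim-hugging slivers)
    inner = poly.buffer(-0.35 * med_edge)
    keep = np.array([inner.contains(Point(p)) for p in cloud_uv], dtype=bool)
    cloud, cloud_uv = cloud[keep], cloud_uv[keep]
    # decimate near-duplicates where curves cross
    if len(cloud) > 0:
        tree = cKDTree(cloud_uv)
        pairs = tree.query_pairs(r=0.35 * med_edge)
        drop = set()
        for a, b in sorted(pairs):
            if a not in drop:
                drop.add(b)
        keep2 = np.array([i not in drop for i in range(len(cloud))], dtype=bool)
        cloud, cloud_uv = cloud[keep2], cloud_uv[keep2]

    pts3 = np.vstack([rim_xyz, cloud])
    uv = np.vstack([rim_uv, cloud_uv])
    tri = Delaunay(uv)
    faces = tri.simplices.copy()
    cent = uv[faces].mean(axis=1)
    inside = np.array([poly.buffer(1e-9 * med_edge).contains(Point(p)) for p in cent])
    faces = faces[inside]
    e1 = uv[faces[:, 1]] - uv[faces[:, 0]]
    e2 = uv[faces[:, 2]] - uv[faces[:, 0]]
    cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    flip = cross < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    faces = faces[np.abs(cross) > 1e-12 * med_edge**2]

    # orient the patch like the surrounding surface
    rim_faces = np.isin(mesh_with_hole.faces, rim_vertices).any(axis=1)
    ref_normal = np.asarray(mesh_with_hole.face_normals)[rim_faces].mean(axis=0)
    v1 = pts3[faces[:, 1]] - pts3[faces[:, 0]]
    v2 = pts3[faces[:, 2]] - pts3[faces[:, 0]]
    patch_normal = np.cross(v1, v2).sum(axis=0)
    if patch_normal @ ref_normal < 0:
        faces = faces[:, [0, 2, 1]]

    # merge: rim points map onto existing vertex ids, cloud points are appended
    n_orig = len(mesh_with_hole.vertices)
    index_map = np.concatenate(
        [rim_vertices, n_orig + np.arange(len(cloud), dtype=np.int64)]
    )
    patch_faces = index_map[faces]
    out_vertices = np.vstack([mesh_with_hole.vertices, cloud])
    out_faces = np.vstack([mesh_with_hole.faces, patch_faces])
    out = make_mesh(out_vertices, out_faces)
    rec = np.zeros(len(out_faces), dtype=bool)
    rec[len(mesh_with_hole.faces):] = True
    out.metadata["reconstructed_faces"] = rec
    return out
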