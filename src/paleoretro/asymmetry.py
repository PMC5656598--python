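"""Bilateral asymmetry quantification on coronal sections.

The protocol: cut the cranial vault with a stack of evenly spaced coronal
planes (default: seven planes 10 mm apart spanning 60 mm), extract the left
and right external profiles of each section, resample each profile to a
fixed number of semilandmarks (default 30), mirror the right profile,
superimpose it on the left by Procrustes, and fit a thin-plate spline
between the two. The per-section bending energy is the diagnostic: an
affine (uniform) deformation of a bilaterally symmetric vault produces
left/right profile pairs that differ by an affine map only, hence bending
energy indistinguishable from zero on every section, while a localised
(non-affine) deformation raises the energy on the sections that cross it.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from ._mesh import chain_segments, validate_mesh
from .errors import DegenerateInputError, LabellingError, OneSidedError
from .geometry import (
    LandmarkConfiguration,
    Plane,
    fit_tps,
    procrustes_align,
)

__all__ = [
    "SectionPlan",
    "SectionContour",
    "SectionProfile",
    "AsymmetryReport",
    "section_mesh",
    "extract_side_profiles",
    "resample_profile",
    "bilateral_bending_energy",
    "run_asymmetry_analysis",
    "default_section_plan",
]


@dataclass(frozen=True)
class SectionPlan:
    """A stack of parallel section planes.

    Planes are placed at coordinates ``start + i * spacing`` measured along
    ``normal`` (coronal planes by convention: normal along the
    antero-posterior axis), for i = 0 .. floor(span/spacing).
    """

    normal: np.ndarray = (0.0, 1.0, 0.0)
    start: float = 0.0
    spacing: float = 10.0
    span: float = 60.0

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm <= 0:
            raise DegenerateInputError("plan normal must be non-zero")
        object.__setattr__(self, "normal", n / norm)
        if self.spacing <= 0:
            raise DegenerateInputError("spacing must be positive")
        if self.span < 0:
            raise DegenerateInputError("span must be non-negative")

    @property
    def n_planes(self) -> int:
        # tiny epsilon so that exact multiples (60/10) count the end plane
        return int(np.floor(self.span / self.spacing + 1e-9)) + 1

    @property
    def offsets(self) -> np.ndarray:
        return self.start + self.spacing * np.arange(self.n_planes)

    def planes(self) -> list[Plane]:
        return [Plane(origin=o * self.normal, normal=self.normal) for o in self.offsets]


@dataclass(frozen=True)
class SectionContour:
    """Mesh-plane intersection: polylines in 3D plus in-plane 2D coordinates."""

    section_index: int
    plane: Plane
    polylines_3d: tuple[np.ndarray, ...]
    polylines_2d: tuple[np.ndarray, ...]

    @property
    def is_empty(self) -> bool:
        return len(self.polylines_3d) == 0


@dataclass(frozen=True)
class SectionProfile:
    """One side's external profile of a section, as an open 2D polyline.

    Ordered from the ventral-most to the dorsal-most endpoint (ascending
    second in-plane coordinate). ``gaps`` records index positions after
    which the underlying contour was interrupted (missing surface); when the
    profile was closed over those gaps by interpolation,
    ``closed_over_gaps`` is set.
    """

    section_index: int
    side: str
    points: np.ndarray
    gaps: tuple[int, ...] = ()
    closed_over_gaps: bool = False

    def __post_init__(self):
        object.__setattr__(self, "points", np.atleast_2d(np.asarray(self.points, float)))

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def section_mesh(mesh: trimesh.Trimesh, plan: SectionPlan) -> list[SectionContour]:
    """Intersect the mesh with every plane of the plan.

    Returns one :class:`SectionContour` per plane that actually intersects
    the mesh; a plan with no intersecting plane produces an empty list and a
    warning, not an error.
    """
    validate_mesh(mesh)
    contours: list[SectionContour] = []
    for i, plane in enumerate(plan.planes()):
        segments = trimesh.intersections.mesh_plane(
            mesh, plane_normal=plane.normal, plane_origin=plane.origin
        )
        if len(segments) == 0:
            continue
        polys3d = chain_segments(np.asarray(segments))
        polys2d = tuple(plane.to_2d(p) for p in polys3d)
        contours.append(
            SectionContour(
                section_index=i,
                plane=plane,
                polylines_3d=tuple(polys3d),
                polylines_2d=polys2d,
            )
        )
    if not contours:
        warnings.warn("no section plane intersects the mesh", stacklevel=2)
    return contours


def _split_polyline_by_plane(
    poly3d: np.ndarray, plane: Plane
) -> list[tuple[np.ndarray, float]]:
    """Split a polyline at its crossings of ``plane``.

    Returns (piece, side) tuples where side is the sign of the piece's
    signed distance to the plane. Crossing points are inserted by linear
    interpolation so pieces start/end on the plane.
    """
    s = plane.signed_distance(poly3d)
    pieces: list[tuple[np.ndarray, float]] = []
    cur = [poly3d[0]]
    cur_sign = np.sign(s[0])
    for i in range(1, len(poly3d)):
        if np.sign(s[i]) == cur_sign or s[i] == 0.0:
            cur.append(poly3d[i])
            continue
        # crossing between i-1 and i
        t = s[i - 1] / (s[i - 1] - s[i])
        x = poly3d[i - 1] + t * (poly3d[i] - poly3d[i - 1])
        cur.append(x)
        if cur_sign != 0:
            pieces.append((np.array(cur), float(cur_sign)))
        cur = [x, poly3d[i]]
        cur_sign = np.sign(s[i])
    if len(cur) > 1:
        pieces.append((np.array(cur), float(cur_sign if cur_sign != 0 else 1.0)))
    return pieces


def _bezier_bridge(p0, t0, p1, t1, n: int) -> np.ndarray:
    """Cubic bridge between two polyline ends with clamped end tangents.

    Control offsets of one third of the chord reproduce a straight segment
    when the tangents align with the chord and approximate a circular arc to
    well under 1% for gaps up to ~40 degrees.
    """
    chord = np.linalg.norm(p1 - p0)
    c0 = p0 + t0 * (chord / 3.0)
    c1 = p1 - t1 * (chord / 3.0)
    t = np.linspace(0.0, 1.0, n)[1:-1, None]
    return (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * c0
        + 3 * (1 - t) * t**2 * c1
        + t**3 * p1
    )


def _chain_side_pieces(
    pieces: list[np.ndarray], interpolate_gaps: bool
) -> tuple[np.ndarray, tuple[int, ...], bool]:
    """Greedily chain a side's pieces end-to-end, optionally bridging gaps."""
    pieces = sorted(pieces, key=lambda p: -np.linalg.norm(np.diff(p, axis=0), axis=1).sum())
    if not interpolate_gaps or len(pieces) == 1:
        main = pieces[0]
        return main, (), False

    chain = pieces[0]
    remaining = pieces[1:]
    gaps: list[int] = []
    while remaining:
        ends = np.array([chain[0], chain[-1]])
        best = None
        for idx, p in enumerate(remaining):
            for ei, e in enumerate(ends):
                for pi, q in enumerate((p[0], p[-1])):
                    d = np.linalg.norm(e - q)
                    if best is None or d < best[0]:
                        best = (d, idx, ei, pi)
        _, idx, ei, pi = best
        piece = remaining.pop(idx)
        if pi == 1:
            piece = piece[::-1]
        if ei == 0:
            chain = chain[::-1]
        # bridge from chain[-1] to piece[0]
        t_end = chain[-1] - chain[-2]
        t_end = t_end / max(np.linalg.norm(t_end), 1e-300)
        t_start = piece[1] - piece[0]
        t_start = t_start / max(np.linalg.norm(t_start), 1e-300)
        seg = np.linalg.norm(np.diff(chain, axis=0), axis=1).mean()
        gap_len = np.linalg.norm(piece[0] - chain[-1])
        n_fill = max(2, int(np.ceil(gap_len / max(seg, 1e-300))) + 1)
        bridge = _bezier_bridge(chain[-1], t_end, piece[0], t_start, n_fill + 2)
        gaps.append(len(chain) - 1)
        chain = np.vstack([chain, bridge, piece])
    return chain, tuple(gaps), True


def extract_side_profiles(
    contour: SectionContour,
    midsagittal: Plane,
    interpolate_gaps: bool = True,
) -> tuple[SectionProfile, SectionProfile]:
    """Split a section contour at the midsagittal plane into side profiles.

    "Left" is the negative side of the midsagittal normal (with the default
    deterministic normal orientation of :func:`best_fit_plane` the normal
    points toward +x, making the anatomical left the x<0 half-space). Within
    each side, pieces are chained end-to-end; gaps from missing surface are
    bridged by a minimal-curvature cubic when ``interpolate_gaps`` is set,
    otherwise the largest-arc-length piece is returned with gap annotations.
    The profile is ordered ventral-most to dorsal-most (ascending second
    in-plane coordinate).
    """
    if contour.is_empty:
        raise DegenerateInputError("empty contour")
    left_pieces: list[np.ndarray] = []
    right_pieces: list[np.ndarray] = []
    for poly in contour.polylines_3d:
        for piece, sign in _split_polyline_by_plane(poly, midsagittal):
            (left_pieces if sign < 0 else right_pieces).append(piece)
    if not left_pieces or not right_pieces:
        raise OneSidedError("contour lies entirely on one side of the midsagittal plane")

    profiles = []
    for side, pieces in (("left", left_pieces), ("right", right_pieces)):
        chain3d, gaps, closed = _chain_side_pieces(pieces, interpolate_gaps)
        pts2d = contour.plane.to_2d(chain3d)
        if pts2d[0, 1] > pts2d[-1, 1]:
            pts2d = pts2d[::-1]
            gaps = tuple(len(pts2d) - 2 - g for g in gaps)
        profiles.append(
            SectionProfile(
                section_index=contour.section_index,
                side=side,
                points=pts2d,
                gaps=gaps,
                closed_over_gaps=closed,
            )
        )
    return profiles[0], profiles[1]


def resample_profile(profile, k: int) -> LandmarkConfiguration:
    """Resample a profile to ``k`` semilandmarks equally spaced by arc length.

    Accepts a :class:`SectionProfile` or a raw (n, 2) polyline. Endpoints are
    included; consecutive arc-length gaps along the polyline are equal to
    machine precision.
    """
    pts = profile.points if isinstance(profile, SectionProfile) else np.atleast_2d(profile)
    if k < 2:
        raise DegenerateInputError("k must be at least 2")
    if len(pts) < 2:
        raise DegenerateInputError("profile needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise DegenerateInputError("zero-length profile")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, k)
    out = np.column_stack([np.interp(targets, cum, pts[:, j]) for j in range(pts.shape[1])])
    out[0] = pts[0]
    out[-1] = pts[-1]
    labels = tuple(f"s{i:02d}" for i in range(k))
    return LandmarkConfiguration(points=out, labels=labels)


def _slide_on_curve(
    reference: LandmarkConfiguration,
    curve: np.ndarray,
    max_iter: int = 40,
) -> LandmarkConfiguration:
    """Slide semilandmarks along a 2D curve to minimise TPS bending energy.

    The sliding positions are parameterised by arc length along ``curve`` (a
    dense polyline), initialised at equal arc-length fractions, and driven
    by damped Newton steps on the bending-energy quadratic form toward
    ``reference``; the line search enforces that positions stay strictly
    ordered along the curve. Endpoints are anatomically anchored and do not
    slide. This removes the spurious tangential mismatch that independent
    per-side arc-length resampling introduces under anisotropic (but
    affine) deformation, while displacement perpendicular to the profile —
    genuine local bending — cannot be slid away.
    """
    from .retrodeform import bending_energy_matrix

    n = len(reference)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]

    def at(s):
        s = np.clip(s, 0.0, total)
        return np.column_stack(
            [np.interp(s, cum, curve[:, 0]), np.interp(s, cum, curve[:, 1])]
        )

    def tangent_at(s):
        eps = total * 1e-5
        d = at(s + eps) - at(s - eps)
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        return d / np.where(norm > 0, norm, 1.0)

    B = bending_energy_matrix(reference)
    free = np.arange(1, n - 1)
    s = np.linspace(0.0, total, n)

    def energy(svec):
        Y = at(svec)
        return float(np.einsum("id,ij,jd->", Y, B, Y))

    e = energy(s)
    for _ in range(max_iter):
        Y = at(s)
        t = tangent_at(s)
        BY = B @ Y
        grad = 2.0 * np.einsum("ij,ij->i", t[free], BY[free])
        H = 2.0 * B[np.ix_(free, free)] * (t[free] @ t[free].T)
        ridge = 1e-12 * max(float(np.abs(H).max()), 1e-300)
        try:
            ds = np.linalg.solve(H + ridge * np.eye(len(free)), -grad)
        except np.linalg.LinAlgError:
            ds, *_ = np.linalg.lstsq(H, -grad, rcond=1e-10)
        step = 1.0
        improved = False
        for _bt in range(25):
            s_try = s.copy()
            s_try[free] = s[free] + step * ds
            if np.all(np.diff(s_try) > 0):
                e_try = energy(s_try)
                if e_try < e:
                    improved = True
                    break
            step *= 0.5
        if not improved:
            break
        s, e = s_try, e_try
        if np.max(np.abs(step * ds)) < 1e-12 * total:
            break
    return reference.with_points(at(s))


def bilateral_bending_energy(
    left: LandmarkConfiguration,
    right: LandmarkConfiguration,
    bmap=None,
    right_curve: np.ndarray | None = None,
) -> tuple[float, float]:
    """Bending energy between a left profile and the mirrored right profile.

    The right configuration is mirrored in-plane, superimposed on the left by
    Procrustes (with scaling, reflection disallowed beyond the explicit
    mirroring), and a TPS is fitted from the left onto the superimposed
    right. Both configurations are first scaled to unit centroid size so
    energies are comparable across sections. Correspondence is by point
    order; ``bmap`` is accepted for interface symmetry but ordering is
    authoritative for resampled profiles.

    When ``right_curve`` is given (a dense 2D polyline of the full right
    profile, un-mirrored, in the same in-plane coordinates as ``right``),
    the right semilandmarks are treated as sliding semilandmarks: after the
    superimposition they slide along the curve to minimise the bending
    energy, making the two sets geometrically homologous before the energy
    is reported.
    """
    if len(left) != len(right):
        raise LabellingError("left and right must have the same number of points")
    if left.dim != 2 or right.dim != 2:
        raise DegenerateInputError("profiles must be 2D in-plane configurations")
    mirrored = right.points.copy()
    mirrored[:, 0] = -mirrored[:, 0]
    mirrored_cfg = LandmarkConfiguration(points=mirrored, labels=left.labels)
    left_u = left.scaled_to_unit_centroid_size()
    transform, aligned, residual = procrustes_align(
        mirrored_cfg, left_u, allow_reflection=False, with_scaling=True
    )
    if right_curve is not None:
        curve = np.atleast_2d(np.asarray(right_curve, dtype=float)).copy()
        curve[:, 0] = -curve[:, 0]
        aligned = _slide_on_curve(left_u, transform.apply(curve))
    spline = fit_tps(left_u, aligned)
    return spline.bending_energy, residual


@dataclass
class AsymmetryReport:
    """Per-section bending-energy table plus the affine-consistency verdict."""

    table: pd.DataFrame
    be_threshold: float
    affine_consistent: bool = field(init=False)

    def __post_init__(self):
        required = {"section_index", "be", "residual", "n_semilandmarks"}
        if not required.issubset(self.table.columns):
            raise DegenerateInputError(f"report table must have columns {sorted(required)}")
        if (self.table["be"] < 0).any():
            raise DegenerateInputError("bending energy must be non-negative")
        self.affine_consistent = bool((self.table["be"] <= self.be_threshold).all())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "n_sections": int(len(self.table)),
            "max_be": float(self.table["be"].max()),
            "mean_be": float(self.table["be"].mean()),
            "be_threshold": float(self.be_threshold),
            "affine_consistent": self.affine_consistent,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def plot_transformation_grid(spline, path, n_grid: int = 18, margin: float = 0.15):
    """Save a TPS deformation-grid figure (warped Cartesian grid + landmarks).

    The classic way to visualise a 2D thin-plate spline: a regular grid over
    the source domain is pushed through the warp; affine maps tilt the grid
    uniformly while non-affine maps bend it locally. The bending energy is
    annotated on the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = spline.source.points
    lo, hi = X.min(axis=0), X.max(axis=0)
    pad = margin * (hi - lo)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], n_grid)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], n_grid)
    fig, ax = plt.subplots(figsize=(5, 5))
    dense = 150
    for x in gx:
        line = np.column_stack([np.full(dense, x), np.linspace(gy[0], gy[-1], dense)])
        w = spline.transform(line)
        ax.plot(w[:, 0], w[:, 1], lw=0.5, color="0.6")
    for y in gy:
        line = np.column_stack([np.linspace(gx[0], gx[-1], dense), np.full(dense, y)])
        w = spline.transform(line)
        ax.plot(w[:, 0], w[:, 1], lw=0.5, color="0.6")
    ax.plot(spline.target.points[:, 0], spline.target.points[:, 1], "o",
            ms=3, color="crimson", label="target")
    warped = spline.transform(X)
    ax.plot(warped[:, 0], warped[:, 1], "+", ms=5, color="navy", label="warped source")
    ax.set_aspect("equal")
    ax.set_title(f"BE = {spline.bending_energy:.3g}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def default_section_plan(
    mesh: trimesh.Trimesh,
    midsagittal: Plane,
    normal=(0.0, 1.0, 0.0),
    spacing: float = 10.0,
    span: float = 60.0,
) -> SectionPlan:
    """Anchor the section stack at the coronal level of maximum cranial width.

    The plane stack is centred on the coordinate (along ``normal``) of the
    vertex farthest from the midsagittal plane — the level approaching the
    maximum width of the cranium — and extends half the span either way.
    """
    validate_mesh(mesh)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    w = np.abs(midsagittal.signed_distance(mesh.vertices))
    anchor = float(mesh.vertices[int(np.argmax(w))] @ n)
    return SectionPlan(normal=n, start=anchor - span / 2.0, spacing=spacing, span=span)


def run_asymmetry_analysis(
    mesh: trimesh.Trimesh,
    plan: SectionPlan | None = None,
    midsagittal: Plane | None = None,
    k: int = 30,
    be_threshold: float = 1e-3,
    interpolate_gaps: bool = True,
    slide: bool = True,
) -> AsymmetryReport:
    """Full per-section asymmetry protocol on a mesh.

    Defaults reproduce the standard protocol: seven coronal sections spaced
    10 mm over a 60 mm span centred at maximum cranial width, 30
    semilandmarks per profile (slid along the profile to minimise bending
    energy, so they are geometrically homologous), affine-consistency
    threshold 1e-3 on unit-centroid-size configurations.
    """
    validate_mesh(mesh)
    if midsagittal is None:
        midsagittal = Plane(origin=mesh.vertices.mean(axis=0), normal=(1.0, 0.0, 0.0))
    if plan is None:
        plan = default_section_plan(mesh, midsagittal)
    records = []
    for contour in section_mesh(mesh, plan):
        left, right = extract_side_profiles(contour, midsagittal, interpolate_gaps)
        lk = resample_profile(left, k)
        rk = resample_profile(right, k)
        curve = resample_profile(right, max(2000, 20 * k)).points if slide else None
        be, residual = bilateral_bending_energy(lk, rk, right_curve=curve)
        records.append(
            {
                "section_index": contour.section_index,
                "be": be,
                "residual": residual,
                "n_semilandmarks": k,
            }
        )
    table = pd.DataFrame.from_records(
        records, columns=["section_index", "be", "residual", "n_semilandmarks"]
    )
    return AsymmetryReport(table=table, be_threshold=be_threshold)
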