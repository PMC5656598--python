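"""Landmark and mesh geometry primitives.

This module implements the geometric core used everywhere else:

* :class:`LandmarkConfiguration` — an ordered, labelled set of 2D/3D points
  (millimetres), the unit of all superimposition and warping computations.
* :func:`procrustes_align` — least-squares superimposition by translation,
  rotation and optionally scaling and/or reflection.
* :func:`mirror_configuration` — reflection across a plane combined with the
  left/right relabelling defined by a :class:`BilateralMap`.
* :class:`ThinPlateSpline` / :func:`fit_tps` — the classical thin-plate
  spline interpolant with kernel U(r) = r^2 log r in 2D and U(r) = r in 3D,
  decomposed into an affine part and an affine-orthogonal non-affine part.
* :func:`tps_bending_energy` — the integral of squared second derivatives of
  the fitted warp, evaluated through the standard quadratic form of the
  non-affine weights (8*pi * w'Kw in 2D, -8*pi * w'Kw in 3D). Affine maps
  have exactly zero bending energy; localised (non-affine) deformation has
  strictly positive energy.
* :func:`signed_mesh_distance` — per-vertex distances from a query mesh to a
  reference surface, signed positive where the query lies outside the
  reference along its outward normal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from ._mesh import closest_point_on_surface, validate_mesh
from .errors import (
    DegenerateInputError,
    LabellingError,
    RankDeficientError,
    SingularSystemError,
)

__all__ = [
    "Plane",
    "LandmarkConfiguration",
    "BilateralMap",
    "RigidTransform",
    "ThinPlateSpline",
    "DistanceMap",
    "procrustes_align",
    "mirror_configuration",
    "fit_tps",
    "tps_bending_energy",
    "signed_mesh_distance",
    "best_fit_plane",
    "midsagittal_plane",
]

_PINV_RCOND = 1e-10


@dataclass(frozen=True)
class Plane:
    """A plane (or line, in 2D) given by a point and a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm < 1e-300:
            raise DegenerateInputError("plane normal must be non-zero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "normal", n / norm)

    @property
    def dim(self) -> int:
        return len(self.normal)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return (points - self.origin) @ self.normal

    def reflect(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        d = self.signed_distance(points)
        return points - 2.0 * d[:, None] * self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic in-plane orthonormal basis (u, v); 3D only.

        v is chosen as close to the global +z axis as possible (so that the
        second in-plane coordinate reads as "vertical" for near-horizontal
        normals), u completes the frame.
        """
        n = self.normal
        ref = np.array([0.0, 0.0, 1.0])
        if abs(n @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        u = np.cross(n, ref)
        u /= np.linalg.norm(u)
        v = np.cross(u, n)
        return u, v

    def to_2d(self, points: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        rel = np.atleast_2d(points) - self.origin
        return np.stack([rel @ u, rel @ v], axis=-1)

    def to_3d(self, points2d: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        p = np.atleast_2d(points2d)
        return self.origin + p[:, :1] * u + p[:, 1:2] * v


@dataclass(frozen=True)
class LandmarkConfiguration:
    """Ordered, labelled points in 2 or 3 dimensions (units: mm)."""

    points: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        labels = tuple(str(l) for l in self.labels)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise DegenerateInputError("points must be an (n, 2) or (n, 3) array")
        if not np.all(np.isfinite(pts)):
            raise DegenerateInputError("all coordinates must be finite")
        if len(labels) != len(pts):
            raise LabellingError("labels and points must have the same length")
        if len(set(labels)) != len(labels):
            raise LabellingError("labels must be unique")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def centroid_size(self) -> float:
        return float(np.linalg.norm(self.points - self.centroid))

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError as exc:
            raise LabellingError(f"label {label!r} not in configuration") from exc

    def with_points(self, points: np.ndarray) -> "LandmarkConfiguration":
        return LandmarkConfiguration(points=points, labels=self.labels)

    def subset(self, labels) -> "LandmarkConfiguration":
        idx = [self.index_of(l) for l in labels]
        return LandmarkConfiguration(points=self.points[idx], labels=tuple(labels))

    def scaled_to_unit_centroid_size(self) -> "LandmarkConfiguration":
        cs = self.centroid_size
        if cs <= 0:
            raise DegenerateInputError("zero centroid size")
        return self.with_points((self.points - self.centroid) / cs)


@dataclass(frozen=True)
class BilateralMap:
    """Left/right label pairing plus unpaired midline labels."""

    pairs: tuple[tuple[str, str], ...]
    midline: tuple[str, ...] = ()

    def __post_init__(self):
        pairs = tuple((str(a), str(b)) for a, b in self.pairs)
        midline = tuple(str(m) for m in self.midline)
        seen: set[str] = set()
        for a, b in pairs:
            if a == b:
                raise LabellingError(f"pair ({a!r}, {b!r}) maps a label to itself")
            for l in (a, b):
                if l in seen:
                    raise LabellingError(f"label {l!r} appears more than once")
                seen.add(l)
        for m in midline:
            if m in seen:
                raise LabellingError(f"midline label {m!r} also appears in pairs")
            seen.add(m)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "midline", midline)

    @property
    def left_labels(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.pairs)

    @property
    def right_labels(self) -> tuple[str, ...]:
        return tuple(b for _, b in self.pairs)

    def partner(self, label: str) -> str:
        for a, b in self.pairs:
            if label == a:
                return b
            if label == b:
                return a
        if label in self.midline:
            return label
        raise LabellingError(f"label {label!r} not in bilateral map")

    def permutation(self, labels) -> np.ndarray:
        """Index array p with p[i] = index of the partner of labels[i]."""
        labels = list(labels)
        pos = {l: i for i, l in enumerate(labels)}
        out = np.empty(len(labels), dtype=np.int64)
        for i, l in enumerate(labels):
            p = self.partner(l)
            if p not in pos:
                raise LabellingError(f"partner {p!r} of {l!r} missing from configuration")
            out[i] = pos[p]
        return out


@dataclass(frozen=True)
class RigidTransform:
    """Similarity transform x -> scale * R x + t with orthonormal R.

    ``det R = +1`` for proper rotations; a determinant of -1 is permitted only
    when the transform was fitted with reflection explicitly allowed, and is
    exposed through :attr:`is_reflection`.
    """

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        d = R.shape[0]
        if R.shape != (d, d) or t.shape != (d,):
            raise DegenerateInputError("rotation/translation shape mismatch")
        if np.max(np.abs(R.T @ R - np.eye(d))) > 1e-10:
            raise DegenerateInputError("rotation matrix is not orthonormal")
        if abs(abs(np.linalg.det(R)) - 1.0) > 1e-10:
            raise DegenerateInputError("|det R| must equal 1")
        if self.scale <= 0:
            raise DegenerateInputError("scale must be positive")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def dim(self) -> int:
        return self.rotation.shape[0]

    @property
    def is_reflection(self) -> bool:
        return bool(np.linalg.det(self.rotation) < 0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(
            rotation=Rinv,
            translation=-(Rinv @ self.translation) / self.scale,
            scale=1.0 / self.scale,
        )

    @classmethod
    def identity(cls, dim: int = 3) -> "RigidTransform":
        return cls(rotation=np.eye(dim), translation=np.zeros(dim), scale=1.0)


def procrustes_align(
    source: LandmarkConfiguration,
    target: LandmarkConfiguration,
    allow_reflection: bool = False,
    with_scaling: bool = False,
) -> tuple[RigidTransform, LandmarkConfiguration, float]:
    """Least-squares superimposition of ``source`` onto ``target``.

    Returns the fitted transform, the transformed source configuration, and
    the residual (the square root of the minimised sum of squared distances).
    """
    if source.labels != target.labels:
        raise LabellingError("source and target must share labels in the same order")
    if source.dim != target.dim:
        raise DegenerateInputError("dimension mismatch")
    d = source.dim
    if len(source) < d + 1:
        raise RankDeficientError(f"need at least {d + 1} points in {d}D")
    X = source.points
    Y = target.points
    muX, muY = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - muX, Y - muY
    if np.linalg.matrix_rank(Xc, tol=1e-10 * max(1.0, np.abs(Xc).max())) < 2:
        raise RankDeficientError("source configuration is collinear")
    M = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(M)
    R = Vt.T @ U.T
    if not allow_reflection and np.linalg.det(R) < 0:
        D = np.eye(d)
        D[-1, -1] = -1.0
        R = Vt.T @ D @ U.T
        S = S.copy()
        S[-1] *= -1.0
    if with_scaling:
        denom = float(np.sum(Xc * Xc))
        s = float(S.sum()) / denom
        if s <= 0:
            raise RankDeficientError("non-positive optimal scale")
    else:
        s = 1.0
    t = muY - s * (R @ muX)
    transform = RigidTransform(rotation=R, translation=t, scale=s)
    aligned = source.with_points(transform.apply(X))
    residual = float(np.linalg.norm(aligned.points - Y))
    return transform, aligned, residual


def mirror_configuration(
    config: LandmarkConfiguration, bmap: BilateralMap, plane: Plane
) -> LandmarkConfiguration:
    """Reflect across ``plane`` and swap left/right labels.

    The returned configuration keeps the original label order: the point
    carrying a left label is the reflected position of its right partner (and
    vice versa); midline labels keep their own reflected positions. Applying
    the operation twice returns the input exactly.
    """
    if plane.dim != config.dim:
        raise DegenerateInputError("plane and configuration dimension mismatch")
    reflected = plane.reflect(config.points)
    perm = bmap.permutation(config.labels)
    return config.with_points(reflected[perm])


@dataclass(frozen=True)
class ThinPlateSpline:
    """A fitted TPS interpolant from ``source`` onto ``target``.

    The map is f(x) = A' [1, x] + sum_i w_i U(|x - s_i|) with the classical
    kernels U(r) = r^2 log r (2D) and U(r) = r (3D). The non-affine weights
    satisfy sum w_i = 0 and sum w_i s_i = 0, so the warp is affine far from
    the landmarks.
    """

    source: LandmarkConfiguration
    target: LandmarkConfiguration
    weights: np.ndarray  # (n, d) non-affine weights
    affine: np.ndarray  # (d+1, d); row 0 is the translation

    @property
    def dim(self) -> int:
        return self.source.dim

    def _kernel(self, r: np.ndarray) -> np.ndarray:
        if self.dim == 2:
            with np.errstate(divide="ignore", invalid="ignore"):
                v = r * r * np.log(r)
            return np.where(r > 0, v, 0.0)
        return r

    def transform(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(points[:, None, :] - self.source.points[None, :, :], axis=-1)
        Phi = self._kernel(r)
        P = np.hstack([np.ones((len(points), 1)), points])
        return Phi @ self.weights + P @ self.affine

    @property
    def bending_energy(self) -> float:
        """Integral of squared second derivatives of the warp (see module doc)."""
        r = np.linalg.norm(
            self.source.points[:, None, :] - self.source.points[None, :, :], axis=-1
        )
        K = self._kernel(r)
        quad = float(np.einsum("id,ij,jd->", self.weights, K, self.weights))
        be = 8.0 * np.pi * quad if self.dim == 2 else -8.0 * np.pi * quad
        return max(be, 0.0)


def fit_tps(source: LandmarkConfiguration, target: LandmarkConfiguration) -> ThinPlateSpline:
    """Fit the thin-plate spline interpolating ``source`` onto ``target``."""
    if source.labels != target.labels:
        raise LabellingError("source and target must share labels in the same order")
    if source.dim != target.dim:
        raise DegenerateInputError("dimension mismatch")
    n, d = source.points.shape
    if n < d + 1:
        raise RankDeficientError(f"need at least {d + 1} points")
    X = source.points
    r = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    scale = max(float(r.max()), 1e-300)
    offdiag = r + np.eye(n) * scale
    if float(offdiag.min()) < 1e-12 * scale:
        raise SingularSystemError("coincident source points")
    if d == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            K = np.where(r > 0, r * r * np.log(np.where(r > 0, r, 1.0)), 0.0)
    else:
        K = r
    P = np.hstack([np.ones((n, 1)), X])
    L = np.zeros((n + d + 1, n + d + 1))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + d + 1, d))
    rhs[:n] = target.points
    sol, *_ = np.linalg.lstsq(L, rhs, rcond=_PINV_RCOND)
    return ThinPlateSpline(source=source, target=target, weights=sol[:n], affine=sol[n:])


def tps_bending_energy(spline: ThinPlateSpline) -> float:
    """Bending energy of a fitted spline; zero iff the map is affine."""
    return spline.bending_energy


@dataclass(frozen=True)
class DistanceMap:
    """Per-vertex signed distances (mm) from a query mesh to a reference mesh.

    Sign convention: positive where the query vertex lies outside the
    reference surface along its outward normal.
    """

    values: np.ndarray
    sign_convention: str = "positive_outside_reference"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise DegenerateInputError("distance map contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def signed_mesh_distance(
    query: trimesh.Trimesh, reference: trimesh.Trimesh
) -> DistanceMap:
    """Signed nearest distance from each query vertex to the reference surface."""
    validate_mesh(query)
    validate_mesh(reference)
    closest, dist, tid = closest_point_on_surface(reference, query.vertices)
    normals = np.asarray(reference.face_normals)[tid]
    side = np.einsum("ij,ij->i", query.vertices - closest, normals)
    sign = np.where(side >= 0, 1.0, -1.0)
    return DistanceMap(values=sign * dist)


def best_fit_plane(points: np.ndarray) -> Plane:
    """Least-squares plane through a point cloud (normal = smallest PC).

    The normal sign is made deterministic by forcing its largest-magnitude
    component positive.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise RankDeficientError("need at least 3 points to fit a plane")
    c = pts.mean(axis=0)
    cov = (pts - c).T @ (pts - c)
    w, V = np.linalg.eigh(cov)
    n = V[:, 0]
    i = int(np.argmax(np.abs(n)))
    if n[i] < 0:
        n = -n
    return Plane(origin=c, normal=n)


def midsagittal_plane(config: LandmarkConfiguration, bmap: BilateralMap) -> Plane:
    """Best-fit symmetry plane through pair midpoints and midline landmarks."""
    pts = []
    for a, b in bmap.pairs:
        pts.append(0.5 * (config.points[config.index_of(a)] + config.points[config.index_of(b)]))
    for m in bmap.midline:
        pts.append(config.points[config.index_of(m)])
    return best_fit_plane(np.array(pts))
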