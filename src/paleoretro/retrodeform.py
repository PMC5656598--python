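"""Retrodeformation: symmetrize a bilateral template and warp the mesh.

The symmetrization is the closed-form reflected-relabelling construction:
the configuration is relabelled through the bilateral map, the optimal
*improper* orthogonal alignment of the relabelled copy onto the original is
solved in closed form, and the symmetrized configuration is the pointwise
midpoint of the original and the aligned copy. Because pair-swapping is an
involutive permutation, the cross-covariance between the configuration and
its relabelled copy is symmetric; the optimal improper orthogonal transform
is then the reflection obtained by flipping the sign of its smallest
eigenvalue, which is itself involutive — so the midpoint configuration is
*exactly* symmetric and the operation is idempotent. No scaling is applied:
retrodeformation must not change the absolute size of the specimen.

Semilandmarks are made geometrically homologous before symmetrization by
sliding them within their local tangent planes to minimise the thin-plate
spline bending energy toward a reference configuration, with projection
back onto the mesh surface after each step.

Finally every mesh vertex is warped by the 3D TPS interpolating the
(relaxed) template onto its symmetrized counterpart; vertices far from all
landmarks follow the affine part of the spline.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from ._mesh import closest_point_on_surface, make_mesh, validate_mesh
from .errors import (
    DegenerateInputError,
    LabellingError,
    MeshInputError,
    ProjectionError,
    RankDeficientError,
)
from .geometry import (
    BilateralMap,
    DistanceMap,
    LandmarkConfiguration,
    RigidTransform,
    ThinPlateSpline,
    fit_tps,
    signed_mesh_distance,
)

__all__ = [
    "SemilandmarkPatch",
    "RetrodeformTemplate",
    "RetrodeformResult",
    "symmetrize_landmarks",
    "relax_semilandmarks",
    "retrodeform_mesh",
    "apply_fragment_transforms",
    "bending_energy_matrix",
]

_PINV_RCOND = 1e-10


@dataclass(frozen=True)
class SemilandmarkPatch:
    """A bilateral pair of semilandmark grids (rows x cols of labels)."""

    left_grid: tuple[tuple[str, ...], ...]
    right_grid: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        lg = tuple(tuple(str(l) for l in row) for row in self.left_grid)
        rg = tuple(tuple(str(l) for l in row) for row in self.right_grid)
        if len(lg) == 0 or len(lg[0]) == 0:
            raise DegenerateInputError("patch grid must be non-empty")
        if len(lg) != len(rg) or any(len(a) != len(b) for a, b in zip(lg, rg)):
            raise DegenerateInputError("left and right grids must have identical shape")
        object.__setattr__(self, "left_grid", lg)
        object.__setattr__(self, "right_grid", rg)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.left_grid), len(self.left_grid[0])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l for row in self.left_grid for l in row) + tuple(
            l for row in self.right_grid for l in row
        )

    @property
    def size(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class RetrodeformTemplate:
    """A bilateral landmark/semilandmark template attached to a mesh surface."""

    config: LandmarkConfiguration
    bilateral: BilateralMap
    patches: tuple[SemilandmarkPatch, ...] = ()
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "patches", tuple(self.patches))
        labels = set(self.config.labels)
        paired = set(self.bilateral.left_labels) | set(self.bilateral.right_labels)
        for l in paired | set(self.bilateral.midline):
            if l not in labels:
                raise LabellingError(f"bilateral-map label {l!r} missing from configuration")
        patch_labels = []
        for p in self.patches:
            for l in p.labels:
                if l not in labels:
                    raise LabellingError(f"patch label {l!r} missing from configuration")
                if l not in paired:
                    raise LabellingError(f"patch label {l!r} is not bilaterally paired")
                patch_labels.append(l)
        if len(set(patch_labels)) != len(patch_labels):
            raise LabellingError("a label appears in more than one patch")
        expected = 2 * self.n_fixed_pairs + sum(p.size for p in self.patches) + len(
            self.bilateral.midline
        )
        if expected != len(self.config):
            raise LabellingError(
                f"template bookkeeping mismatch: {expected} != {len(self.config)} points"
            )

    @property
    def semilandmark_labels(self) -> tuple[str, ...]:
        return tuple(l for p in self.patches for l in p.labels)

    @property
    def fixed_labels(self) -> tuple[str, ...]:
        semi = set(self.semilandmark_labels)
        return tuple(l for l in self.config.labels if l not in semi)

    @property
    def n_fixed_pairs(self) -> int:
        semi = set(self.semilandmark_labels)
        return sum(1 for a, b in self.bilateral.pairs if a not in semi and b not in semi)

    def with_points(self, points: np.ndarray, **meta) -> "RetrodeformTemplate":
        return RetrodeformTemplate(
            config=self.config.with_points(points),
            bilateral=self.bilateral,
            patches=self.patches,
            metadata={**self.metadata, **meta},
        )


def _symmetrize_points(points: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Closed-form symmetrization of a point set under an involutive pairing."""
    mu = points.mean(axis=0)
    Xc = points - mu
    C = Xc.T @ Xc[perm]
    C = 0.5 * (C + C.T)  # exactly symmetric analytically; enforce numerically
    w, V = np.linalg.eigh(C)
    signs = np.ones(len(w))
    signs[0] = -1.0  # flip the smallest eigenvalue: optimal improper transform
    Q = V @ np.diag(signs) @ V.T
    aligned = Xc[perm] @ Q.T + mu
    return 0.5 * (points + aligned)


def symmetrize_landmarks(template, bmap: BilateralMap | None = None) -> LandmarkConfiguration:
    """Symmetrize a bilateral configuration (closed form; exact and idempotent).

    Accepts a :class:`RetrodeformTemplate` or a bare
    :class:`LandmarkConfiguration` together with a :class:`BilateralMap`.
    The fitted alignment contains no scaling and no reflection beyond the
    explicit relabelled reflection, so the output preserves absolute size.
    """
    if isinstance(template, RetrodeformTemplate):
        config, bmap = template.config, template.bilateral
    else:
        config = template
        if bmap is None:
            raise LabellingError("a BilateralMap is required with a bare configuration")
    if len(bmap.pairs) < 3:
        raise RankDeficientError("need at least 3 bilateral pairs to symmetrize")
    perm = bmap.permutation(config.labels)
    return config.with_points(_symmetrize_points(config.points, perm))


def bending_energy_matrix(reference: LandmarkConfiguration) -> np.ndarray:
    """The n x n bending-energy quadratic form of a source configuration.

    For a TPS from ``reference`` onto any target Y, the bending energy is
    proportional to sum_d Y[:, d]' B Y[:, d]; B is the upper-left block of
    the pseudo-inverse of the bordered kernel matrix, sign-corrected per
    kernel so that the quadratic form is non-negative (the raw block is
    negative semidefinite for the 3D kernel U(r) = r).
    """
    X = reference.points
    n, d = X.shape
    r = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
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
    B = np.linalg.pinv(L, rcond=_PINV_RCOND)[:n, :n]
    B = 0.5 * (B + B.T)
    return B if d == 2 else -B


def _tangent_basis(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(normals), 1))
    swap = np.abs(normals[:, 2]) > 0.9
    ref[swap] = [1.0, 0.0, 0.0]
    t1 = np.cross(normals, ref)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(normals, t1)
    return t1, t2


def relax_semilandmarks(
    template: RetrodeformTemplate,
    mesh: trimesh.Trimesh,
    reference: LandmarkConfiguration,
    max_iter: int = 10,
    rel_tol: float = 1e-6,
    surface_tol: float | None = None,
) -> RetrodeformTemplate:
    """Slide patch semilandmarks on the surface to minimise bending energy.

    Each semilandmark moves within the tangent plane of the mesh at its
    current position; the unconstrained tangential offsets minimising the
    TPS bending energy toward ``reference`` are solved in closed form, the
    slid points are projected back to the nearest surface point, and the
    step is accepted only if the energy decreased (with step halving
    otherwise), so the energy is non-increasing across iterations. Fixed
    (non-patch) landmarks never move.

    The iteration schedule (at most ``max_iter`` passes, stop when the
    relative energy change drops below ``rel_tol``) and the convergence log
    are recorded in the returned template's ``metadata['relaxation']``.
    """
    validate_mesh(mesh)
    if template.config.labels != reference.labels:
        raise LabellingError("template and reference must share labels in the same order")
    if surface_tol is None:
        surface_tol = 0.02 * float(np.linalg.norm(mesh.extents))
    slide_idx = np.array(
        [template.config.index_of(l) for l in template.semilandmark_labels], dtype=np.int64
    )
    if len(slide_idx) == 0:
        return template.with_points(template.config.points, relaxation={"iterations": 0})

    Y = template.config.points.copy()
    _, d0, _ = closest_point_on_surface(mesh, Y[slide_idx])
    if float(d0.max()) > surface_tol:
        raise ProjectionError(
            f"semilandmark {float(d0.max()):.3g} mm from surface exceeds tolerance "
            f"{surface_tol:.3g} mm"
        )

    B = bending_energy_matrix(reference)

    def energy(pts: np.ndarray) -> float:
        return float(np.einsum("id,ij,jd->", pts, B, pts))

    log = []
    e_prev = energy(Y)
    for it in range(max_iter):
        closest, _, tid = closest_point_on_surface(mesh, Y[slide_idx])
        normals = np.asarray(mesh.face_normals)[tid]
        t1, t2 = _tangent_basis(normals)
        m = len(slide_idx)
        T = np.zeros((2 * m, 3))
        T[0::2] = t1
        T[1::2] = t2
        rows = np.repeat(slide_idx, 2)
        Bsub = B[np.ix_(slide_idx, slide_idx)]
        # M[(j,a),(k,b)] = B[j,k] * (t_ja . t_kb);  rhs = -t_ja . (B Y)[j]
        dots = T @ T.T
        M = Bsub[np.repeat(np.arange(m), 2)[:, None], np.repeat(np.arange(m), 2)[None, :]]
        M = M * dots
        BY = B @ Y
        rhs = -np.einsum("qd,qd->q", T, BY[rows])
        alpha, *_ = np.linalg.lstsq(M, rhs, rcond=_PINV_RCOND)

        step = 1.0
        accepted = False
        for _attempt in range(5):
            offsets = (alpha[0::2, None] * t1 + alpha[1::2, None] * t2) * step
            Y_try = Y.copy()
            Y_try[slide_idx] = Y[slide_idx] + offsets
            proj, _, _ = closest_point_on_surface(mesh, Y_try[slide_idx])
            Y_try[slide_idx] = proj
            e_try = energy(Y_try)
            if e_try <= e_prev * (1.0 + 1e-12):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        Y = Y_try
        change = abs(e_prev - e_try) / max(e_prev, 1e-300)
        log.append({"iteration": it, "energy": e_try, "rel_change": change})
        e_prev = e_try
        if change < rel_tol:
            break
    return template.with_points(
        Y, relaxation={"iterations": len(log), "final_energy": e_prev, "log": log}
    )


@dataclass(frozen=True)
class RetrodeformResult:
    """Output of :func:`retrodeform_mesh`."""

    symmetrized: LandmarkConfiguration
    warped_mesh: trimesh.Trimesh
    distance_map: DistanceMap
    spline: ThinPlateSpline
    convergence: dict


def retrodeform_mesh(
    mesh: trimesh.Trimesh,
    template: RetrodeformTemplate,
    relax: bool = True,
    **relax_kwargs,
) -> RetrodeformResult:
    """Remove bilateral (taphonomic) asymmetry from a mesh.

    Pipeline: relax semilandmarks toward a provisional symmetrized template,
    symmetrize the relaxed template, and warp every mesh vertex by the 3D
    TPS interpolating the relaxed template onto its symmetrized counterpart.
    The result carries the signed distance map of the warped mesh against
    the input (positive where the restoration moved the surface outward).
    """
    validate_mesh(mesh)
    working = template
    convergence: dict = {"relaxed": False}
    if relax and template.patches:
        provisional = symmetrize_landmarks(template)
        working = relax_semilandmarks(template, mesh, provisional, **relax_kwargs)
        convergence = {"relaxed": True, **working.metadata.get("relaxation", {})}
    symmetrized = symmetrize_landmarks(working)
    spline = fit_tps(working.config, symmetrized)
    warped = make_mesh(spline.transform(mesh.vertices), mesh.faces)
    dmap = signed_mesh_distance(warped, mesh)
    return RetrodeformResult(
        symmetrized=symmetrized,
        warped_mesh=warped,
        distance_map=dmap,
        spline=spline,
        convergence=convergence,
    )


def apply_fragment_transforms(
    fragments: list[trimesh.Trimesh], transforms: list[RigidTransform]
) -> trimesh.Trimesh:
    """Rigidly reposition fragments and concatenate them into one mesh.

    Per-fragment provenance is preserved in ``metadata['fragment_id']`` (one
    integer per face of the composite).
    """
    if len(fragments) != len(transforms):
        raise MeshInputError("fragments and transforms must have equal length")
    if len(fragments) == 0:
        raise MeshInputError("no fragments given")
    verts = []
    faces = []
    frag_id = []
    offset = 0
    for i, (frag, tf) in enumerate(zip(fragments, transforms)):
        validate_mesh(frag)
        v = tf.apply(frag.vertices)
        verts.append(v)
        faces.append(np.asarray(frag.faces) + offset)
        frag_id.append(np.full(len(frag.faces), i, dtype=np.int64))
        offset += len(v)
    out = make_mesh(np.vstack(verts), np.vstack(faces))
    out.metadata["fragment_id"] = np.concatenate(frag_id)
    return out
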