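"""Ground-truthed synthetic fixtures emulating a taphonomically deformed calvarium.

The generator produces a bilaterally symmetric half-ellipsoid shell (a stand-in
for the cranial vault), a bilateral landmark/semilandmark template with the
same structure as a real retrodeformation template (18 fixed bilateral pairs,
4 bilateral semilandmark patches, 8 midline points — 172 points in total), a
parametric taphonomic deformation (lateral shear emulating the sediment pack
pushing the vault from left to right, an occipital tilt, an optional uniform
lateral compression and an optional localised non-affine dent), excision of a
surface region with rim extraction, and fragmentation with known rigid
scatter. Every output is a pure function of its parameters and seed, and the
applied deformation is recorded so recovery can be scored against ground
truth.

Note on recoverability: bilateral retrodeformation can only undo the
*asymmetric* part of a deformation. A lateral shear is exactly mirror-
antisymmetric and is removed completely; a uniform lateral compression is
mirror-symmetric and therefore invisible to any symmetry-based method. The
recovery benchmark consequently drives the shear magnitude, while the
compression factor is a scene-dressing parameter.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from ._mesh import geodesic_distances, make_mesh, validate_mesh
from .errors import DegenerateInputError, MeshInputError, ResolutionError
from .geometry import BilateralMap, LandmarkConfiguration, RigidTransform
from .retrodeform import RetrodeformTemplate, SemilandmarkPatch

__all__ = [
    "CalvariumParams",
    "TaphonomicDeformation",
    "DentSpec",
    "ExcisionRecord",
    "DeformationGroundTruth",
    "generate_calvarium",
    "apply_taphonomic_deformation",
    "excise_region",
    "fragment_and_scatter",
]


@dataclass(frozen=True)
class CalvariumParams:
    """Half-ellipsoid vault parameters (mm).

    ``a``/``b``/``c`` are the lateral / antero-posterior / vertical
    semi-axes; ``resolution`` is the target edge length of the generated
    shell. ``thickness`` is reserved for a future two-sheet shell; the
    generated fixture is the external vault surface, which is the surface
    all the analyses operate on.
    """

    a: float = 70.0
    b: float = 90.0
    c: float = 60.0
    thickness: float = 0.0
    resolution: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise DegenerateInputError("semi-axes must be positive")
        if self.resolution <= 0:
            raise DegenerateInputError("resolution must be positive")
        if self.resolution > min(self.a, self.b, self.c) / 5.0:
            raise ResolutionError(
                "resolution coarser than one fifth of the smallest semi-axis"
            )


def _ellipsoid_point(params: CalvariumParams, theta, phi) -> np.ndarray:
    """Surface point at polar angle theta (from apex) and azimuth phi.

    phi = 0 points to +x (anatomical right), phi = pi/2 to +y (anterior);
    the x -> -x mirror maps phi -> pi - phi, so parameter sets closed under
    that map give exactly mirror-symmetric point sets.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    return np.stack(
        [
            params.a * np.sin(theta) * np.cos(phi),
            params.b * np.sin(theta) * np.sin(phi),
            params.c * np.cos(theta),
        ],
        axis=-1,
    )


def _grid_counts(params: CalvariumParams) -> tuple[int, int]:
    mean_r = (params.a + params.b + params.c) / 3.0
    n_theta = max(6, int(round((np.pi / 2) * mean_r / params.resolution)))
    m_phi = max(8, int(round(2 * np.pi * mean_r / params.resolution)))
    if m_phi % 2 == 1:
        m_phi += 1
    return n_theta, m_phi


def generate_calvarium(
    params: CalvariumParams | None = None,
) -> tuple[trimesh.Trimesh, RetrodeformTemplate]:
    """Symmetric half-ellipsoid shell plus its bilateral template.

    The mesh is a UV-style triangulation of the z >= 0 half ellipsoid whose
    azimuth samples phi = pi(2j+1)/m (m even) are closed under the mirror
    phi -> pi - phi, making the vertex set exactly symmetric about x = 0.
    The template has 18 fixed bilateral landmark pairs, 4 bilateral 4x4
    semilandmark patches and 8 midline points (172 points), all placed by a
    deterministic surface parameterization. Output is a pure function of
    ``params`` (the seed is recorded for provenance).
    """
    if params is None:
        params = CalvariumParams()
    n_theta, m_phi = _grid_counts(params)
    thetas = np.linspace(0.0, np.pi / 2, n_theta + 1)[1:]
    phis = np.pi * (2 * np.arange(m_phi) + 1) / m_phi

    verts = [np.array([[0.0, 0.0, params.c]])]
    for th in thetas:
        verts.append(_ellipsoid_point(params, np.full(m_phi, th), phis))
    vertices = np.vstack(verts)

    faces = []
    # apex fan (ring 0 starts at index 1)
    for j in range(m_phi):
        faces.append([0, 1 + j, 1 + (j + 1) % m_phi])
    for i in range(n_theta - 1):
        r0 = 1 + i * m_phi
        r1 = r0 + m_phi
        for j in range(m_phi):
            j2 = (j + 1) % m_phi
            faces.append([r0 + j, r1 + j, r1 + j2])
            faces.append([r0 + j, r1 + j2, r0 + j2])
    mesh = make_mesh(vertices, np.array(faces, dtype=np.int64))
    # outward orientation: apex fan above built with phi increasing is outward
    # for a convex dome; verify and flip if needed
    centroid = mesh.vertices.mean(axis=0)
    outward = np.einsum(
        "ij,ij->i", mesh.triangles_center - centroid, mesh.face_normals
    ).mean()
    if outward < 0:
        mesh = make_mesh(mesh.vertices, mesh.faces[:, [0, 2, 1]])

    labels: list[str] = []
    points: list[np.ndarray] = []
    pairs: list[tuple[str, str]] = []

    def add_pair(name: str, theta: float, phi_right: float):
        pr = _ellipsoid_point(params, theta, phi_right)
        pl = _ellipsoid_point(params, theta, np.pi - phi_right)
        labels.extend([f"L_{name}", f"R_{name}"])
        points.extend([pl, pr])
        pairs.append((f"L_{name}", f"R_{name}"))

    # 18 fixed bilateral pairs on a 6 x 3 (theta x phi) lattice of the right side
    fixed_thetas = np.deg2rad([15.0, 30.0, 45.0, 60.0, 75.0, 85.0])
    fixed_phis = np.deg2rad([20.0, 45.0, 70.0])
    k = 0
    for th in fixed_thetas:
        for ph in fixed_phis:
            add_pair(f"lm{k:02d}", th, ph)
            k += 1

    # 4 bilateral 4x4 semilandmark patches over the parietal wall
    patch_windows = [
        (np.deg2rad([25.0, 55.0]), np.deg2rad([10.0, 35.0])),
        (np.deg2rad([25.0, 55.0]), np.deg2rad([-35.0, -10.0])),
        (np.deg2rad([60.0, 84.0]), np.deg2rad([12.0, 40.0])),
        (np.deg2rad([60.0, 84.0]), np.deg2rad([-40.0, -12.0])),
    ]
    patches = []
    for p_idx, (th_rng, ph_rng) in enumerate(patch_windows):
        lg, rg = [], []
        for r_i, th in enumerate(np.linspace(*th_rng, 4)):
            lrow, rrow = [], []
            for c_i, ph in enumerate(np.linspace(*ph_rng, 4)):
                name = f"p{p_idx}_r{r_i}c{c_i}"
                add_pair(name, float(th), float(ph))
                lrow.append(f"L_{name}")
                rrow.append(f"R_{name}")
            lg.append(tuple(lrow))
            rg.append(tuple(rrow))
        patches.append(SemilandmarkPatch(left_grid=tuple(lg), right_grid=tuple(rg)))

    # 8 midline points along the sagittal arc (phi = +-90 deg -> x = 0 exactly)
    midline = []
    for i, th in enumerate(np.deg2rad([20.0, 40.0, 60.0, 80.0])):
        for j, ph in enumerate((np.pi / 2, -np.pi / 2)):
            name = f"ML{i}{j}"
            labels.append(name)
            points.append(_ellipsoid_point(params, th, ph))
            midline.append(name)

    config = LandmarkConfiguration(points=np.vstack(points), labels=tuple(labels))
    template = RetrodeformTemplate(
        config=config,
        bilateral=BilateralMap(pairs=tuple(pairs), midline=tuple(midline)),
        patches=tuple(patches),
        metadata={"params": params, "seed": params.seed},
    )
    return mesh, template


@dataclass(frozen=True)
class DentSpec:
    """A localised inward (non-affine) dent: centre, radius and depth (mm)."""

    center: tuple[float, float, float]
    radius: float
    depth: float

    def __post_init__(self):
        if self.radius <= 0:
            raise DegenerateInputError("dent radius must be positive")


@dataclass(frozen=True)
class TaphonomicDeformation:
    """Parametric sediment-compression scenario applied to the whole object.

    The affine part composes, in order: uniform lateral compression (x scale
    ``compression``), lateral shear (x += ``shear`` * z; the flattened left
    wall and correspondingly bent right wall of a vault pushed sideways by
    the sediment pack), and occipital tilt (rotation by ``tilt_deg`` about
    the antero-posterior y axis, which tilts the transverse torus in
    posterior view). With no dent the map is exactly affine, so a bilateral
    bending-energy analysis of the deformed object must report values
    indistinguishable from zero.
    """

    compression: float = 1.0
    shear: float = 0.0
    tilt_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dent: DentSpec | None = None

    @property
    def affine(self) -> np.ndarray:
        C = np.diag([self.compression, 1.0, 1.0])
        S = np.eye(3)
        S[0, 2] = self.shear
        t = np.deg2rad(self.tilt_deg)
        R = np.array(
            [[np.cos(t), 0.0, -np.sin(t)], [0.0, 1.0, 0.0], [np.sin(t), 0.0, np.cos(t)]]
        )
        return R @ S @ C

    def __post_init__(self):
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise DegenerateInputError("singular affine deformation")

    @property
    def is_affine(self) -> bool:
        return self.dent is None

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        return points @ self.affine.T + np.asarray(self.translation, dtype=float)


@dataclass(frozen=True)
class ExcisionRecord:
    """Ground truth of an excised region."""

    removed_mesh: trimesh.Trimesh
    rim_polyline: np.ndarray  # ordered rim coordinates, closed loops concatenated
    rim_vertices: np.ndarray  # indices into the holed mesh
    face_mask: np.ndarray  # True where the original face was removed


@dataclass(frozen=True)
class DeformationGroundTruth:
    """Everything needed to score recovery against the pristine fixture."""

    pristine_mesh: trimesh.Trimesh
    pristine_template: RetrodeformTemplate
    deformation: TaphonomicDeformation
    seed: int = 0
    excision: ExcisionRecord | None = None
    fragment_transforms: tuple[RigidTransform, ...] = ()


def apply_taphonomic_deformation(
    mesh: trimesh.Trimesh,
    template: RetrodeformTemplate,
    deformation: TaphonomicDeformation,
) -> tuple[trimesh.Trimesh, RetrodeformTemplate, DeformationGroundTruth]:
    """Deform mesh and template, recording the ground truth.

    The optional dent displaces vertices inward (along the inward surface
    normal at the dent centre, snapped to the nearest mesh vertex so the
    peak displacement equals ``depth`` exactly) with a smooth
    raised-cosine profile of the given radius; the same displacement field
    is applied to the template points.
    """
    validate_mesh(mesh)
    V = deformation.apply_points(mesh.vertices)
    T = deformation.apply_points(template.config.points)
    if deformation.dent is not None:
        dmesh = make_mesh(V, mesh.faces)
        center = np.asarray(deformation.dent.center, dtype=float)
        ci = int(np.argmin(np.linalg.norm(V - center, axis=1)))
        c = V[ci]
        n_in = -np.asarray(dmesh.vertex_normals)[ci]

        def dent_field(pts: np.ndarray) -> np.ndarray:
            r = np.linalg.norm(pts - c, axis=1) / deformation.dent.radius
            amp = np.where(r < 1.0, 0.5 * (1.0 + np.cos(np.pi * np.minimum(r, 1.0))), 0.0)
            return deformation.dent.depth * amp[:, None] * n_in

        V = V + dent_field(V)
        T = T + dent_field(T)
    gt = DeformationGroundTruth(
        pristine_mesh=make_mesh(mesh.vertices.copy(), mesh.faces.copy()),
        pristine_template=template,
        deformation=deformation,
        seed=int(template.metadata.get("seed", 0)),
    )
    return make_mesh(V, mesh.faces), template.with_points(T), gt


@dataclass(frozen=True)
class GeodesicDisc:
    """Region spec: all surface within a geodesic radius of a centre point."""

    center: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class BoxRegion:
    """Region spec: all faces whose centroid lies inside an axis-aligned box."""

    bounds_min: tuple[float, float, float]
    bounds_max: tuple[float, float, float]


def excise_region(mesh: trimesh.Trimesh, region) -> tuple[trimesh.Trimesh, ExcisionRecord]:
    """Remove the faces inside a region; extract the hole rim.

    Returns the holed mesh (original vertex order preserved; unreferenced
    vertices are kept so indices remain stable) and the ground-truth record
    with the removed submesh and the ordered rim polyline.
    """
    validate_mesh(mesh)
    if isinstance(region, GeodesicDisc):
        if region.radius < 0:
            raise DegenerateInputError("negative radius")
        if region.radius == 0:
            mask = np.zeros(len(mesh.faces), dtype=bool)
        else:
            dist = geodesic_distances(mesh, np.asarray(region.center, dtype=float))
            mask = dist[mesh.faces].mean(axis=1) < region.radius
    elif isinstance(region, BoxRegion):
        lo = np.asarray(region.bounds_min, dtype=float)
        hi = np.asarray(region.bounds_max, dtype=float)
        cent = mesh.triangles_center
        mask = np.all((cent >= lo) & (cent <= hi), axis=1)
    else:
        raise DegenerateInputError(f"unknown region spec {type(region).__name__}")
    if mask.all():
        raise MeshInputError("region covers the whole mesh")

    kept_faces = mesh.faces[~mask]
    holed = make_mesh(mesh.vertices.copy(), kept_faces)
    removed = make_mesh(mesh.vertices.copy(), mesh.faces[mask])

    if not mask.any():
        rim_poly = np.zeros((0, 3))
        rim_idx = np.zeros(0, dtype=np.int64)
    else:
        # rim = edges interior in the original mesh that became boundary
        def _edge_counts(faces):
            e = np.sort(
                np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]),
                axis=1,
            )
            uniq, cnt = np.unique(e, axis=0, return_counts=True)
            return {tuple(row): c for row, c in zip(uniq, cnt)}

        orig_counts = _edge_counts(np.asarray(mesh.faces))
        kept_counts = _edge_counts(np.asarray(kept_faces))
        rim_edges = [
            e for e, c in kept_counts.items() if c == 1 and orig_counts.get(e, 0) == 2
        ]
        # order into loops
        adj: dict[int, list[int]] = {}
        for u, v in rim_edges:
            adj.setdefault(int(u), []).append(int(v))
            adj.setdefault(int(v), []).append(int(u))
        visited: set[int] = set()
        loops = []
        for start in adj:
            if start in visited:
                continue
            loop = [start]
            visited.add(start)
            prev, cur = -1, start
            while True:
                nxt = [w for w in adj[cur] if w != prev and w not in visited]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                visited.add(cur)
                loop.append(cur)
            loops.append(loop)
        loops.sort(key=len, reverse=True)
        rim_idx = np.array([v for loop in loops for v in loop], dtype=np.int64)
        rim_poly = mesh.vertices[rim_idx]

    record = ExcisionRecord(
        removed_mesh=removed,
        rim_polyline=rim_poly,
        rim_vertices=rim_idx,
        face_mask=mask,
    )
    return holed, record


def fragment_and_scatter(
    mesh: trimesh.Trimesh,
    n_fragments: int,
    max_displacement: float = 5.0,
    max_rotation_deg: float = 10.0,
    seed: int = 0,
) -> tuple[list[trimesh.Trimesh], list[RigidTransform]]:
    """Partition the mesh into connected fragments and rigidly scatter them.

    Fragments are grown from random seed faces on the face-adjacency graph
    (every fragment is edge-connected); each is perturbed by a random
    rotation about its centroid (angle <= ``max_rotation_deg``) and a random
    translation (norm <= ``max_displacement``). Applying the inverses of the
    returned transforms restores the original composite exactly.
    """
    validate_mesh(mesh)
    n_faces = len(mesh.faces)
    if n_fragments < 1:
        raise MeshInputError("need at least one fragment")
    if n_fragments > n_faces:
        raise MeshInputError("more fragments than faces")
    rng = np.random.default_rng(seed)

    adjacency = mesh.face_adjacency
    neighbors: list[list[int]] = [[] for _ in range(n_faces)]
    for a, b in adjacency:
        neighbors[a].append(int(b))
        neighbors[b].append(int(a))
    seeds = rng.choice(n_faces, size=n_fragments, replace=False)
    owner = np.full(n_faces, -1, dtype=np.int64)
    from collections import deque

    queue = deque()
    for i, s in enumerate(seeds):
        owner[s] = i
        queue.append(int(s))
    while queue:
        f = queue.popleft()
        for g in neighbors[f]:
            if owner[g] < 0:
                owner[g] = owner[f]
                queue.append(g)
    # isolated components unreached by any seed join the nearest-labelled seed 0
    owner[owner < 0] = 0

    fragments = []
    transforms = []
    for i in range(n_fragments):
        fmask = owner == i
        sub_faces = mesh.faces[fmask]
        used = np.unique(sub_faces)
        remap = np.full(len(mesh.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        frag = make_mesh(mesh.vertices[used], remap[sub_faces])
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(max_rotation_deg) * rng.uniform()
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t_vec = direction * max_displacement * rng.uniform()
        c = frag.vertices.mean(axis=0)
        translation = c - R @ c + t_vec
        tf = RigidTransform(rotation=R, translation=translation)
        fragments.append(make_mesh(tf.apply(frag.vertices), frag.faces))
        transforms.append(tf)
    return fragments, transforms
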