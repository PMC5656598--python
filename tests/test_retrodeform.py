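import numpy as np
import pytest

from paleoretro import (
    BilateralMap,
    LandmarkConfiguration,
    RigidTransform,
    apply_fragment_transforms,
    relax_semilandmarks,
    retrodeform_mesh,
    symmetrize_landmarks,
)
from paleoretro.errors import LabellingError, MeshInputError, RankDeficientError
from paleoretro.pipeline import _rigid_rmsd
from paleoretro.retrodeform import bending_energy_matrix
from paleoretro.synthetic import (
    TaphonomicDeformation,
    apply_taphonomic_deformation,
    fragment_and_scatter,
)


def _rand_rotation(rng):
    R, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(R) < 0:
        R[:, 0] *= -1
    return R


def _symmetry_residual(config, bmap):
    """Residual of mirroring-with-relabelling + rigid alignment onto itself."""
    from paleoretro.geometry import Plane, mirror_configuration, procrustes_align

    plane = Plane(origin=config.centroid, normal=(1.0, 0.0, 0.0))
    mirrored = mirror_configuration(config, bmap, plane)
    _, _, res = procrustes_align(mirrored, config, with_scaling=False)
    return res


class TestSymmetrize:
    def test_symmetric_template_is_fixed_point(self, calvarium):
        _, template = calvarium
        out = symmetrize_landmarks(template)
        assert np.abs(out.points - template.config.points).max() < 1e-10

    def test_output_is_exactly_symmetric_and_idempotent(self, calvarium, rng):
        _, template = calvarium
        sheared = template.config.points @ np.array(
            [[1.0, 0.0, 0.15], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        ).T
        tpl = template.with_points(sheared)
        out = symmetrize_landmarks(tpl)
        assert _symmetry_residual(out, template.bilateral) < 1e-8 * out.centroid_size
        again = symmetrize_landmarks(tpl.with_points(out.points))
        assert np.abs(again.points - out.points).max() < 1e-10

    def test_equivariant_under_rigid_motion(self, calvarium, rng):
        _, template = calvarium
        sheared = template.config.points @ np.array(
            [[1.0, 0.0, 0.1], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        ).T
        tpl = template.with_points(sheared)
        base = symmetrize_landmarks(tpl).points
        R = _rand_rotation(rng)
        t = rng.normal(size=3) * 10
        moved = symmetrize_landmarks(tpl.with_points(sheared @ R.T + t)).points
        assert np.abs(moved - (base @ R.T + t)).max() < 1e-9 * tpl.config.centroid_size

    def test_shear_recovery_close_to_pristine(self, calvarium):
        # symmetric template + known shear: the symmetrized configuration
        # must sit close to the pre-shear template after rigid alignment
        _, template = calvarium
        S = np.array([[1.0, 0.0, 0.12], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        sheared = template.config.points @ S.T
        out = symmetrize_landmarks(template.with_points(sheared))
        labels = template.config.labels
        rmsd = _rigid_rmsd(out.points, template.config.points, labels)
        applied_rms = np.sqrt(((sheared - template.config.points) ** 2).sum(axis=1).mean())
        assert rmsd <= 0.02 * applied_rms

    def test_preserves_size(self, calvarium):
        _, template = calvarium
        S = np.array([[1.0, 0.0, 0.1], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        tpl = template.with_points(template.config.points @ S.T)
        out = symmetrize_landmarks(tpl)
        # no scaling anywhere: centroid size stays between that of the input
        # and its mirrored copy (they are equal), up to the averaging effect
        assert out.centroid_size == pytest.approx(tpl.config.centroid_size, rel=0.02)

    def test_too_few_pairs_raises(self):
        cfg = LandmarkConfiguration(
            np.array([[1.0, 0, 0], [-1.0, 0, 0], [2.0, 1, 0], [-2.0, 1, 0]]),
            ("R_a", "L_a", "R_b", "L_b"),
        )
        bmap = BilateralMap(pairs=(("L_a", "R_a"), ("L_b", "R_b")))
        with pytest.raises(RankDeficientError):
            symmetrize_landmarks(cfg, bmap)


def _flat_patch_template():
    """Bilateral 4x4 patches on the z=0 plane plus fixed corner pairs."""
    from paleoretro.retrodeform import RetrodeformTemplate, SemilandmarkPatch

    pts, labels, pairs = [], [], []
    for r_i, y in enumerate(np.linspace(-6, 6, 4)):
        for c_i, x in enumerate(np.linspace(2, 8, 4)):
            labels += [f"L_p0_r{r_i}c{c_i}", f"R_p0_r{r_i}c{c_i}"]
            pts += [[-x, y, 0.0], [x, y, 0.0]]
            pairs.append((f"L_p0_r{r_i}c{c_i}", f"R_p0_r{r_i}c{c_i}"))
    for i, (x, y) in enumerate([(9.5, -9.0), (9.5, 0.0), (9.5, 9.0)]):
        labels += [f"L_f{i}", f"R_f{i}"]
        pts += [[-x, y, 0.0], [x, y, 0.0]]
        pairs.append((f"L_f{i}", f"R_f{i}"))
    cfg = LandmarkConfiguration(np.array(pts), tuple(labels))
    bmap = BilateralMap(pairs=tuple(pairs))
    patch = SemilandmarkPatch(
        left_grid=tuple(tuple(f"L_p0_r{r}c{c}" for c in range(4)) for r in range(4)),
        right_grid=tuple(tuple(f"R_p0_r{r}c{c}" for c in range(4)) for r in range(4)),
    )
    return RetrodeformTemplate(config=cfg, bilateral=bmap, patches=(patch,))


class TestRelax:
    def test_self_reference_no_movement(self, plane_mesh):
        tpl = _flat_patch_template()
        out = relax_semilandmarks(tpl, plane_mesh, tpl.config)
        assert np.abs(out.config.points - tpl.config.points).max() <= 1e-9

    def test_in_plane_mismatch_fully_relaxed(self, plane_mesh, rng):
        # in-plane sliding is unpenalised: a reference that differs from the
        # template by in-plane displacement of the semilandmarks is reachable
        tpl = _flat_patch_template()
        ref_pts = tpl.config.points.copy()
        semi = [tpl.config.index_of(l) for l in tpl.semilandmark_labels]
        ref_pts[semi, :2] += rng.normal(scale=0.4, size=(len(semi), 2))
        ref = tpl.config.with_points(ref_pts)
        out = relax_semilandmarks(tpl, plane_mesh, ref)
        B = bending_energy_matrix(ref)
        e = float(np.einsum("id,ij,jd->", out.config.points, B, out.config.points))
        assert e <= 1e-8

    def test_fixed_landmarks_never_move(self, plane_mesh, rng):
        tpl = _flat_patch_template()
        ref_pts = tpl.config.points.copy()
        semi = [tpl.config.index_of(l) for l in tpl.semilandmark_labels]
        ref_pts[semi, :2] += rng.normal(scale=0.4, size=(len(semi), 2))
        out = relax_semilandmarks(tpl, plane_mesh, tpl.config.with_points(ref_pts))
        fixed = [tpl.config.index_of(l) for l in tpl.fixed_labels]
        assert np.abs(out.config.points[fixed] - tpl.config.points[fixed]).max() == 0.0

    def test_energy_monotone_per_iteration(self, calvarium):
        mesh, template = calvarium
        provisional = symmetrize_landmarks(template)
        # perturb the template slightly so there is something to relax
        S = np.array([[1.0, 0.0, 0.08], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        tpl = template.with_points(template.config.points @ S.T)
        out = relax_semilandmarks(tpl, mesh, provisional, surface_tol=20.0)
        log = out.metadata["relaxation"]["log"]
        energies = [rec["energy"] for rec in log]
        assert all(b <= a * (1 + 1e-12) for a, b in zip(energies, energies[1:]))


class TestRetrodeformMesh:
    def test_symmetric_input_is_identity(self, calvarium):
        mesh, template = calvarium
        result = retrodeform_mesh(mesh, template, relax=False)
        assert np.abs(result.warped_mesh.vertices - mesh.vertices).max() <= 1e-8
        assert np.abs(result.distance_map.values).max() <= 1e-6

    @pytest.mark.parametrize("shear", [0.05, 0.1, 0.2])
    def test_affine_recovery_removes_90_percent(self, calvarium, shear):
        mesh, template = calvarium
        deformed, dtpl, _ = apply_taphonomic_deformation(
            mesh, template, TaphonomicDeformation(shear=shear, tilt_deg=8.0)
        )
        result = retrodeform_mesh(deformed, dtpl)
        labels = tuple(f"v{i}" for i in range(len(mesh.vertices)))
        pre = _rigid_rmsd(deformed.vertices, mesh.vertices, labels)
        post = _rigid_rmsd(result.warped_mesh.vertices, mesh.vertices, labels)
        assert 1.0 - post / pre >= 0.90

    def test_recovery_error_monotone_in_shear(self, calvarium):
        mesh, template = calvarium
        labels = tuple(f"v{i}" for i in range(len(mesh.vertices)))
        posts = []
        for shear in (0.05, 0.1, 0.2):
            deformed, dtpl, _ = apply_taphonomic_deformation(
                mesh, template, TaphonomicDeformation(shear=shear, tilt_deg=8.0)
            )
            result = retrodeform_mesh(deformed, dtpl, relax=False)
            posts.append(_rigid_rmsd(result.warped_mesh.vertices, mesh.vertices, labels))
        assert posts[0] < posts[1] < posts[2]

    def test_distance_map_shows_opposite_lateral_lobes(self, calvarium):
        mesh, template = calvarium
        deformed, dtpl, _ = apply_taphonomic_deformation(
            mesh, template, TaphonomicDeformation(shear=0.1, tilt_deg=8.0)
        )
        result = retrodeform_mesh(deformed, dtpl, relax=False)
        v = result.warped_mesh.vertices
        d = result.distance_map.values
        upper = v[:, 2] > np.percentile(v[:, 2], 60)
        left = d[upper & (v[:, 0] < -20)].mean()
        right = d[upper & (v[:, 0] > 20)].mean()
        assert left * right < 0  # opposite-signed lateral lobes

    def test_warp_interpolates_template_exactly(self, calvarium):
        mesh, template = calvarium
        deformed, dtpl, _ = apply_taphonomic_deformation(
            mesh, template, TaphonomicDeformation(shear=0.1)
        )
        result = retrodeform_mesh(deformed, dtpl, relax=False)
        warped_lm = result.spline.transform(dtpl.config.points)
        assert np.abs(warped_lm - result.symmetrized.points).max() < 1e-8


class TestFragments:
    def test_identity_transforms_concatenate(self, calvarium):
        mesh, _ = calvarium
        frags, _ = fragment_and_scatter(mesh, 4, max_displacement=0.0,
                                        max_rotation_deg=0.0, seed=1)
        composite = apply_fragment_transforms(
            frags, [RigidTransform.identity() for _ in frags]
        )
        assert len(composite.faces) == len(mesh.faces)
        assert composite.metadata["fragment_id"].max() == 3

    def test_pure_translation_moves_every_vertex(self, calvarium):
        mesh, _ = calvarium
        frags, _ = fragment_and_scatter(mesh, 1, max_displacement=0.0,
                                        max_rotation_deg=0.0, seed=0)
        t = np.array([3.0, -2.0, 1.0])
        moved = apply_fragment_transforms(
            [frags[0]], [RigidTransform(rotation=np.eye(3), translation=t)]
        )
        assert np.allclose(moved.vertices - frags[0].vertices, t, atol=1e-12)

    def test_inverse_transforms_restore_composite(self, calvarium):
        mesh, _ = calvarium
        frags, tfs = fragment_and_scatter(mesh, 6, max_displacement=8.0,
                                          max_rotation_deg=15.0, seed=7)
        restored = apply_fragment_transforms(frags, [t.inverse() for t in tfs])
        from scipy.spatial import cKDTree

        d, _ = cKDTree(mesh.vertices).query(restored.vertices)
        assert d.max() < 1e-9

    def test_fragments_partition_faces(self, calvarium):
        mesh, _ = calvarium
        frags, _ = fragment_and_scatter(mesh, 5, seed=2)
        assert sum(len(f.faces) for f in frags) == len(mesh.faces)
        assert all(len(f.faces) > 0 for f in frags)

    def test_length_mismatch_raises(self, calvarium):
        mesh, _ = calvarium
        frags, tfs = fragment_and_scatter(mesh, 2, seed=0)
        with pytest.raises(MeshInputError):
            apply_fragment_transforms(frags, tfs[:1])


class TestTemplateValidation:
    def test_patch_label_must_be_paired(self):
        from paleoretro.retrodeform import RetrodeformTemplate, SemilandmarkPatch

        cfg = LandmarkConfiguration(
            np.array([[1.0, 0, 0], [-1.0, 0, 0], [2.0, 0, 0], [-2.0, 0, 0],
                      [0.0, 1, 0]]),
            ("R_a", "L_a", "R_b", "L_b", "solo"),
        )
        bmap = BilateralMap(pairs=(("L_a", "R_a"), ("L_b", "R_b")), midline=("solo",))
        patch = SemilandmarkPatch(left_grid=(("solo",),), right_grid=(("L_a",),))
        with pytest.raises(LabellingError):
            RetrodeformTemplate(config=cfg, bilateral=bmap, patches=(patch,))
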