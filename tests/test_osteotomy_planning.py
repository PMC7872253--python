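"""Chevron plan construction, virtual osteotomy, thickness and alignment."""

import dataclasses

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from coxaplan.core import BoneMesh, LandmarkSet
from coxaplan.geometry import DegenerateInputError
from coxaplan.osteotomy_planning import (
    OsteotomyPlan,
    chevron_planes,
    clip_mesh,
    interface_fit,
    max_subchondral_thickness,
    superimpose_landmarks,
)
from coxaplan.synthetic_data import FemurParams, generate_femur

from conftest import random_rigid


def random_landmarks(rng) -> LandmarkSet:
    while True:
        pts = rng.normal(size=(4, 3)) * 10
        try:
            return LandmarkSet(*pts)
        except ValueError:
            continue


class TestChevronPlanes:
    def test_defining_points_on_their_planes(self, rng):
        for _ in range(25):
            lm = random_landmarks(rng)
            plan = chevron_planes(lm)
            diag = np.linalg.norm(np.ptp(lm.physeal_points(), axis=0))
            for p in (lm.craniomedial, lm.caudomedial, lm.craniolateral):
                assert abs(plan.plane_a.signed_distance(p)) < 1e-9 * diag
            for p in (lm.caudomedial, lm.caudolateral, lm.craniolateral):
                assert abs(plan.plane_b.signed_distance(p)) < 1e-9 * diag

    def test_ridge_through_shared_landmarks(self, rng):
        lm = random_landmarks(rng)
        plan = chevron_planes(lm)
        diag = np.linalg.norm(np.ptp(lm.physeal_points(), axis=0))
        for shared in (lm.caudomedial, lm.craniolateral):
            assert abs(plan.plane_a.signed_distance(shared)) < 1e-9 * diag
            assert abs(plan.plane_b.signed_distance(shared)) < 1e-9 * diag

    def test_collinear_triple_rejected(self):
        with pytest.raises(DegenerateInputError):
            LandmarkSet([0, 0, 0], [2, 0, 0], [1, 0, 0], [0, 5, 1])

    def test_dihedral_matches_generator(self, default_femur):
        _, lm, gt = default_femur
        plan = chevron_planes(lm, head_reference=gt.head_center)
        assert plan.dihedral_angle == pytest.approx(gt.chevron_dihedral, abs=1e-6)

    def test_commutes_with_rigid_transform(self, rng):
        lm = random_landmarks(rng)
        plan = chevron_planes(lm)
        t = random_rigid(rng)
        plan_t = chevron_planes(lm.transformed(t))
        for pl, pl_t in ((plan.plane_a, plan_t.plane_a),
                         (plan.plane_b, plan_t.plane_b)):
            n_moved = t.apply_vector(pl.normal)
            assert np.allclose(np.abs(n_moved @ pl_t.normal), 1.0, atol=1e-9)
            assert abs(pl_t.signed_distance(t.apply(pl.point))) < 1e-9


def single_plane_plan(z: float, head_ref) -> OsteotomyPlan:
    lm = LandmarkSet([0.1, 0, z], [0, 0.2, z], [-0.2, 0.1, z], [0.1, -0.2, z])
    return chevron_planes(lm, head_reference=head_ref)


class TestClipMesh:
    def test_unit_cube_halved(self):
        cube = trimesh.creation.box(
            extents=[1, 1, 1],
            transform=trimesh.transformations.translation_matrix([0.5, 0.5, 0.5]))
        graft, rem = clip_mesh(cube, single_plane_plan(0.5, [0, 0, 1]))
        assert graft.volume == pytest.approx(0.5, rel=1e-9)
        assert rem.volume == pytest.approx(0.5, rel=1e-9)
        assert graft.is_watertight and rem.is_watertight

    def test_planes_missing_mesh(self):
        cube = trimesh.creation.box(extents=[1, 1, 1])
        with pytest.warns(UserWarning):
            graft, rem = clip_mesh(cube, single_plane_plan(5.0, [0, 0, 10]))
        assert len(graft.mesh.faces) == 0
        assert rem.volume == pytest.approx(1.0)

    def test_non_watertight_rejected(self):
        open_mesh = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                                    faces=[[0, 1, 2]])
        with pytest.raises(ValueError):
            clip_mesh(open_mesh, single_plane_plan(0.0, [0, 0, 1]))

    def test_volume_conservation_random_poses(self, rng):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        for _ in range(50):
            lm = random_landmarks(rng)
            plan = chevron_planes(lm, head_reference=rng.normal(size=3) * 5)
            graft, rem = clip_mesh(mesh, plan)
            assert graft.volume + rem.volume == pytest.approx(
                mesh.volume, rel=1e-3)

    def test_femoral_head_graft_vs_voxel_oracle(self, default_femur):
        """Graft volume agrees with an independent analytic voxel count."""
        from coxaplan.synthetic_data import neck_direction

        bone, lm, gt = default_femur
        p = FemurParams()
        plan = OsteotomyPlan(plane_a=gt.chevron_plane_a,
                             plane_b=gt.chevron_plane_b, source_landmarks=lm)
        graft, _ = clip_mesh(bone, plan)
        # oracle: voxel centers inside the analytic union of primitives and
        # on the head side of both planes, counted on a 0.2 mm grid
        h = 0.2
        lo = graft.mesh.bounds[0] - 1
        hi = graft.mesh.bounds[1] + 1
        axes = [np.arange(lo[i], hi[i], h) for i in range(3)]
        g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        d = neck_direction(p.inclination, p.version, p.side)
        hc = gt.head_center
        t = g @ d
        inside = (np.linalg.norm(g - hc, axis=1) <= p.head_radius) | (
            (np.linalg.norm(g - np.outer(t, d), axis=1) <= p.neck_radius)
            & (t >= 0) & (t <= p.neck_length)
        )
        inside &= (gt.chevron_plane_a.signed_distance(g) >= 0)
        inside &= (gt.chevron_plane_b.signed_distance(g) >= 0)
        oracle = inside.sum() * h**3
        assert graft.volume == pytest.approx(oracle, rel=0.01)


class TestSubchondralThickness:
    @pytest.mark.parametrize("cut_z,expect,ok", [(7.0, 5.0, True), (3.0, 9.0, False)])
    def test_spherical_cap_thickness(self, cut_z, expect, ok):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=12.0)
        plan = single_plane_plan(cut_z, [0, 0, 12])
        graft, _ = clip_mesh(sph, plan)
        graft.regions["articular"] = np.where(
            np.linalg.norm(graft.vertices, axis=1) > 11.9)[0]
        res = max_subchondral_thickness(graft)
        assert res.max_thickness == pytest.approx(expect, abs=0.2)
        assert res.thickness_ok is ok

    def test_empty_graft_is_trivially_ok(self):
        empty = BoneMesh(mesh=trimesh.Trimesh(vertices=np.zeros((0, 3)),
                                              faces=np.zeros((0, 3), int)))
        res = max_subchondral_thickness(empty)
        assert res.max_thickness == 0.0 and res.thickness_ok

    def test_missing_labels_error(self):
        sph = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        with pytest.raises(ValueError):
            max_subchondral_thickness(BoneMesh(mesh=sph))


class TestSuperimposeLandmarks:
    def test_identity(self, rng):
        src = rng.normal(size=(4, 3)) * 10
        t, rmsd = superimpose_landmarks(src, src)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(t.translation, 0, atol=1e-9)
        assert rmsd < 1e-9

    def test_recovers_known_transform(self, rng):
        src = rng.normal(size=(4, 3)) * 10
        R = Rotation.random(random_state=5).as_matrix()
        tr = np.array([4.0, -2.0, 9.0])
        t, rmsd = superimpose_landmarks(src, src @ R.T + tr)
        assert np.allclose(t.rotation, R, atol=1e-9)
        assert np.allclose(t.translation, tr, atol=1e-9)
        assert rmsd < 1e-9

    def test_mirrored_landmarks_rejected(self, rng):
        src = rng.normal(size=(4, 3)) * 10
        with pytest.raises(DegenerateInputError):
            superimpose_landmarks(src, src * np.array([-1.0, 1.0, 1.0]))

    def test_rmsd_invariant_under_prerotation(self, rng):
        src = rng.normal(size=(4, 3)) * 10
        dst = src + rng.normal(0, 0.5, size=(4, 3))
        _, rmsd0 = superimpose_landmarks(src, dst)
        R = Rotation.random(random_state=9).as_matrix()
        _, rmsd1 = superimpose_landmarks(src @ R.T, dst @ R.T)
        assert rmsd0 == pytest.approx(rmsd1, abs=1e-9)


class TestInterfaceFit:
    def test_identical_surfaces(self):
        m = trimesh.creation.icosphere(subdivisions=3, radius=11.0)
        fit = interface_fit(BoneMesh(mesh=m), BoneMesh(mesh=m.copy()))
        assert fit.mean_separation == pytest.approx(0.0, abs=1e-12)

    def test_cut_surfaces_offset_along_normal(self):
        m = trimesh.creation.box(extents=[20, 20, 2])
        m2 = m.copy()
        m2.vertices = m2.vertices + np.array([0, 0, 3.0])
        # apposing cut faces: top of the lower slab, bottom of the upper
        top = np.where(m.face_normals[:, 2] > 0.9)[0]
        bottom = np.where(m2.face_normals[:, 2] < -0.9)[0]
        fit = interface_fit(BoneMesh(mesh=m), BoneMesh(mesh=m2),
                            donor_faces=top, recipient_faces=bottom)
        assert fit.mean_separation == pytest.approx(1.0, abs=0.05)
        assert fit.max_separation == pytest.approx(1.0, abs=0.05)

    def test_shared_plan_donor_fits_recipient_bed(self, coarse_femur):
        bone, lm, gt = coarse_femur
        plan = OsteotomyPlan(plane_a=gt.chevron_plane_a,
                             plane_b=gt.chevron_plane_b, source_landmarks=lm)
        graft, _ = clip_mesh(bone, plan)
        graft2, _ = clip_mesh(bone, plan)
        fit = interface_fit(graft, graft2, n_samples=400)
        assert fit.mean_separation < 0.1
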