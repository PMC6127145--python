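"""Rigid alignment, mean shapes, expansion distances, enclosed volumes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventmorph import (
    CorrespondedSurface,
    DataError,
    DegeneracyError,
    SurfaceMesh,
    align_to,
    apply_expansion,
    expansion_map,
    group_mean_shape,
    mesh_volume,
    rigid_procrustes,
)
from ventmorph.mesh import icosphere
from ventmorph.synthetic import VENTRICLE_EXPANSION_ZONES, base_ventricle_shape


def rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * k @ k


class TestProcrustes:
    def test_identity_for_identical_point_sets(self, rng):
        pts = rng.normal(size=(30, 3))
        t = rigid_procrustes(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)

    def test_planted_rigid_motion_recovered(self, rng):
        pts = rng.normal(size=(50, 3)) * 10
        rot = rotation([0, 1, 0], np.deg2rad(25))
        trans = np.array([3.0, -2.0, 7.0])
        t = rigid_procrustes(pts, pts @ rot.T + trans)
        np.testing.assert_allclose(t.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(t.translation, trans, atol=1e-9)

    def test_pure_scaling_yields_identity_rotation_with_residual(self, rng):
        pts = rng.normal(size=(20, 3))
        t = rigid_procrustes(pts, 2.0 * pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        resid = np.linalg.norm(t.apply(pts) - 2.0 * pts)
        assert resid > 1e-3  # rigid alignment cannot absorb scale

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegeneracyError):
            rigid_procrustes(pts, pts[::-1])

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), angle=st.floats(0.1, 3.0))
    def test_residual_invariant_under_joint_rotation(self, seed, angle):
        rng = np.random.default_rng(seed)
        src = rng.normal(size=(15, 3))
        tgt = src + rng.normal(scale=0.2, size=src.shape)
        rot = rotation(rng.normal(size=3) + 0.1, angle)

        def residual(a, b):
            t = rigid_procrustes(a, b)
            return np.sum((t.apply(a) - b) ** 2)

        assert residual(src @ rot.T, tgt @ rot.T) == pytest.approx(
            residual(src, tgt), abs=1e-9)


class TestGroupMean:
    def _surf(self, verts, level=2):
        return CorrespondedSurface(verts, level=level)

    def test_two_copies_return_the_surface(self):
        sp = icosphere(2)
        verts = np.asarray(sp.vertices, float) * 5.0
        mean = group_mean_shape([self._surf(verts), self._surf(verts.copy())])
        np.testing.assert_allclose(mean.vertices, verts, atol=1e-9)

    def test_noisy_sphere_mean_shrinks_noise(self):
        rng = np.random.default_rng(5)
        sp = icosphere(2)
        truth = np.asarray(sp.vertices, float) * 10.0
        surfs = [self._surf(truth + rng.normal(scale=0.1, size=truth.shape))
                 for _ in range(10)]
        mean = group_mean_shape(surfs)
        # coordinate-wise RMS ~ sigma / sqrt(n) = 0.032
        rms = np.sqrt(np.mean((mean.vertices - truth) ** 2))
        assert rms < 0.05

    def test_mixed_levels_rejected(self):
        a = self._surf(np.asarray(icosphere(2).vertices, float), level=2)
        b = CorrespondedSurface(np.asarray(icosphere(3).vertices, float), level=3)
        with pytest.raises(Exception):
            group_mean_shape([a, b])


class TestExpansionMap:
    def test_subject_equals_mean_gives_zero_map(self):
        sp = icosphere(2)
        verts = np.asarray(sp.vertices, float) * 8.0
        mean = CorrespondedSurface(verts, level=2)
        subj = align_to(CorrespondedSurface(verts.copy(), level=2), mean)
        assert expansion_map(subj, mean).values.max() < 1e-9

    def test_uniform_normal_offset_gives_constant_map(self):
        sp = icosphere(3)
        verts = np.asarray(sp.vertices, float) * 20.0
        mean = CorrespondedSurface(verts, level=3)
        mesh = SurfaceMesh(verts, np.asarray(sp.faces))
        offset = verts + 2.0 * mesh.vertex_normals()
        subj = CorrespondedSurface(offset, level=3)
        subj.aligned = True  # same frame by construction
        vals = expansion_map(subj, mean).values
        np.testing.assert_allclose(vals, 2.0, rtol=0.01)

    def test_unaligned_subject_rejected(self):
        sp = icosphere(2)
        verts = np.asarray(sp.vertices, float)
        with pytest.raises(DataError):
            expansion_map(CorrespondedSurface(verts, level=2),
                          CorrespondedSurface(verts, level=2))

    def test_planted_zone_expansion_recovered(self):
        mesh, lab = base_ventricle_shape(3, "left")
        expanded = apply_expansion(mesh, lab, 1.0, amplitude=3.0, noise_sd=0.0)
        mean = CorrespondedSurface(mesh.vertices, level=3)
        subj = CorrespondedSurface(expanded.vertices, level=3)
        subj.aligned = True
        vals = expansion_map(subj, mean).values
        assert abs(vals.max() - 3.0) / 3.0 < 0.05
        assert lab.mask(VENTRICLE_EXPANSION_ZONES)[np.argmax(vals)]

    def test_invariant_under_joint_rigid_motion(self):
        mesh, lab = base_ventricle_shape(2, "left")
        expanded = apply_expansion(mesh, lab, 0.7, amplitude=4.0, noise_sd=0.0)
        rot = rotation([1, 2, 3], 0.8)
        trans = np.array([4.0, 5.0, -6.0])

        def dmap(mv, sv):
            mean = CorrespondedSurface(mv, level=2)
            subj = CorrespondedSurface(sv, level=2)
            subj.aligned = True
            return expansion_map(subj, mean).values

        base = dmap(mesh.vertices, expanded.vertices)
        moved = dmap(mesh.vertices @ rot.T + trans, expanded.vertices @ rot.T + trans)
        np.testing.assert_allclose(moved, base, atol=1e-9)


class TestVolume:
    def test_unit_icosphere_volume(self):
        sp = icosphere(4)
        mesh = SurfaceMesh(np.asarray(sp.vertices, float), np.asarray(sp.faces))
        expected = 4.0 * np.pi / 3.0
        assert abs(mesh_volume(mesh) - expected) / expected < 0.01

    def test_ellipsoid_volume(self):
        sp = icosphere(4)
        verts = np.asarray(sp.vertices, float) * [6.0, 2.0, 1.5]
        mesh = SurfaceMesh(verts, np.asarray(sp.faces))
        expected = 4.0 / 3.0 * np.pi * 6 * 2 * 1.5
        assert abs(mesh_volume(mesh) - expected) / expected < 0.02

    def test_scaling_law(self):
        mesh, _ = base_ventricle_shape(2, "left")
        v1 = mesh_volume(mesh)
        v2 = mesh_volume(SurfaceMesh(2.0 * mesh.vertices, mesh.faces))
        assert v2 == pytest.approx(8.0 * v1, rel=1e-9)

    def test_rigid_invariance(self):
        mesh, _ = base_ventricle_shape(2, "left")
        rot = rotation([1, 1, 0], 1.1)
        moved = SurfaceMesh(mesh.vertices @ rot.T + [10, 20, 30], mesh.faces)
        assert mesh_volume(moved) == pytest.approx(mesh_volume(mesh), rel=1e-9)

    def test_additive_over_disjoint_components(self):
        sp = icosphere(2)
        v = np.asarray(sp.vertices, float)
        f = np.asarray(sp.faces)
        two = SurfaceMesh(np.vstack([v, v + [5.0, 0, 0]]),
                          np.vstack([f, f + len(v)]))
        assert mesh_volume(two) == pytest.approx(
            2 * mesh_volume(SurfaceMesh(v, f)), rel=1e-12)

    def test_inverted_orientation_warns_negative(self):
        sp = icosphere(2)
        flipped = SurfaceMesh(np.asarray(sp.vertices, float),
                              np.asarray(sp.faces)[:, [0, 2, 1]])
        with pytest.warns(UserWarning):
            assert mesh_volume(flipped) < 0
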