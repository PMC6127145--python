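"""SPHARM correspondence: parameterization, decomposition, alignment."""

import numpy as np
import pytest

from ventmorph import (
    SurfaceMesh,
    TopologyError,
    correspond,
    first_order_align,
    mesh_volume,
    rigid_procrustes,
    rotate_coefficients,
    spharm_decompose,
    spharm_reconstruct,
    spherical_parameterize,
)
from ventmorph.mesh import icosphere
from ventmorph.spharm import SphericalParam, _solid_angles, real_sh_basis, sh_index
from ventmorph.synthetic import base_ventricle_shape


def unit_sphere_mesh(level=3):
    sp = icosphere(level)
    return SurfaceMesh(np.asarray(sp.vertices, float), np.asarray(sp.faces))


def sphere_directions(level):
    u = np.asarray(icosphere(level).vertices, float)
    return u / np.linalg.norm(u, axis=1, keepdims=True)


class TestParameterization:
    def test_unit_sphere_maps_near_identity(self):
        mesh = unit_sphere_mesh(3)
        p = spherical_parameterize(mesh)
        # the discrete area-cost minimum is not exactly the identity map
        # (flat triangle areas vs solid angles), but it is very close
        assert p.area_cost < 1e-4
        assert np.abs(p.unit - mesh.vertices).max() < 5e-3

    def test_ellipsoid_no_flips_and_full_spherical_area(self):
        mesh, _ = base_ventricle_shape(4, "left", bend_amplitude=0.0)
        p = spherical_parameterize(mesh)
        omega = _solid_angles(p.unit, mesh.faces)
        assert omega.min() > 0
        assert abs(omega.sum() - 4 * np.pi) / (4 * np.pi) < 0.01

    def test_open_mesh_rejected(self):
        mesh = unit_sphere_mesh(2)
        open_mesh = SurfaceMesh(mesh.vertices, mesh.faces[:-1])
        with pytest.raises(TopologyError):
            spherical_parameterize(open_mesh)

    def test_area_distortion_reduced_from_initial_embedding(self):
        mesh, _ = base_ventricle_shape(3, "left")
        p = spherical_parameterize(mesh)
        # Gauss-map initial cost for this elongated shape is O(100)
        assert p.area_cost < 10.0


class TestDecomposition:
    def test_sphere_energy_is_first_order(self):
        mesh = unit_sphere_mesh(3)
        p = spherical_parameterize(mesh)
        c = spharm_decompose(mesh, p, l_max=8)
        e = c.degree_energy()
        assert e[:2].sum() / e.sum() > 0.999

    def test_ellipsoid_coefficients_match_analytic_projection(self):
        # identity parameterization of an axis-aligned ellipsoid: the
        # coordinate functions are exactly degree-1 real harmonics with
        # amplitudes a/N, b/N, c/N where N = sqrt(3 / 4 pi)
        a, b, c = 6.0, 2.0, 1.5
        dirs = sphere_directions(3)
        verts = dirs * [a, b, c]
        coeffs = spharm_decompose(verts, SphericalParam(unit=dirs), l_max=6)
        n = np.sqrt(3.0 / (4.0 * np.pi))
        expected = np.zeros_like(coeffs.coeffs)
        expected[sh_index(1, 1), 0] = a / n
        expected[sh_index(1, -1), 1] = b / n
        expected[sh_index(1, 0), 2] = c / n
        np.testing.assert_allclose(coeffs.coeffs, expected, atol=1e-9)

    def test_residual_monotone_in_degree(self):
        mesh, _ = base_ventricle_shape(3, "left")
        p = spherical_parameterize(mesh)
        resids = [spharm_decompose(mesh, p, l_max=L).residual_rms for L in (4, 6, 8, 10, 12)]
        assert np.all(np.diff(resids) < 0)

    def test_reconstruct_degree0_collapses_to_centroid(self):
        dirs = sphere_directions(2)
        coeffs = spharm_decompose(dirs * 2.0 + [1.0, -2.0, 0.5],
                                  SphericalParam(unit=dirs), l_max=4)
        coeffs.coeffs[1:] = 0.0
        rec = spharm_reconstruct(coeffs, level=2)
        assert np.abs(rec.vertices - rec.vertices[0]).max() < 1e-12
        np.testing.assert_allclose(rec.vertices[0], [1.0, -2.0, 0.5], atol=1e-9)

    def test_sphere_reconstruction_radius_one(self):
        mesh = unit_sphere_mesh(3)
        p = spherical_parameterize(mesh)
        c = spharm_decompose(mesh, p, l_max=8)
        rec = spharm_reconstruct(c, level=3)
        radii = np.linalg.norm(rec.vertices, axis=1)
        np.testing.assert_allclose(radii, 1.0, atol=1e-6)

    def test_decompose_reconstruct_round_trip(self):
        mesh, _ = base_ventricle_shape(3, "left")
        p = spherical_parameterize(mesh)
        c = spharm_decompose(mesh, p, l_max=8)
        rec = spharm_reconstruct(c, level=3)
        c2 = spharm_decompose(rec.vertices, SphericalParam(unit=sphere_directions(3)),
                              l_max=8)
        scale = np.abs(c.coeffs).max()
        assert np.abs(c2.coeffs - c.coeffs).max() / scale < 1e-6


class TestFirstOrderAlignment:
    def _aligned_ellipsoid_coeffs(self):
        dirs = sphere_directions(3)
        verts = dirs * [6.0, 2.0, 1.5]
        coeffs = spharm_decompose(verts, SphericalParam(unit=dirs), l_max=6)
        aligned, _ = first_order_align(coeffs)
        return aligned

    def test_already_aligned_ellipsoid_identity(self):
        aligned = self._aligned_ellipsoid_coeffs()
        again, rot = first_order_align(aligned)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(again.coeffs, aligned.coeffs, atol=1e-9)

    def test_planted_parameter_rotation_recovered(self):
        aligned = self._aligned_ellipsoid_coeffs()
        ang = np.deg2rad(30)
        rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                       [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        rotated = rotate_coefficients(aligned, rz)
        recovered, rot = first_order_align(rotated)
        np.testing.assert_allclose(rot, rz.T, atol=1e-6)
        np.testing.assert_allclose(recovered.coeffs, aligned.coeffs, atol=1e-6)

    def test_sphere_warns_and_returns_identity(self):
        dirs = sphere_directions(2)
        coeffs = spharm_decompose(dirs, SphericalParam(unit=dirs), l_max=4)
        with pytest.warns(UserWarning):
            out, rot = first_order_align(coeffs)
        np.testing.assert_allclose(rot, np.eye(3))
        np.testing.assert_allclose(out.coeffs, coeffs.coeffs)


class TestCorrespondence:
    def test_rigid_motion_propagates_to_corresponded_surfaces(self):
        mesh, _ = base_ventricle_shape(3, "left")
        ang = np.deg2rad(40)
        rot = np.array([[np.cos(ang), 0, np.sin(ang)], [0, 1, 0],
                        [-np.sin(ang), 0, np.cos(ang)]])
        moved = SurfaceMesh(mesh.vertices @ rot.T + [5.0, -3.0, 2.0], mesh.faces)
        c1 = correspond(mesh, l_max=8, level=3)
        c2 = correspond(moved, l_max=8, level=3)
        t = rigid_procrustes(c1.vertices, c2.vertices)
        np.testing.assert_allclose(t.rotation, rot, atol=1e-3)
        resid = np.linalg.norm(t.apply(c1.vertices) - c2.vertices, axis=1)
        assert resid.max() < 1e-3

    def test_corresponded_volume_close_to_input(self):
        mesh, _ = base_ventricle_shape(3, "left")
        c = correspond(mesh, l_max=12, level=3)
        assert abs(mesh_volume(c.to_mesh()) - mesh_volume(mesh)) / mesh_volume(mesh) < 0.05


def test_real_basis_is_orthonormal_on_quadrature_grid():
    from ventmorph.spharm import _quadrature_grid, _unit_to_angles

    dirs, w = _quadrature_grid(8)
    theta, phi = _unit_to_angles(dirs)
    b = real_sh_basis(theta, phi, 4)
    gram = b.T @ (w[:, None] * b)
    np.testing.assert_allclose(gram, np.eye(b.shape[1]), atol=1e-10)
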