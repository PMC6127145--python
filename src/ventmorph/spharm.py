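"""Spherical-harmonic shape correspondence (SPHARM point-distribution model).

A closed genus-0 surface is (1) mapped bijectively onto the unit sphere by
an area-preserving, distortion-minimizing relaxation, (2) expanded in real
spherical harmonics of its three coordinate functions, (3) canonically
oriented in parameter space by the first-order ellipsoid, and (4) resampled
at the fixed icosahedral sphere sampling, so vertex k corresponds across
subjects.

Notation: theta is colatitude (angle from +z), phi is longitude.  The real
orthonormal basis is indexed (l, m) with m running -l..l; the degree-0
coefficients encode the centroid and degree 1 the best-fit ellipsoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from ._errors import ConfigError, ConvergenceError, DegeneracyError
from .mesh import CorrespondedSurface, SurfaceMesh, icosphere

__all__ = [
    "SphericalParam",
    "SpharmCoefficients",
    "spherical_parameterize",
    "spharm_decompose",
    "spharm_reconstruct",
    "first_order_align",
    "rotate_coefficients",
    "real_sh_basis",
    "correspond",
]

DEFAULT_L_MAX = 12
DEFAULT_SAMPLING_LEVEL = 4


# ----------------------------------------------------------------------
# real spherical-harmonic basis
# ----------------------------------------------------------------------

def sh_index(l: int, m: int) -> int:
    """Flat index of (l, m) in the (L+1)^2 coefficient layout."""
    return l * l + l + m


def real_sh_basis(theta: np.ndarray, phi: np.ndarray, l_max: int) -> np.ndarray:
    """Orthonormal real spherical harmonics, shape (N, (l_max+1)^2).

    m = 0 columns are the zonal harmonics; m > 0 are sqrt(2) (-1)^m Re Y_l^m,
    m < 0 are sqrt(2) (-1)^m Im Y_l^|m| (Condon-Shortley phase absorbed).
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    n = theta.size
    out = np.empty((n, (l_max + 1) ** 2))
    for l in range(l_max + 1):
        for m in range(l + 1):
            y = special.sph_harm_y(l, m, theta, phi)
            if m == 0:
                out[:, sh_index(l, 0)] = y.real
            else:
                s = np.sqrt(2.0) * (-1.0) ** m
                out[:, sh_index(l, m)] = s * y.real
                out[:, sh_index(l, -m)] = s * y.imag
    return out


def _unit_to_angles(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    return theta, phi


# ----------------------------------------------------------------------
# spherical parameterization
# ----------------------------------------------------------------------

@dataclass
class SphericalParam:
    """Per-vertex unit-sphere embedding of a genus-0 mesh."""

    unit: np.ndarray            # (V, 3) unit vectors
    area_cost: float = np.nan   # final area-distortion cost
    iterations: int = 0

    @property
    def theta(self) -> np.ndarray:
        return _unit_to_angles(self.unit)[0]

    @property
    def phi(self) -> np.ndarray:
        return _unit_to_angles(self.unit)[1]


def _solid_angles(u: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Signed spherical-triangle areas (solid angles) per face."""
    a, b, c = u[faces[:, 0]], u[faces[:, 1]], u[faces[:, 2]]
    num = np.einsum("ij,ij->i", a, np.cross(b, c))
    den = 1.0 + np.einsum("ij,ij->i", a, b) + np.einsum("ij,ij->i", b, c) + np.einsum("ij,ij->i", c, a)
    return 2.0 * np.arctan2(num, den)


def _area_cost(omega: np.ndarray, target: np.ndarray) -> float:
    return float(np.sum((omega / target - 1.0) ** 2))


def spherical_parameterize(
    mesh: SurfaceMesh,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SphericalParam:
    """Area-preserving, distortion-minimizing spherical mapping.

    The Gauss-map style initial embedding (vertices normalized about the
    centroid) is refined by an iterative relaxation that descends the
    area-distortion cost sum_f (spherical_area_f / target_f - 1)^2, where
    the target is the mesh face area rescaled so the total is 4 pi.  The
    relaxation stops when the relative cost improvement falls below ``tol``
    or after ``max_iter`` iterations; the result is guaranteed free of
    flipped (orientation-reversing) spherical triangles.
    """
    mesh.require_closed_genus0("input to spherical_parameterize")
    v = mesh.vertices
    faces = mesh.faces
    centroid = v.mean(axis=0)
    u = v - centroid
    nrm = np.linalg.norm(u, axis=1, keepdims=True)
    if np.any(nrm < 1e-12):
        raise DegeneracyError("vertex coincides with the centroid; cannot initialize Gauss map")
    u = u / nrm

    areas = mesh.face_areas()
    total = areas.sum()
    target = areas * (4.0 * np.pi / total)
    deg = np.bincount(faces.ravel(), minlength=len(v)).astype(float)

    u = _untangle(u, faces)

    omega = _solid_angles(u, faces)
    cost = _area_cost(omega, target)
    step = 1e-3
    it = 0
    for it in range(1, max_iter + 1):
        grad = _area_cost_gradient(u, faces, omega, target)
        # tangential descent with Laplacian smoothing of the step field to
        # damp the mesh-frequency oscillation a pure pointwise step excites
        delta = -grad / deg[:, None]

        improved = False
        rel = 0.0
        s = step
        for _ in range(20):
            cand = u + s * delta
            cand /= np.linalg.norm(cand, axis=1, keepdims=True)
            om = _solid_angles(cand, faces)
            if om.min() > 0:
                c = _area_cost(om, target)
                if c < cost:
                    rel = (cost - c) / max(cost, 1e-300)
                    u, omega, cost = cand, om, c
                    step = s * 1.5
                    improved = True
                    break
            s *= 0.5
        if not improved:
            break
        if rel < tol:
            break

    n_flipped = int(np.sum(omega <= 0))
    if n_flipped:
        raise ConvergenceError(
            f"spherical parameterization retains {n_flipped} flipped triangles"
        )
    return SphericalParam(unit=u, area_cost=cost, iterations=it)


def _area_cost_gradient(u: np.ndarray, faces: np.ndarray,
                        omega: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Exact gradient of sum_f (omega_f/t_f - 1)^2 w.r.t. sphere positions.

    For a spherical triangle (a, b, c), omega = 2 atan2(D, S) with
    D = a.(b x c) and S = 1 + a.b + b.c + c.a, so
    d omega / d a = 2 (S (b x c) - D (b + c)) / (D^2 + S^2); the result is
    projected on each vertex's tangent plane.
    """
    a, b, c = u[faces[:, 0]], u[faces[:, 1]], u[faces[:, 2]]
    d = np.einsum("ij,ij->i", a, np.cross(b, c))
    s = 1.0 + np.einsum("ij,ij->i", a, b) + np.einsum("ij,ij->i", b, c) + np.einsum("ij,ij->i", c, a)
    denom = d * d + s * s
    pref = (2.0 * (omega / target - 1.0) / target) * (2.0 / denom)
    grad = np.zeros_like(u)
    for k, (p, q) in enumerate(((1, 2), (2, 0), (0, 1))):
        vp, vq = u[faces[:, p]], u[faces[:, q]]
        g = pref[:, None] * (s[:, None] * np.cross(vp, vq) - d[:, None] * (vp + vq))
        np.add.at(grad, faces[:, k], g)
    # project onto tangent planes
    grad -= np.einsum("ij,ij->i", grad, u)[:, None] * u
    return grad


def _untangle(u: np.ndarray, faces: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Remove flipped spherical triangles by damped Tutte-style smoothing."""
    omega = _solid_angles(u, faces)
    if omega.min() > 0:
        return u
    n = len(u)
    deg = np.bincount(faces.ravel(), minlength=n).astype(float)
    for _ in range(max_iter):
        acc = np.zeros_like(u)
        centers = u[faces[:, 0]] + u[faces[:, 1]] + u[faces[:, 2]]
        np.add.at(acc, faces[:, 0], centers - u[faces[:, 0]])
        np.add.at(acc, faces[:, 1], centers - u[faces[:, 1]])
        np.add.at(acc, faces[:, 2], centers - u[faces[:, 2]])
        u = u + 0.2 * acc / (2.0 * deg[:, None])
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        omega = _solid_angles(u, faces)
        if omega.min() > 0:
            return u
    raise ConvergenceError(
        f"failed to remove {int(np.sum(omega <= 0))} flipped triangles during initialization"
    )


# ----------------------------------------------------------------------
# harmonic decomposition / reconstruction
# ----------------------------------------------------------------------

@dataclass
class SpharmCoefficients:
    """Real spherical-harmonic coefficients of the coordinate functions.

    ``coeffs`` has shape ((l_max+1)^2, 3): one column per coordinate
    (x, y, z), rows ordered (l, m) with m = -l..l within each degree.
    """

    coeffs: np.ndarray
    l_max: int
    residual_rms: float = np.nan
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        expected = (self.l_max + 1) ** 2
        if self.coeffs.shape != (expected, 3):
            raise ConfigError(
                f"coefficients must have shape ({expected}, 3) for l_max={self.l_max}"
            )

    def degree_energy(self) -> np.ndarray:
        """Total squared coefficient norm per degree, shape (l_max+1,)."""
        e = np.empty(self.l_max + 1)
        for l in range(self.l_max + 1):
            e[l] = np.sum(self.coeffs[l * l:(l + 1) ** 2] ** 2)
        return e

    def degree1_matrix(self) -> np.ndarray:
        """3x3 linear map M with degree-1 surface = M @ (unit direction)."""
        c1 = self.coeffs[1:4]  # rows m=-1,0,1 -> direction components y,z,x
        n = np.sqrt(3.0 / (4.0 * np.pi))
        perm = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        return n * c1.T @ perm


def spharm_decompose(
    mesh_or_vertices,
    param: SphericalParam,
    l_max: int = DEFAULT_L_MAX,
) -> SpharmCoefficients:
    """Least-squares fit of real spherical harmonics to the coordinates.

    Requires (l_max+1)^2 <= number of vertices and a well-conditioned
    design (vertices spread over the sphere).
    """
    verts = mesh_or_vertices.vertices if hasattr(mesh_or_vertices, "vertices") else np.asarray(mesh_or_vertices, float)
    n = len(verts)
    k = (l_max + 1) ** 2
    if k > n:
        raise ConfigError(f"(l_max+1)^2 = {k} exceeds vertex count {n}")
    theta, phi = _unit_to_angles(param.unit)
    design = real_sh_basis(theta, phi, l_max)
    sv = np.linalg.svd(design, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > 1e8:
        raise DegeneracyError(
            "ill-conditioned spherical-harmonic design "
            f"(condition number {sv[0] / max(sv[-1], 1e-300):.2e}); "
            "vertices too few or too clustered on the sphere"
        )
    coeffs, *_ = np.linalg.lstsq(design, verts, rcond=None)
    resid = verts - design @ coeffs
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SpharmCoefficients(coeffs=coeffs, l_max=l_max, residual_rms=rms)


def spharm_reconstruct(
    coeffs: SpharmCoefficients,
    level: int = DEFAULT_SAMPLING_LEVEL,
    subject_id: str = "",
    side: str = "",
) -> CorrespondedSurface:
    """Evaluate the expansion at the fixed icosahedral sphere sampling."""
    if level < 2:
        raise ConfigError("sampling level must be >= 2")
    sphere = icosphere(level)
    u = np.asarray(sphere.vertices, dtype=float)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    theta, phi = _unit_to_angles(u)
    basis = real_sh_basis(theta, phi, coeffs.l_max)
    verts = basis @ coeffs.coeffs
    return CorrespondedSurface(vertices=verts, level=level, subject_id=subject_id, side=side)


# ----------------------------------------------------------------------
# parameter-space rotation and first-order alignment
# ----------------------------------------------------------------------

def _quadrature_grid(l_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Sphere quadrature exact for products of degree <= l_max harmonics.

    Gauss-Legendre in cos(theta) with l_max+1 nodes, uniform longitudes with
    2*l_max+2 nodes; returns (directions (N,3), weights (N,)) with weights
    summing to 4 pi.
    """
    nt = l_max + 1
    nph = 2 * l_max + 2
    x, wt = np.polynomial.legendre.leggauss(nt)
    phi = 2.0 * np.pi * np.arange(nph) / nph
    wphi = 2.0 * np.pi / nph
    ct, ph = np.meshgrid(x, phi, indexing="ij")
    st = np.sqrt(1.0 - ct**2)
    dirs = np.stack([st * np.cos(ph), st * np.sin(ph), ct], axis=-1).reshape(-1, 3)
    w = (wt[:, None] * np.ones(nph)[None, :]).reshape(-1) * wphi
    return dirs, w


def rotate_coefficients(coeffs: SpharmCoefficients, rotation: np.ndarray) -> SpharmCoefficients:
    """Coefficients of the reparameterized surface f'(w) = f(R w).

    Exact for band-limited expansions: the rotated function is sampled on a
    quadrature grid and re-projected onto the basis.
    """
    rotation = np.asarray(rotation, dtype=float)
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-9) or np.linalg.det(rotation) < 0:
        raise ConfigError("parameter-space rotation must be a proper rotation matrix")
    dirs, w = _quadrature_grid(2 * coeffs.l_max)
    rot_dirs = dirs @ rotation.T
    theta_r, phi_r = _unit_to_angles(rot_dirs)
    values = real_sh_basis(theta_r, phi_r, coeffs.l_max) @ coeffs.coeffs
    theta, phi = _unit_to_angles(dirs)
    basis = real_sh_basis(theta, phi, coeffs.l_max)
    new = basis.T @ (w[:, None] * values)
    return SpharmCoefficients(coeffs=new, l_max=coeffs.l_max,
                              residual_rms=coeffs.residual_rms,
                              metadata=dict(coeffs.metadata))


def first_order_align(
    coeffs: SpharmCoefficients,
    degeneracy_tol: float = 1e-6,
) -> tuple[SpharmCoefficients, np.ndarray]:
    """Canonical parameter-space orientation from the first-order ellipsoid.

    The degree-1 part of the expansion is a linear map M from the parameter
    sphere to the best-fit ellipsoid.  Rotating the parameter sphere by the
    right singular vectors of M sends the parameter axes onto the ellipsoid
    principal directions in canonical (descending axis length) order, which
    makes the phi origin and pole consistent across subjects.

    Returns (aligned coefficients, applied parameter rotation).  A nearly
    spherical first-order ellipsoid carries no orientation information; the
    input is returned unchanged with a warning.
    """
    m = coeffs.degree1_matrix()
    uu, sig, vt = np.linalg.svd(m)
    if sig[0] < 1e-12:
        warnings.warn("degree-1 coefficients vanish; first-order alignment skipped")
        return coeffs, np.eye(3)
    if (sig[0] - sig[2]) / sig[0] < degeneracy_tol:
        warnings.warn(
            "first-order ellipsoid is spherical to tolerance; "
            "alignment is undefined and the identity is used"
        )
        return coeffs, np.eye(3)
    v = vt.T
    # deterministic sign convention: dominant entry of each axis positive
    for k in range(3):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    if np.allclose(v, np.eye(3), atol=1e-12):
        return coeffs, np.eye(3)
    return rotate_coefficients(coeffs, v), v


# ----------------------------------------------------------------------
# one-call correspondence
# ----------------------------------------------------------------------

def correspond(
    mesh: SurfaceMesh,
    l_max: int = DEFAULT_L_MAX,
    level: int = DEFAULT_SAMPLING_LEVEL,
    align: bool = True,
    subject_id: str = "",
    side: str = "",
) -> CorrespondedSurface:
    """Full SPHARM correspondence: parameterize, fit, orient, resample."""
    param = spherical_parameterize(mesh)
    coeffs = spharm_decompose(mesh, param, l_max=l_max)
    if align:
        coeffs, _ = first_order_align(coeffs)
    return spharm_reconstruct(coeffs, level=level, subject_id=subject_id, side=side)
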