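"""Rigid alignment, control mean shape, expansion distances and volumes.

The "expansion map" is the unsigned per-vertex Euclidean distance between a
subject's corresponded surface and the healthy-control average shape, after
rigid Procrustes alignment (rotation + translation, no scaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._errors import ConfigError, DataError, DegeneracyError, TopologyError
from .mesh import CorrespondedSurface

__all__ = [
    "RigidTransform",
    "ExpansionMap",
    "rigid_procrustes",
    "apply_transform",
    "align_to",
    "group_mean_shape",
    "expansion_map",
    "mesh_volume",
]


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation; rotation is proper (det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ConfigError("rotation must be orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise ConfigError("rotation must be proper (determinant +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class ExpansionMap:
    """Unsigned per-vertex distance (mm) to the control average shape."""

    values: np.ndarray
    subject_id: str = ""
    side: str = ""
    level: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise DataError("expansion distances must be finite and nonnegative")


def rigid_procrustes(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid motion taking ``source`` onto ``target`` (Kabsch).

    Closed form via SVD of the cross-covariance with determinant correction;
    no scaling.  Points are matched by index.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3 or len(src) < 3:
        raise ConfigError("point sets must be matching (N, 3) arrays with N >= 3")
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    a = src - mu_s
    b = tgt - mu_t
    h = a.T @ b
    u, sig, vt = np.linalg.svd(h)
    rank_s = np.linalg.matrix_rank(a, tol=1e-9 * max(1.0, np.abs(a).max()))
    if rank_s < 2:
        raise DegeneracyError("source points are collinear; rotation is not identifiable")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_t - rot @ mu_s
    return RigidTransform(rot, trans)


def apply_transform(surface: CorrespondedSurface, transform: RigidTransform,
                    aligned: bool = True) -> CorrespondedSurface:
    out = surface.copy(vertices=transform.apply(surface.vertices))
    out.aligned = aligned
    return out


def align_to(surface: CorrespondedSurface, reference: CorrespondedSurface) -> CorrespondedSurface:
    """Rigidly align a corresponded surface to a reference (e.g. the control mean)."""
    if surface.level != reference.level:
        raise TopologyError("cannot align surfaces sampled at different levels")
    t = rigid_procrustes(surface.vertices, reference.vertices)
    return apply_transform(surface, t)


def group_mean_shape(
    surfaces: list[CorrespondedSurface],
    iterate: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> CorrespondedSurface:
    """Average shape of a group (generalized Procrustes).

    Each surface is rigidly aligned to the evolving vertex-wise mean until
    the mean moves less than ``tol`` mm (RMS).  With ``iterate=False`` a
    single pass against the plain arithmetic mean is performed.
    """
    if len(surfaces) < 2:
        raise ConfigError("group mean requires at least 2 surfaces")
    levels = {s.level for s in surfaces}
    if len(levels) != 1:
        raise TopologyError(f"mixed sampling levels {sorted(levels)}")
    level = levels.pop()
    stack = np.stack([s.vertices for s in surfaces])
    mean = stack.mean(axis=0)
    n_pass = max_iter if iterate else 1
    for _ in range(n_pass):
        aligned = np.empty_like(stack)
        for i in range(len(stack)):
            t = rigid_procrustes(stack[i], mean)
            aligned[i] = t.apply(stack[i])
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    out = CorrespondedSurface(vertices=mean, level=level, subject_id="group_mean")
    out.aligned = True
    return out


def expansion_map(subject: CorrespondedSurface, mean: CorrespondedSurface) -> ExpansionMap:
    """Unsigned vertex-wise Euclidean distance subject vs. mean shape."""
    if subject.level != mean.level:
        raise TopologyError("subject and mean sampled at different levels")
    if not subject.aligned:
        raise DataError(
            "subject surface is not flagged as rigidly aligned to the mean; "
            "align with align_to() first"
        )
    d = np.linalg.norm(subject.vertices - mean.vertices, axis=1)
    return ExpansionMap(values=d, subject_id=subject.subject_id,
                        side=subject.side, level=subject.level)


def signed_expansion_map(subject: CorrespondedSurface, mean: CorrespondedSurface) -> ExpansionMap:
    """Displacement projected on the outward normal of the mean shape.

    Off by default in the pipeline: the reference definition of the
    ventricle difference is the unsigned distance.  Returned as a plain
    array wrapped in ExpansionMap semantics is not possible (values may be
    negative), so this returns a bare ndarray.
    """
    if subject.level != mean.level:
        raise TopologyError("subject and mean sampled at different levels")
    if not subject.aligned:
        raise DataError("subject surface is not aligned to the mean")
    normals = mean.to_mesh().vertex_normals()
    return np.einsum("ij,ij->i", subject.vertices - mean.vertices, normals)


def mesh_volume(mesh) -> float:
    """Enclosed volume (mm^3) by the signed-tetrahedron (divergence) sum.

    Positive for outward-oriented closed surfaces; an inverted orientation
    yields a negative value with a warning.
    """
    if isinstance(mesh, CorrespondedSurface):
        verts, faces = mesh.vertices, mesh.faces
    else:
        verts, faces = mesh.vertices, mesh.faces
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    vol = float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)
    if vol < 0:
        warnings.warn("negative enclosed volume: surface orientation is inverted")
    return vol
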