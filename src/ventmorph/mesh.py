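"""Mesh containers and basic geometry.

All meshes are triangulated surfaces in millimetres, right-handed
coordinates, faces oriented outward, vertex indices 0-based.  ``trimesh``
backs construction (icospheres), topology checks and OBJ/PLY export;
the containers here stay thin so fixed-topology vertex order is never
silently re-processed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from ._errors import TopologyError

__all__ = [
    "SurfaceMesh",
    "CorrespondedSurface",
    "icosphere",
    "icosphere_vertex_count",
]


def icosphere(subdivisions: int) -> trimesh.Trimesh:
    """Unit icosphere; subdivision level 2 -> 162 vertices, 3 -> 642, 4 -> 2562."""
    return trimesh.creation.icosphere(subdivisions=subdivisions)


def icosphere_vertex_count(subdivisions: int) -> int:
    return 10 * 4**subdivisions + 2


@dataclass
class SurfaceMesh:
    """Closed triangulated 3-D surface.

    Parameters
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 3) int array, outward-oriented triangles
    """

    vertices: np.ndarray
    faces: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise TopologyError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise TopologyError("faces must be (F, 3) triangles")

    # -- derived quantities ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def euler_characteristic(self) -> int:
        tm = self.to_trimesh()
        return int(tm.euler_number)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def is_closed(self) -> bool:
        tm = self.to_trimesh()
        return bool(tm.is_watertight and tm.is_winding_consistent)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        return np.asarray(self.to_trimesh().vertex_normals, dtype=float)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), dict(self.metadata))

    def require_closed_genus0(self, what: str = "mesh") -> None:
        tm = self.to_trimesh()
        if not tm.is_watertight:
            raise TopologyError(f"{what} is not closed (open boundary or non-manifold edges)")
        if not tm.is_winding_consistent:
            raise TopologyError(f"{what} is not consistently oriented")
        if tm.euler_number != 2:
            raise TopologyError(
                f"{what} is not genus 0 (Euler characteristic {tm.euler_number}, expected 2)"
            )


@dataclass
class CorrespondedSurface:
    """Fixed-topology surface sampled on the icosahedral sphere sampling.

    Vertex ``k`` corresponds across every subject sampled at the same
    ``level`` (level 3 -> 642 vertices, level 4 -> 2562).
    """

    vertices: np.ndarray
    level: int
    subject_id: str = ""
    side: str = ""
    aligned: bool = False

    _faces_cache: dict = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        expected = icosphere_vertex_count(self.level)
        if len(self.vertices) != expected:
            raise TopologyError(
                f"sampling level {self.level} implies {expected} vertices, "
                f"got {len(self.vertices)}"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def faces(self) -> np.ndarray:
        return icosphere(self.level).faces.copy()

    def to_mesh(self) -> SurfaceMesh:
        return SurfaceMesh(self.vertices.copy(), self.faces)

    def copy(self, **updates) -> "CorrespondedSurface":
        kw = dict(
            vertices=self.vertices.copy(),
            level=self.level,
            subject_id=self.subject_id,
            side=self.side,
            aligned=self.aligned,
        )
        kw.update(updates)
        return CorrespondedSurface(**kw)
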