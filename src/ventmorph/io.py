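"""Standard-format I/O: OBJ/PLY/GIFTI surfaces, CSV/GIFTI scalar maps,
covariate tables and plain-text rigid transforms.

Conventions: millimetres, right-handed coordinates, outward-oriented
faces, 0-based vertex indices.  Round-trips preserve coordinates and
values to better than 1e-6 relative.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from ._errors import DataError
from .mesh import SurfaceMesh

__all__ = [
    "read_surface",
    "write_surface",
    "read_scalar_map",
    "write_scalar_map",
    "read_covariates",
    "write_covariates",
    "read_transform",
    "write_transform",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = ("subject_id", "group", "age", "sex", "icv_mm3", "kmmse", "severity")

_SURFACE_EXTS = (".obj", ".ply", ".surf.gii", ".gii")


def _ext(path: Path) -> str:
    name = path.name.lower()
    for e in (".surf.gii", ".shape.gii", ".func.gii"):
        if name.endswith(e):
            return e
    return path.suffix.lower()


def read_surface(path) -> SurfaceMesh:
    """Load a triangulated surface from OBJ, PLY or GIFTI (.surf.gii)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"surface file not found: {path}")
    ext = _ext(path)
    if ext in (".obj", ".ply"):
        try:
            tm = trimesh.load(path, process=False, force="mesh")
        except Exception as exc:  # noqa: BLE001 - surface format errors vary
            raise DataError(f"could not parse surface {path}: {exc}") from exc
        return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
    if ext in (".surf.gii", ".gii"):
        import nibabel as nib

        img = nib.load(str(path))
        verts = faces = None
        for da in img.darrays:
            if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                verts = np.asarray(da.data, float)
            elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = np.asarray(da.data, np.int64)
        if verts is None or faces is None:
            raise DataError(f"GIFTI file {path} lacks POINTSET/TRIANGLE arrays")
        return SurfaceMesh(verts, faces)
    raise DataError(f"unrecognized surface extension {ext!r} for {path}")


def write_surface(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ext = _ext(path)
    if ext == ".obj":
        with open(path, "w") as fh:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    elif ext == ".ply":
        mesh.to_trimesh().export(path, encoding="ascii")
    elif ext in (".surf.gii", ".gii"):
        import nibabel as nib

        da_v = nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                        intent="NIFTI_INTENT_POINTSET")
        da_f = nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                        intent="NIFTI_INTENT_TRIANGLE")
        nib.save(nib.gifti.GiftiImage(darrays=[da_v, da_f]), str(path))
    else:
        raise DataError(f"unrecognized surface extension {ext!r} for {path}")


def read_scalar_map(path, subject_id: str | None = None) -> np.ndarray:
    """Load a per-vertex scalar map from CSV (subject_id, vertex_index, value)
    or GIFTI (.shape.gii)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"scalar map not found: {path}")
    ext = _ext(path)
    if ext == ".csv":
        df = pd.read_csv(path)
        for col in ("subject_id", "vertex_index", "value"):
            if col not in df.columns:
                raise DataError(f"scalar map {path} is missing column {col!r}")
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
            if df.empty:
                raise DataError(f"no rows for subject {subject_id!r} in {path}")
        elif df["subject_id"].nunique() > 1:
            raise DataError(f"{path} holds several subjects; pass subject_id")
        df = df.sort_values("vertex_index")
        idx = df["vertex_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise DataError(f"vertex indices in {path} are not a dense 0-based range")
        values = df["value"].to_numpy(dtype=float)
    elif ext in (".shape.gii", ".func.gii", ".gii"):
        import nibabel as nib

        img = nib.load(str(path))
        values = np.asarray(img.darrays[0].data, dtype=float)
    else:
        raise DataError(f"unrecognized scalar-map extension {ext!r} for {path}")
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        head = ", ".join(map(str, bad[:10]))
        raise DataError(f"scalar map {path} has non-finite values at vertices [{head}"
                        f"{'...' if bad.size > 10 else ''}]")
    return values


def write_scalar_map(values: np.ndarray, path, subject_id: str = "subject") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(values, dtype=float)
    ext = _ext(path)
    if ext == ".csv":
        pd.DataFrame({
            "subject_id": subject_id,
            "vertex_index": np.arange(len(values)),
            "value": values,
        }).to_csv(path, index=False, float_format="%.10g")
    elif ext in (".shape.gii", ".func.gii", ".gii"):
        import nibabel as nib

        da = nib.gifti.GiftiDataArray(values.astype(np.float32),
                                      intent="NIFTI_INTENT_SHAPE")
        nib.save(nib.gifti.GiftiImage(darrays=[da]), str(path))
    else:
        raise DataError(f"unrecognized scalar-map extension {ext!r} for {path}")


def read_covariates(path) -> pd.DataFrame:
    """Load and schema-check the per-subject covariate table."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"covariate file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"covariate table {path} is missing columns: {', '.join(missing)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise DataError(f"duplicate subject ids in {path}: {dups}")
    bad_group = set(df["group"].unique()) - {"INPH", "control"}
    if bad_group:
        raise DataError(f"unknown group labels in {path}: {sorted(bad_group)}")
    for col in ("age", "icv_mm3", "kmmse"):
        if df[col].isna().any():
            rows = df.index[df[col].isna()].tolist()
            raise DataError(f"missing {col!r} values in {path} at rows {rows}")
    return df


def write_covariates(table: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in COVARIATE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, float_format="%.10g")


def write_coefficients(coeffs, path) -> None:
    """Serialize spherical-harmonic coefficients as CSV (coordinate, l, m, value)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for j, coord in enumerate("xyz"):
        for l in range(coeffs.l_max + 1):
            for m in range(-l, l + 1):
                rows.append({"coordinate": coord, "l": l, "m": m,
                             "value": coeffs.coeffs[l * l + l + m, j]})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_coefficients(path):
    from .spharm import SpharmCoefficients

    df = pd.read_csv(Path(path))
    for col in ("coordinate", "l", "m", "value"):
        if col not in df.columns:
            raise DataError(f"coefficient file {path} is missing column {col!r}")
    l_max = int(df["l"].max())
    coeffs = np.zeros(((l_max + 1) ** 2, 3))
    col_of = {"x": 0, "y": 1, "z": 2}
    for _, row in df.iterrows():
        coeffs[int(row.l) ** 2 + int(row.l) + int(row.m), col_of[row.coordinate]] = row.value
    return SpharmCoefficients(coeffs=coeffs, l_max=l_max)


def write_transform(transform, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, transform.as_matrix(), fmt="%.12g")


def read_transform(path):
    from .align import RigidTransform

    m = np.loadtxt(Path(path))
    if m.shape != (4, 4):
        raise DataError(f"transform file {path} is not a 4x4 matrix")
    return RigidTransform(m[:3, :3], m[:3, 3])
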