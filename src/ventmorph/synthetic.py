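"""Synthetic INPH / control cohort generator.

Emulates the study inputs end-to-end: per-subject left/right lateral
ventricle surfaces, per-vertex cortical-thickness maps already in vertex
correspondence, and a covariate table (group, age, sex, ICV, K-MMSE).

A single latent, positive "severity" factor s_i drives both regional
ventricular surface expansion (superior body, medial frontal horn,
temporal horn) and regional cortical thinning (orbitofrontal, rostral
anterior cingulate, parahippocampal, temporal pole, insula, inferior
temporal, fusiform), so the correlated structure that sparse CCA is meant
to detect exists by construction and is recoverable.  Controls have
s_i = 0 and differ from the base anatomy only by measurement noise and a
head-size (ICV-coupled) global scale.

Geometry is parametric: an icosphere deformed into a bent ellipsoid stands
in for the ventricle, a larger ellipsoid per hemisphere for the cortex;
zones are spherical-cap patches in the parameter domain, not anatomical
atlases.  The pipeline's statistics are geometry-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._errors import ConfigError
from .mesh import SurfaceMesh, icosphere

__all__ = [
    "CohortConfig",
    "ZoneLabels",
    "Cohort",
    "base_ventricle_shape",
    "base_cortex_shape",
    "apply_expansion",
    "generate_thickness",
    "generate_cohort",
    "transfer_labels",
    "VENTRICLE_EXPANSION_ZONES",
    "CORTICAL_THINNING_ZONES",
]

VENTRICLE_EXPANSION_ZONES = ("superior_body", "frontal_horn_medial", "temporal_horn")
VENTRICLE_ZONES = VENTRICLE_EXPANSION_ZONES + ("inferior_body",)
CORTICAL_THINNING_ZONES = (
    "orbitofrontal",
    "rostral_ACC",
    "parahippocampal",
    "temporal_pole",
    "insula",
    "inferior_temporal",
    "fusiform",
)

# spherical-cap zone definitions in the parameter domain: name -> (center, angle)
_VENTRICLE_ZONE_DEFS = {
    "frontal_horn_medial": ((0.92, 0.30, 0.25), 0.90),
    "temporal_horn": ((-0.92, 0.00, -0.35), 0.90),
    "superior_body": ((0.0, 0.0, 1.0), 1.30),
    "inferior_body": ((0.0, 0.0, -1.0), 0.55),
}
# priority order for label assignment (caps may overlap slightly)
_VENTRICLE_ZONE_ORDER = ("frontal_horn_medial", "temporal_horn", "superior_body", "inferior_body")

_CORTEX_ZONE_DEFS = {
    "left": {
        "orbitofrontal": ((0.85, 0.15, -0.50), 0.40),
        "rostral_ACC": ((0.65, 0.55, 0.50), 0.40),
        "parahippocampal": ((-0.30, 0.55, -0.75), 0.40),
        "temporal_pole": ((0.25, -0.75, -0.60), 0.40),
    },
    "right": {
        "orbitofrontal": ((0.85, 0.15, -0.50), 0.40),
        "rostral_ACC": ((0.65, 0.55, 0.50), 0.40),
        "insula": ((0.10, -0.90, 0.10), 0.40),
        "inferior_temporal": ((-0.20, -0.75, -0.62), 0.40),
        "fusiform": ((-0.80, -0.15, -0.55), 0.40),
    },
}

# calibrated defaults (see docs/methods.md): chosen so cohort-mean total
# ventricle volumes and mean cortical thickness land near the target
# population values for a 33 + 23 cohort.
DEFAULT_BASE_SCALE = 1.1983
DEFAULT_EXPANSION_AMPLITUDE = 21.8   # mm outward per unit severity at zone centers
DEFAULT_THINNING_AMPLITUDE = 1.2     # mm thinning per unit severity at zone centers
_ICV_REF_CM3 = 1078.5                # control-population mean ICV


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class ZoneLabels:
    """Per-vertex zone labels plus the parametric geometry that defines them.

    ``labels`` holds one zone name (or ``"other"``) per vertex;
    ``directions`` are the unit parameter-sphere directions the caps are
    evaluated on, so smooth per-zone bump fields can be reconstructed for
    any subset of zones.
    """

    labels: np.ndarray
    directions: np.ndarray
    zone_defs: dict

    def mask(self, zones) -> np.ndarray:
        zones = [zones] if isinstance(zones, str) else list(zones)
        return np.isin(self.labels, zones)

    def zone_bump(self, zone: str) -> np.ndarray:
        """cos^2 bump: 1 at the zone center, 0 at (and outside) the cap edge."""
        center, angle = self.zone_defs[zone]
        ang = np.arccos(np.clip(self.directions @ _unit(center), -1.0, 1.0))
        t = np.clip(ang / angle, 0.0, 1.0)
        return np.cos(0.5 * np.pi * t) ** 2

    def bump_field(self, zones) -> np.ndarray:
        """Pointwise maximum of the per-zone bumps; support = union of caps."""
        zones = [zones] if isinstance(zones, str) else list(zones)
        return np.max(np.stack([self.zone_bump(z) for z in zones]), axis=0)

    def core_mask(self, zones, threshold: float = 0.8) -> np.ndarray:
        """Vertices where the bump field is close to its peak."""
        return self.bump_field(zones) >= threshold


def _assign_labels(directions: np.ndarray, zone_defs: dict, order) -> np.ndarray:
    labels = np.full(len(directions), "other", dtype=object)
    unassigned = np.ones(len(directions), dtype=bool)
    for name in order:
        center, angle = zone_defs[name]
        ang = np.arccos(np.clip(directions @ _unit(center), -1.0, 1.0))
        sel = unassigned & (ang <= angle)
        labels[sel] = name
        unassigned &= ~sel
    return labels.astype(str)


# ----------------------------------------------------------------------
# base geometry
# ----------------------------------------------------------------------

def base_ventricle_shape(
    resolution: int,
    side: str = "left",
    axes: tuple[float, float, float] = (30.0, 10.0, 7.5),
    bend_amplitude: float = 8.0,
) -> tuple[SurfaceMesh, ZoneLabels]:
    """Parametric stand-in for a lateral-ventricle surface.

    An icosphere is stretched to an elongated ellipsoid (semi-axes ``axes``
    in mm, long axis x) and bent by a smooth vertical shear
    z += bend * (x/a)^2 mimicking the ventricular arc; the shear has unit
    Jacobian so the enclosed volume stays exactly the ellipsoid volume.
    The right side is the mirror image (x -> -x) of the left.
    """
    if resolution < 2:
        raise ConfigError("mesh resolution must be >= 2 (>= 162 vertices)")
    if side not in ("left", "right"):
        raise ConfigError(f"side must be 'left' or 'right', got {side!r}")
    sphere = icosphere(resolution)
    u = np.asarray(sphere.vertices, dtype=float)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    a, b, c = axes
    verts = np.column_stack([a * u[:, 0], b * u[:, 1], c * u[:, 2]])
    verts[:, 2] += bend_amplitude * (verts[:, 0] / a) ** 2
    faces = np.asarray(sphere.faces, dtype=np.int64)
    directions = u
    zone_defs = dict(_VENTRICLE_ZONE_DEFS)
    if side == "right":
        verts = verts * np.array([-1.0, 1.0, 1.0])
        faces = faces[:, [0, 2, 1]]
        directions = directions * np.array([-1.0, 1.0, 1.0])
        zone_defs = {
            name: (tuple(np.array(ctr) * np.array([-1.0, 1.0, 1.0])), ang)
            for name, (ctr, ang) in zone_defs.items()
        }
    labels = _assign_labels(directions, zone_defs, _VENTRICLE_ZONE_ORDER)
    mesh = SurfaceMesh(verts, faces, metadata={"side": side, "structure": "ventricle"})
    return mesh, ZoneLabels(labels=labels, directions=directions, zone_defs=zone_defs)


def base_cortex_shape(
    resolution: int,
    hemisphere: str = "left",
    axes: tuple[float, float, float] = (65.0, 80.0, 60.0),
) -> tuple[SurfaceMesh, ZoneLabels]:
    """Parametric cortical hemisphere surface with the seven thinning zones."""
    if resolution < 2:
        raise ConfigError("cortex resolution must be >= 2")
    if hemisphere not in ("left", "right"):
        raise ConfigError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")
    sphere = icosphere(resolution)
    u = np.asarray(sphere.vertices, dtype=float)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    a, b, c = axes
    verts = np.column_stack([a * u[:, 0], b * u[:, 1], c * u[:, 2]])
    faces = np.asarray(sphere.faces, dtype=np.int64)
    zone_defs = {k: (tuple(v[0]), v[1]) for k, v in _CORTEX_ZONE_DEFS[hemisphere].items()}
    labels = _assign_labels(u, zone_defs, list(zone_defs))
    mesh = SurfaceMesh(verts, faces, metadata={"hemisphere": hemisphere, "structure": "cortex"})
    return mesh, ZoneLabels(labels=labels, directions=u, zone_defs=zone_defs)


# ----------------------------------------------------------------------
# severity effects
# ----------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def apply_expansion(
    mesh: SurfaceMesh,
    labels: ZoneLabels,
    severity: float,
    amplitude: float = DEFAULT_EXPANSION_AMPLITUDE,
    noise_sd: float = 0.0,
    seed=0,
) -> SurfaceMesh:
    """Displace vertices outward along their normals by severity-scaled bumps.

    displacement(v) = severity * amplitude * A(v) + N(0, noise_sd), where
    A is the smooth bump field over the three expansion zones (1 at zone
    centers, 0 outside the zones, in particular 0 on the inferior body).
    With ``noise_sd = 0`` the enclosed volume is strictly increasing in
    severity.
    """
    if severity < 0:
        raise ConfigError("severity must be nonnegative")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    if severity == 0 and noise_sd == 0:
        return mesh.copy()
    bump = labels.bump_field(VENTRICLE_EXPANSION_ZONES)
    d = severity * amplitude * bump
    if noise_sd > 0:
        d = d + _as_rng(seed).normal(0.0, noise_sd, size=mesh.n_vertices)
    verts = mesh.vertices + d[:, None] * mesh.vertex_normals()
    return SurfaceMesh(verts, mesh.faces.copy(), dict(mesh.metadata))


def generate_thickness(
    cortex_mesh: SurfaceMesh,
    labels: ZoneLabels,
    severity: float,
    thinning_amplitude: float = DEFAULT_THINNING_AMPLITUDE,
    noise_sd: float = 0.0,
    seed=0,
    baseline=2.9,
) -> np.ndarray:
    """Per-vertex cortical thickness (mm) under severity-scaled zonal thinning.

    T(v) = T0(v) - severity * amplitude * B(v) + N(0, noise_sd), clipped
    below at 0.5 mm.  B is supported exactly on the seven named zones, so
    zone-exterior vertices keep their baseline value when noise_sd = 0.
    """
    if severity < 0:
        raise ConfigError("severity must be nonnegative")
    t0 = np.broadcast_to(np.asarray(baseline, dtype=float), (cortex_mesh.n_vertices,)).copy()
    if t0.min() < 1.5 or t0.max() > 4.5:
        raise ConfigError("baseline thickness must lie in [1.5, 4.5] mm")
    zones = [z for z in CORTICAL_THINNING_ZONES if z in labels.zone_defs]
    t = t0 - severity * thinning_amplitude * labels.bump_field(zones)
    if noise_sd > 0:
        t = t + _as_rng(seed).normal(0.0, noise_sd, size=t.size)
    return np.clip(t, 0.5, None)


# ----------------------------------------------------------------------
# cohort generation
# ----------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Demographic defaults follow the target population: INPH n=33 aged
    73.5 +- 5.0 y, 21/33 male, ICV 1151.5 +- 135.1 cm^3, K-MMSE 19.9 +- 6.9;
    controls n=23 aged 70.9 +- 4.3 y, 9/23 male, ICV 1078.5 +- 95.2 cm^3,
    K-MMSE 27.1 +- 2.4.  Severity is truncated-normal(1.0, 0.35) > 0 for
    INPH and exactly 0 for controls; head size couples to ventricle scale
    through (ICV / reference ICV)^(1/3) so the ICV adjustment in the
    downstream ANCOVA is non-trivial.
    """

    n_inph: int = 33
    n_control: int = 23
    seed: int = 0
    severity_mean: float = 1.0
    severity_sd: float = 0.35
    expansion_amplitude: float = DEFAULT_EXPANSION_AMPLITUDE
    thinning_amplitude: float = DEFAULT_THINNING_AMPLITUDE
    noise_sd_shape: float = 0.4
    noise_sd_thickness: float = 0.25
    mesh_resolution: int = 3
    cortex_resolution: int = 4
    base_scale: float = DEFAULT_BASE_SCALE
    baseline_thickness: float = 2.9
    age_mean: dict = field(default_factory=lambda: {"INPH": 73.5, "control": 70.9})
    age_sd: dict = field(default_factory=lambda: {"INPH": 5.0, "control": 4.3})
    icv_mean_cm3: dict = field(default_factory=lambda: {"INPH": 1151.5, "control": 1078.5})
    icv_sd_cm3: dict = field(default_factory=lambda: {"INPH": 135.1, "control": 95.2})
    kmmse_mean: dict = field(default_factory=lambda: {"INPH": 19.9, "control": 27.1})
    kmmse_sd: dict = field(default_factory=lambda: {"INPH": 6.9, "control": 2.4})
    male_fraction: dict = field(default_factory=lambda: {"INPH": 21 / 33, "control": 9 / 23})

    def validate(self) -> None:
        if self.n_inph < 3 or self.n_control < 3:
            raise ConfigError("need at least 3 subjects per group")
        sds = [self.severity_sd, self.noise_sd_shape, self.noise_sd_thickness,
               *self.age_sd.values(), *self.icv_sd_cm3.values(), *self.kmmse_sd.values()]
        if any(s < 0 for s in sds):
            raise ConfigError("standard deviations must be nonnegative")
        if self.mesh_resolution < 2 or self.cortex_resolution < 2:
            raise ConfigError("mesh resolutions must be >= 2")
        if self.severity_mean <= 0:
            raise ConfigError("severity_mean must be positive")
        n = max(self.n_inph, self.n_control)
        if n > 1 and all(s == 0 for s in sds):
            warnings.warn("all spread parameters are zero: subjects will be duplicates")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    """Generated cohort: covariate table, surfaces, thickness maps, labels."""

    table: pd.DataFrame
    ventricles: dict            # subject_id -> {"left": SurfaceMesh, "right": SurfaceMesh}
    thickness: dict             # subject_id -> (V_left + V_right,) thickness array
    ventricle_labels: dict      # side -> ZoneLabels
    cortex_labels: dict         # hemisphere -> ZoneLabels
    cortex_meshes: dict         # hemisphere -> SurfaceMesh
    config: CohortConfig

    @property
    def subject_ids(self) -> list:
        return list(self.table["subject_id"])

    def group_ids(self, group: str) -> list:
        return list(self.table.loc[self.table["group"] == group, "subject_id"])

    def thickness_matrix(self, subject_ids=None) -> np.ndarray:
        ids = subject_ids if subject_ids is not None else self.subject_ids
        return np.stack([self.thickness[s] for s in ids])

    def ventricle_volumes(self) -> pd.DataFrame:
        from .align import mesh_volume

        rows = []
        for sid in self.subject_ids:
            lv = mesh_volume(self.ventricles[sid]["left"])
            rv = mesh_volume(self.ventricles[sid]["right"])
            rows.append({"subject_id": sid, "left_mm3": lv, "right_mm3": rv,
                         "total_mm3": lv + rv})
        return pd.DataFrame(rows)


def _truncated_positive_normal(rng, mean, sd, size):
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise ConfigError("severity distribution produces non-positive draws too often")


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw a full synthetic cohort; bit-reproducible given the config seed."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    vent, vent_lab, cortex, cortex_lab = {}, {}, {}, {}
    for side in ("left", "right"):
        m, lab = base_ventricle_shape(config.mesh_resolution, side)
        vent[side], vent_lab[side] = m, lab
        cm, clab = base_cortex_shape(config.cortex_resolution, side)
        cortex[side], cortex_lab[side] = cm, clab

    rows, ventricles, thickness = [], {}, {}
    for group, n, prefix in (("INPH", config.n_inph, "INPH"), ("control", config.n_control, "CTRL")):
        if config.severity_sd > 0 and group == "INPH":
            sev = _truncated_positive_normal(rng, config.severity_mean, config.severity_sd, n)
        elif group == "INPH":
            sev = np.full(n, config.severity_mean)
        else:
            sev = np.zeros(n)
        age = rng.normal(config.age_mean[group], config.age_sd[group], size=n)
        icv_cm3 = rng.normal(config.icv_mean_cm3[group], config.icv_sd_cm3[group], size=n)
        icv_cm3 = np.clip(icv_cm3, 500.0, None)
        male = rng.random(n) < config.male_fraction[group]
        kmmse = np.clip(rng.normal(config.kmmse_mean[group], config.kmmse_sd[group], size=n), 0, 30)
        evans = rng.normal(0.32 if group == "INPH" else 0.28, 0.01, size=n)
        for i in range(n):
            sid = f"{prefix}{i + 1:03d}"
            scale = config.base_scale * (icv_cm3[i] / _ICV_REF_CM3) ** (1.0 / 3.0)
            sides = {}
            for side in ("left", "right"):
                base = vent[side]
                scaled = SurfaceMesh(base.vertices * scale, base.faces.copy(), dict(base.metadata))
                sides[side] = apply_expansion(
                    scaled, vent_lab[side], float(sev[i]),
                    amplitude=config.expansion_amplitude,
                    noise_sd=config.noise_sd_shape, seed=rng,
                )
            ventricles[sid] = sides
            tmap = [
                generate_thickness(
                    cortex[h], cortex_lab[h], float(sev[i]),
                    thinning_amplitude=config.thinning_amplitude,
                    noise_sd=config.noise_sd_thickness, seed=rng,
                    baseline=config.baseline_thickness,
                )
                for h in ("left", "right")
            ]
            thickness[sid] = np.concatenate(tmap)
            rows.append({
                "subject_id": sid, "group": group, "age": float(age[i]),
                "sex": "M" if male[i] else "F", "icv_mm3": float(icv_cm3[i] * 1000.0),
                "kmmse": float(kmmse[i]), "severity": float(sev[i]),
                "evans_ratio": float(evans[i]),
            })

    table = pd.DataFrame(rows)
    return Cohort(table=table, ventricles=ventricles, thickness=thickness,
                  ventricle_labels=vent_lab, cortex_labels=cortex_lab,
                  cortex_meshes=cortex, config=config)


def transfer_labels(template_vertices: np.ndarray, source_mesh: SurfaceMesh,
                    labels: ZoneLabels) -> np.ndarray:
    """Nearest-neighbour transfer of zone labels onto a resampled template."""
    tree = cKDTree(source_mesh.vertices)
    _, idx = tree.query(np.asarray(template_vertices, dtype=float))
    return labels.labels[idx]


def common_frame_expansion(cohort: Cohort) -> dict:
    """Expansion maps computed in the generator's shared construction frame.

    All generated surfaces live in one coordinate frame, so the control
    average shape can be formed directly and the subject-vs-mean distances
    carry no rigid-alignment residue; head-size scale differences are left
    to the downstream ANCOVA ICV covariate.  This is the ground-truth
    reference for planted-signal recovery; the Procrustes path in
    :mod:`ventmorph.align` is the choice for data in arbitrary frames.

    Returns ``{side: (n_subjects, V) array}`` with rows in cohort order.
    """
    from .align import expansion_map
    from .mesh import CorrespondedSurface

    level = cohort.config.mesh_resolution
    out = {}
    for side in ("left", "right"):
        stack = {sid: cohort.ventricles[sid][side].vertices
                 for sid in cohort.subject_ids}
        mean = CorrespondedSurface(
            np.mean([stack[s] for s in cohort.group_ids("control")], axis=0),
            level=level, subject_id="control_mean", side=side)
        maps = []
        for sid in cohort.subject_ids:
            surf = CorrespondedSurface(stack[sid].copy(), level=level,
                                       subject_id=sid, side=side)
            surf.aligned = True  # shared frame by construction
            maps.append(expansion_map(surf, mean).values)
        out[side] = np.stack(maps)
    return out
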