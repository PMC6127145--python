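"""End-to-end orchestration: generate -> correspond -> align -> score -> stats -> SCCA.

`run_pipeline` executes the enabled stages in dependency order on either a
synthetic cohort (the default) or user-supplied files, optionally writing
every intermediate in standard formats plus a JSON manifest that records
the configuration and seed needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigError, DataError
from .align import align_to, expansion_map, group_mean_shape, mesh_volume
from .mesh import CorrespondedSurface, icosphere_vertex_count
from .scca import PermutationResult, SccaConfig, SccaResult, permutation_test, scca_fit
from .spharm import correspond
from .stats import demographic_tests, vertexwise_ancova, volume_ancova
from .synthetic import CohortConfig, generate_cohort, transfer_labels
from .wscore import fit_control_model, wscore_matrix
from . import io as vio

logger = logging.getLogger("ventmorph")

ALL_STAGES = ("generate", "correspond", "align", "wscore", "stats", "scca")


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None        # read cohort from files instead of generating
    stages: tuple = ALL_STAGES
    seed: int = 0
    outdir: str | None = None
    # correspondence
    use_spharm: bool = True
    spharm_l_max: int = 10
    sampling_level: int | None = None   # default: the generator mesh resolution
    # statistics
    alpha_family: float = 0.01
    covariates: tuple = ("age", "icv_mm3")
    # SCCA
    scca: SccaConfig = field(default_factory=SccaConfig)
    scca_input: str = "raw"             # 'raw' or 'wscore'
    thickness_sign: float = -1.0        # negate thickness so positive weights mark thinning
    thickness_fwhm: float = 30.0        # surface smoothing of thickness maps (mm)
    n_permutations: int = 2000

    def __post_init__(self):
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        if self.scca_input not in ("raw", "wscore"):
            raise ConfigError("scca_input must be 'raw' or 'wscore'")
        if self.input_dir is not None and "generate" in self.stages:
            raise ConfigError("exactly one input source: drop 'generate' when input_dir is set")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


@dataclass
class ResultsBundle:
    """Everything a run produced, plus the manifest to reproduce it."""

    cohort_table: pd.DataFrame | None = None
    volumes: pd.DataFrame | None = None
    demographics: object = None
    corresponded: dict | None = None          # side -> {sid: CorrespondedSurface}
    mean_shapes: dict | None = None           # side -> CorrespondedSurface
    expansion: dict | None = None             # side -> DataFrame (subjects x V)
    template_labels: dict | None = None       # side -> per-vertex zone labels
    wscore_maps: dict | None = None           # side -> DataFrame (INPH subjects x V)
    volume_tests: dict | None = None          # ANCOVA results per volume measure
    vertexwise: dict | None = None            # side -> VertexStatResult
    scca_result: SccaResult | None = None
    scca_permutation: PermutationResult | None = None
    manifest: dict = field(default_factory=dict)


def _load_cohort_from_files(cfg: RunConfig):
    base = Path(cfg.input_dir)
    table = vio.read_covariates(base / "covariates.csv")
    meshes, thickness = {}, {}
    for sid in table["subject_id"]:
        sides = {}
        for side in ("left", "right"):
            p = base / f"{sid}_{side}.obj"
            if not p.exists():
                raise DataError(f"missing ventricle surface {p}")
            sides[side] = vio.read_surface(p)
        meshes[sid] = sides
        tpath = base / f"{sid}_thickness.csv"
        if tpath.exists():
            thickness[sid] = vio.read_scalar_map(tpath, subject_id=sid)
    return table, meshes, thickness


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Run the enabled stages; returns a ResultsBundle (and writes outdir)."""
    t0 = time.time()
    bundle = ResultsBundle()
    timings = {}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    cohort = None
    table = None
    meshes = None
    thickness = None

    # ---------------- generate / load ----------------
    if "generate" in config.stages:
        tic = time.time()
        cc = dataclasses.replace(config.cohort, seed=config.seed)
        cohort = generate_cohort(cc)
        table = cohort.table
        meshes = cohort.ventricles
        thickness = cohort.thickness
        timings["generate"] = time.time() - tic
        if outdir:
            vio.write_covariates(table, outdir / "covariates.csv")
    elif config.input_dir is not None:
        table, meshes, thickness = _load_cohort_from_files(config)
    else:
        raise DataError("pipeline needs either the 'generate' stage or input_dir")
    bundle.cohort_table = table

    downstream = [s for s in config.stages if s != "generate"]
    if not downstream:
        bundle.manifest = _manifest(config, timings, t0)
        _write_manifest(bundle, outdir)
        return bundle

    inph_ids = list(table.loc[table["group"] == "INPH", "subject_id"])
    ctrl_ids = list(table.loc[table["group"] == "control", "subject_id"])

    # ---------------- correspond ----------------
    if "correspond" in config.stages:
        tic = time.time()
        level = config.sampling_level
        corresponded = {"left": {}, "right": {}}
        for side in ("left", "right"):
            for sid, sides in meshes.items():
                mesh = sides[side]
                if config.use_spharm:
                    lv = level or _level_for(mesh.n_vertices)
                    corresponded[side][sid] = correspond(
                        mesh, l_max=config.spharm_l_max, level=lv,
                        subject_id=sid, side=side)
                else:
                    lv = _level_for(mesh.n_vertices)
                    corresponded[side][sid] = CorrespondedSurface(
                        mesh.vertices.copy(), level=lv, subject_id=sid, side=side)
        bundle.corresponded = corresponded
        timings["correspond"] = time.time() - tic
    else:
        corresponded = None

    # ---------------- align + expansion ----------------
    if "align" in config.stages:
        if corresponded is None:
            raise DataError("stage 'align' requires stage 'correspond' in the same run")
        tic = time.time()
        bundle.mean_shapes, bundle.expansion, bundle.template_labels = {}, {}, {}
        for side in ("left", "right"):
            ctrl_surfs = [corresponded[side][sid] for sid in ctrl_ids]
            mean = group_mean_shape(ctrl_surfs)
            rows = {}
            for sid in table["subject_id"]:
                aligned = align_to(corresponded[side][sid], mean)
                rows[sid] = expansion_map(aligned, mean).values
            bundle.mean_shapes[side] = mean
            bundle.expansion[side] = pd.DataFrame.from_dict(rows, orient="index")
            if cohort is not None:
                bundle.template_labels[side] = _template_labels(
                    cohort, side, config, mean.level)
        vols = []
        for sid, sides in meshes.items():
            lv = mesh_volume(sides["left"])
            rv = mesh_volume(sides["right"])
            vols.append({"subject_id": sid, "left_mm3": lv, "right_mm3": rv,
                         "total_mm3": lv + rv})
        bundle.volumes = pd.DataFrame(vols).set_index("subject_id").loc[
            table["subject_id"]].reset_index()
        timings["align"] = time.time() - tic
        if outdir:
            bundle.volumes.to_csv(outdir / "volumes.csv", index=False)
            for side in ("left", "right"):
                bundle.expansion[side].to_csv(outdir / f"expansion_{side}.csv")

    # ---------------- W-scores ----------------
    if "wscore" in config.stages:
        if bundle.expansion is None:
            raise DataError("stage 'wscore' requires stage 'align' in the same run")
        tic = time.time()
        bundle.wscore_maps = {}
        ctrl_tab = table[table["group"] == "control"].reset_index(drop=True)
        inph_tab = table[table["group"] == "INPH"].reset_index(drop=True)
        for side in ("left", "right"):
            exp = bundle.expansion[side]
            model = fit_control_model(exp.loc[ctrl_ids].to_numpy(), ctrl_tab,
                                      covariate_names=config.covariates)
            w = wscore_matrix(exp.loc[inph_ids].to_numpy(), inph_tab, model)
            bundle.wscore_maps[side] = pd.DataFrame(w, index=inph_ids)
        timings["wscore"] = time.time() - tic
        if outdir:
            for side in ("left", "right"):
                bundle.wscore_maps[side].to_csv(outdir / f"wscore_{side}.csv")

    # ---------------- statistics ----------------
    if "stats" in config.stages:
        if bundle.expansion is None:
            raise DataError("stage 'stats' requires stage 'align' in the same run")
        tic = time.time()
        bundle.demographics = demographic_tests(
            table, ["sex", "age", "kmmse"],
            test_map={"sex": "chi2", "age": "welch_t", "kmmse": "welch_t"})
        if bundle.volumes is not None:
            vols = bundle.volumes
            bundle.volume_tests = {
                col: volume_ancova(vols[f"{col}_mm3"].to_numpy(), table,
                                   covariates=config.covariates)
                for col in ("left", "right", "total")
            }
            # head size itself is compared adjusting for age only
            bundle.volume_tests["icv"] = volume_ancova(
                table["icv_mm3"].to_numpy(), table, covariates=("age",))
        n_family = sum(bundle.expansion[s].shape[1] for s in ("left", "right"))
        bundle.vertexwise = {}
        for side in ("left", "right"):
            bundle.vertexwise[side] = vertexwise_ancova(
                bundle.expansion[side].loc[table["subject_id"]].to_numpy(), table,
                covariates=config.covariates, alpha_family=config.alpha_family,
                n_tests=n_family)
        timings["stats"] = time.time() - tic
        if outdir:
            bundle.demographics.to_frame().to_csv(outdir / "demographics.csv", index=False)
            for side in ("left", "right"):
                bundle.vertexwise[side].to_frame().to_csv(
                    outdir / f"vertexwise_{side}.csv", index=False)

    # ---------------- SCCA ----------------
    if "scca" in config.stages:
        if bundle.expansion is None:
            raise DataError("stage 'scca' requires stage 'align' in the same run")
        if thickness is None or not thickness:
            raise DataError("SCCA requires per-subject thickness maps")
        tic = time.time()
        if config.scca_input == "wscore":
            if bundle.wscore_maps is None:
                raise DataError("scca_input='wscore' requires stage 'wscore'")
            x = np.hstack([bundle.wscore_maps[s].loc[inph_ids].to_numpy()
                           for s in ("left", "right")])
        else:
            x = np.hstack([bundle.expansion[s].loc[inph_ids].to_numpy()
                           for s in ("left", "right")])
        y_raw = np.stack([thickness[sid] for sid in inph_ids])
        if cohort is not None and config.thickness_fwhm > 0:
            from .stats import smooth_surface_scalar

            n_left = cohort.cortex_meshes["left"].n_vertices
            y_raw = np.stack([
                np.concatenate([
                    smooth_surface_scalar(row[:n_left], cohort.cortex_meshes["left"],
                                          config.thickness_fwhm),
                    smooth_surface_scalar(row[n_left:], cohort.cortex_meshes["right"],
                                          config.thickness_fwhm),
                ])
                for row in y_raw
            ])
        y = config.thickness_sign * y_raw
        bundle.scca_result = scca_fit(x, y, config.scca)
        bundle.scca_permutation = permutation_test(
            x, y, config.scca, n_permutations=config.n_permutations,
            seed=config.seed + 1)
        timings["scca"] = time.time() - tic
        if outdir:
            np.savetxt(outdir / "scca_u.csv", bundle.scca_result.u, fmt="%.10g")
            np.savetxt(outdir / "scca_v.csv", bundle.scca_result.v, fmt="%.10g")
            np.savetxt(outdir / "scca_permuted_r.csv",
                       bundle.scca_permutation.permuted_r, fmt="%.10g")

    bundle.manifest = _manifest(config, timings, t0)
    _write_manifest(bundle, outdir)
    return bundle


def _level_for(n_vertices: int) -> int:
    level = int(round(np.log((n_vertices - 2) / 10) / np.log(4)))
    if icosphere_vertex_count(level) != n_vertices:
        raise DataError(
            f"{n_vertices} vertices is not an icosahedral sampling; "
            "native correspondence requires icosphere topology")
    return level


def _template_labels(cohort, side, config: RunConfig, level: int) -> np.ndarray:
    """Zone labels on the corresponded template.

    Correspondence is parametric, so the labels of template vertices are
    read off the base anatomy: the base shape is run through the same
    correspondence as the subjects and each resampled vertex inherits the
    label of the nearest base-mesh vertex.  In native mode the template
    preserves the base vertex order and labels transfer by index.
    """
    from .synthetic import base_ventricle_shape

    base, labels = base_ventricle_shape(cohort.config.mesh_resolution, side)
    if not config.use_spharm:
        return labels.labels.copy()
    base_corr = correspond(base, l_max=config.spharm_l_max, level=level, side=side)
    return transfer_labels(base_corr.vertices, base, labels)


def _manifest(config: RunConfig, timings: dict, t0: float) -> dict:
    from . import __version__

    return {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages_run": list(timings),
        "skipped_stages": [s for s in ALL_STAGES if s not in timings and s not in config.stages],
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "elapsed_s": round(time.time() - t0, 3),
        "version": __version__,
    }


def _write_manifest(bundle: ResultsBundle, outdir) -> None:
    if outdir:
        with open(Path(outdir) / "manifest.json", "w") as fh:
            json.dump(bundle.manifest, fh, indent=2, default=str)
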