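"""Tests of the synthetic cohort generator and its planted ground truth."""

import numpy as np
import pytest
from scipy import sparse

from ventmorph import (
    CohortConfig,
    ConfigError,
    apply_expansion,
    base_cortex_shape,
    base_ventricle_shape,
    generate_cohort,
    generate_thickness,
    mesh_volume,
)
from ventmorph.synthetic import (
    CORTICAL_THINNING_ZONES,
    VENTRICLE_EXPANSION_ZONES,
    VENTRICLE_ZONES,
)


class TestBaseShapes:
    def test_icosphere_combinatorics(self):
        mesh, _ = base_ventricle_shape(3, "left")
        assert mesh.n_vertices == 642
        assert mesh.n_faces == 1280
        assert mesh.euler_characteristic == 2
        assert mesh.is_closed()

    def test_unbent_ellipsoid_volume_matches_analytic(self):
        axes = (30.0, 10.0, 7.5)
        mesh, _ = base_ventricle_shape(4, "left", axes=axes, bend_amplitude=0.0)
        expected = 4.0 / 3.0 * np.pi * np.prod(axes)
        assert abs(mesh_volume(mesh) - expected) / expected < 0.02

    def test_bend_shear_preserves_volume(self):
        flat, _ = base_ventricle_shape(3, "left", bend_amplitude=0.0)
        bent, _ = base_ventricle_shape(3, "left", bend_amplitude=8.0)
        assert mesh_volume(bent) == pytest.approx(mesh_volume(flat), rel=1e-9)

    def test_right_side_is_mirror_of_left(self):
        left, llab = base_ventricle_shape(3, "left")
        right, rlab = base_ventricle_shape(3, "right")
        np.testing.assert_allclose(right.vertices, left.vertices * [-1, 1, 1])
        assert list(llab.labels) == list(rlab.labels)
        assert right.is_closed() and mesh_volume(right) > 0

    def test_resolution_below_two_rejected(self):
        with pytest.raises(ConfigError):
            base_ventricle_shape(1, "left")

    @pytest.mark.parametrize("builder,zones", [
        (lambda: base_ventricle_shape(3, "left"), VENTRICLE_ZONES),
        (lambda: base_cortex_shape(3, "left"), None),
        (lambda: base_cortex_shape(3, "right"), None),
    ])
    def test_zones_are_single_connected_patches(self, builder, zones):
        mesh, lab = builder()
        names = zones if zones is not None else tuple(lab.zone_defs)
        edges = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]],
                           mesh.faces[:, [2, 0]]])
        for name in names:
            sel = np.flatnonzero(lab.labels == name)
            assert sel.size > 0, name
            remap = -np.ones(mesh.n_vertices, dtype=int)
            remap[sel] = np.arange(sel.size)
            keep = (remap[edges[:, 0]] >= 0) & (remap[edges[:, 1]] >= 0)
            sub = edges[keep]
            adj = sparse.coo_matrix(
                (np.ones(len(sub)), (remap[sub[:, 0]], remap[sub[:, 1]])),
                shape=(sel.size, sel.size))
            n_comp, _ = sparse.csgraph.connected_components(adj, directed=False)
            assert n_comp == 1, f"zone {name} split into {n_comp} patches"

    def test_every_vertex_has_exactly_one_label(self):
        _, lab = base_ventricle_shape(2, "left")
        assert lab.labels.shape == lab.directions.shape[:1]
        assert set(lab.labels) <= set(VENTRICLE_ZONES) | {"other"}


class TestExpansion:
    def test_zero_severity_zero_noise_is_identity(self):
        mesh, lab = base_ventricle_shape(2, "left")
        out = apply_expansion(mesh, lab, 0.0, noise_sd=0.0)
        np.testing.assert_array_equal(out.vertices, mesh.vertices)

    def test_displacement_linear_in_severity(self):
        mesh, lab = base_ventricle_shape(2, "left")
        d1 = apply_expansion(mesh, lab, 1.0, amplitude=5.0, noise_sd=0.0).vertices - mesh.vertices
        d2 = apply_expansion(mesh, lab, 2.0, amplitude=5.0, noise_sd=0.0).vertices - mesh.vertices
        np.testing.assert_allclose(np.linalg.norm(d2, axis=1),
                                   2 * np.linalg.norm(d1, axis=1), atol=1e-12)

    def test_negative_severity_rejected(self):
        mesh, lab = base_ventricle_shape(2, "left")
        with pytest.raises(ConfigError):
            apply_expansion(mesh, lab, -0.5)

    def test_volume_strictly_increasing_in_severity(self):
        mesh, lab = base_ventricle_shape(3, "left")
        vols = [mesh_volume(apply_expansion(mesh, lab, s, noise_sd=0.0))
                for s in (0.0, 0.3, 0.8, 1.5)]
        assert np.all(np.diff(vols) > 0)

    def test_inferior_body_untouched_without_noise(self):
        mesh, lab = base_ventricle_shape(3, "left")
        out = apply_expansion(mesh, lab, 1.2, noise_sd=0.0)
        inf = lab.mask("inferior_body")
        np.testing.assert_allclose(out.vertices[inf], mesh.vertices[inf], atol=1e-12)


class TestThickness:
    def test_zero_severity_returns_baseline_exactly(self):
        mesh, lab = base_cortex_shape(2, "left")
        t = generate_thickness(mesh, lab, 0.0, noise_sd=0.0)
        np.testing.assert_array_equal(t, np.full(mesh.n_vertices, 2.9))

    def test_zone_exterior_keeps_baseline_at_any_severity(self):
        mesh, lab = base_cortex_shape(3, "left")
        outside = ~lab.mask(list(lab.zone_defs))
        for sev in (0.5, 2.0):
            t = generate_thickness(mesh, lab, sev, noise_sd=0.0)
            np.testing.assert_allclose(t[outside], 2.9, atol=1e-12)

    def test_thickness_clipped_below(self):
        mesh, lab = base_cortex_shape(2, "left")
        t = generate_thickness(mesh, lab, 50.0, thinning_amplitude=1.0, noise_sd=0.0)
        assert t.min() >= 0.5

    def test_baseline_out_of_band_rejected(self):
        mesh, lab = base_cortex_shape(2, "left")
        with pytest.raises(ConfigError):
            generate_thickness(mesh, lab, 0.0, baseline=5.2)

    def test_zone_mean_thickness_decreasing_in_severity(self):
        mesh, lab = base_cortex_shape(3, "left")
        zone = lab.mask(list(lab.zone_defs))
        means = [generate_thickness(mesh, lab, s, noise_sd=0.0)[zone].mean()
                 for s in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(means) < 0)


class TestCohort:
    def test_same_seed_reproduces_bit_identical_cohorts(self, small_cohort):
        cfg = small_cohort.config
        other = generate_cohort(CohortConfig(**{**cfg.to_dict()}))
        assert small_cohort.table.equals(other.table)
        for sid in small_cohort.subject_ids:
            for side in ("left", "right"):
                np.testing.assert_array_equal(
                    small_cohort.ventricles[sid][side].vertices,
                    other.ventricles[sid][side].vertices)
            np.testing.assert_array_equal(small_cohort.thickness[sid],
                                          other.thickness[sid])

    def test_empty_control_group_rejected(self):
        with pytest.raises(ConfigError):
            generate_cohort(CohortConfig(n_control=0))

    def test_male_counts_follow_group_frequencies(self):
        counts = {"INPH": [], "control": []}
        for seed in range(10):
            co = generate_cohort(CohortConfig(mesh_resolution=2,
                                              cortex_resolution=2, seed=seed))
            t = co.table
            for g in counts:
                counts[g].append(((t.group == g) & (t.sex == "M")).sum())
        # binomial means 21 (n=33, p=21/33) and 9 (n=23, p=9/23)
        assert abs(np.mean(counts["INPH"]) - 21) < 3
        assert abs(np.mean(counts["control"]) - 9) < 3

    def test_controls_have_zero_severity_and_valid_ranges(self, small_cohort):
        t = small_cohort.table
        assert (t.loc[t.group == "control", "severity"] == 0).all()
        assert (t.loc[t.group == "INPH", "severity"] > 0).all()
        assert (t.icv_mm3 > 0).all()
        assert t.kmmse.between(0, 30).all()

    def test_cohort_volume_means_match_study_targets(self):
        # average over a few cohorts: the claim concerns the generator's
        # expected volumes, not a single 33-subject draw
        inph, ctrl = [], []
        for seed in (0, 1, 2):
            co = generate_cohort(CohortConfig(seed=seed, cortex_resolution=2))
            g = co.ventricle_volumes().merge(co.table, on="subject_id") \
                .groupby("group")["total_mm3"].mean()
            inph.append(g["INPH"])
            ctrl.append(g["control"])
        assert abs(np.mean(inph) - 119128.9) / 119128.9 < 0.15
        assert abs(np.mean(ctrl) - 32360.1) / 32360.1 < 0.15

    def test_inph_mean_thickness_in_printed_band(self, default_cohort):
        th = default_cohort.thickness_matrix(default_cohort.group_ids("INPH"))
        assert 2.7 <= th.mean() <= 2.9

    def test_severity_correlates_with_planted_expansion_and_thinning(self, default_cohort):
        co = default_cohort
        inph = co.table[co.table.group == "INPH"]
        sev = inph.severity.to_numpy()
        base, lab = base_ventricle_shape(co.config.mesh_resolution, "left")
        zone = lab.mask(VENTRICLE_EXPANSION_ZONES)
        exp_means = []
        for sid, icv in zip(inph.subject_id, inph.icv_mm3):
            scale = co.config.base_scale * (icv / 1000.0 / 1078.5) ** (1 / 3)
            d = np.linalg.norm(co.ventricles[sid]["left"].vertices
                               - base.vertices * scale, axis=1)
            exp_means.append(d[zone].mean())
        assert np.corrcoef(sev, exp_means)[0, 1] > 0.8
        thin_mask = np.concatenate([
            co.cortex_labels[h].mask(list(co.cortex_labels[h].zone_defs))
            for h in ("left", "right")])
        thin_means = [(2.9 - co.thickness[sid][thin_mask]).mean()
                      for sid in inph.subject_id]
        assert np.corrcoef(sev, thin_means)[0, 1] > 0.8
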