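"""Synthetic-data generator: localization statistics and fixture ground truth."""

import numpy as np
import pandas as pd
import pytest

from telostorm.densitometry import mean_telomere_length, normalize_dot_blot
from telostorm.shape import cluster_anisotropy, radius_of_gyration
from telostorm.simulate import (
    AcquisitionParams,
    DotBlotSpec,
    FociScene,
    GelLaneSpec,
    StructureModel,
    noise_variance_3d,
    radius_for_target_rg,
    render_conventional_image,
    rg_uniform_ball,
    sample_cluster_rgs,
    simulate_dot_blot,
    simulate_foci_image,
    simulate_gel_profile,
    simulate_localizations,
)

ZERO_NOISE = dict(sigma_xy=0.0, sigma_z=0.0, blink_mean=1.0, n_frames=1000)


class TestStructureModel:
    def test_sphere_requires_equal_axes(self):
        with pytest.raises(ValueError):
            StructureModel(0, [0, 0, 0], shape="sphere", axes=[50, 50, 20])

    def test_nonpositive_axes_rejected(self):
        with pytest.raises(ValueError):
            StructureModel(0, [0, 0, 0], axes=[50, 50, -1], shape="ellipsoid")

    def test_nonfinite_center_rejected(self):
        with pytest.raises(ValueError):
            StructureModel(0, [np.nan, 0, 0], radius=50)

    def test_segmented_path_emitters_respect_count(self, rng):
        s = StructureModel(0, [0, 0, 0], shape="segmented-path", axes=[150, 80, 40], n_emitters=500)
        assert s.sample_emitters(rng).shape == (500, 3)


class TestSimulateLocalizations:
    def test_zero_noise_single_blink_localizations_are_emitter_positions(self):
        acq = AcquisitionParams(seed=1, **ZERO_NOISE)
        s = StructureModel(0, [0, 0, 0], radius=100.0, n_emitters=300)
        sim = simulate_localizations([s], acq)
        assert len(sim.table) == 300
        # zero error + one blink per emitter: observed Rg equals the emitter Rg
        assert radius_of_gyration(sim.table.positions) == pytest.approx(
            sim.truth["rg_emitters_nm"].iloc[0], rel=1e-12
        )

    def test_localization_counts_partition_the_table(self):
        acq = AcquisitionParams(seed=2, n_frames=2000, blink_mean=3.0, background_density=5.0)
        structs = [
            StructureModel(i, [1500.0 * i, 0.0, 0.0], radius=80.0, n_emitters=100)
            for i in range(3)
        ]
        sim = simulate_localizations(structs, acq)
        counts = sim.table.df["truth_cluster"].value_counts()
        for sid in range(3):
            assert counts[sid] == sim.truth.set_index("structure_id")["n_locs"][sid]
        assert counts.sum() == len(sim.table)
        assert (sim.table.df["truth_cluster"] == -1).sum() > 0  # background present

    def test_seeded_determinism(self):
        structs = [StructureModel(0, [0, 0, 0], radius=90.0, n_emitters=150)]
        acq = AcquisitionParams(seed=7, n_frames=500)
        a = simulate_localizations(structs, acq).table.df
        b = simulate_localizations(structs, acq).table.df
        pd.testing.assert_frame_equal(a, b)

    def test_structure_outside_z_depth_rejected(self):
        acq = AcquisitionParams(seed=0, z_depth=700.0, n_frames=100)
        s = StructureModel(0, [0, 0, 400.0], radius=50.0)
        with pytest.raises(ValueError, match="z-depth"):
            simulate_localizations([s], acq)

    def test_empty_structure_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_localizations([], AcquisitionParams(seed=0))

    def test_uniform_ball_matches_closed_form_rg(self):
        """A dense zero-noise uniform ball reproduces Rg = √(3/5)·R."""
        acq = AcquisitionParams(seed=3, **ZERO_NOISE)
        s = StructureModel(0, [0, 0, 0], radius=100.0, n_emitters=100_000)
        sim = simulate_localizations([s], acq)
        assert radius_of_gyration(sim.table.positions) == pytest.approx(
            rg_uniform_ball(100.0), rel=0.01
        )

    def test_anisotropic_structure_axis_ratio_recovered(self):
        acq = AcquisitionParams(seed=4, **ZERO_NOISE)
        s = StructureModel(
            0, [0, 0, 0], shape="ellipsoid", axes=[120.0, 120.0, 30.0], n_emitters=50_000
        )
        sim = simulate_localizations([s], acq)
        spreads = cluster_anisotropy(sim.table.positions)
        assert spreads[0] / spreads[2] == pytest.approx(120.0 / 30.0, rel=0.05)

    def test_injected_drift_moves_late_frames(self):
        total = np.array([200.0, 0.0, 0.0])

        def drift(frames):
            return np.asarray(frames, float)[:, None] / 999 * total[None, :]

        acq = AcquisitionParams(seed=5, drift=drift, **ZERO_NOISE)
        s = StructureModel(0, [0, 0, 0], radius=50.0, n_emitters=5000)
        df = simulate_localizations([s], acq).table.df
        early = df[df.frame < 200]["x_nm"].mean()
        late = df[df.frame >= 800]["x_nm"].mean()
        # mean drift of frames <200 is ~20 nm, of frames >=800 is ~180 nm
        assert late - early == pytest.approx(160.0, abs=15.0)


class TestSampleClusterRgs:
    def test_matches_per_structure_simulation_statistics(self):
        """The vectorized group sampler agrees with the molecule-list path."""
        acq = AcquisitionParams(seed=0, n_frames=1000)
        rng = np.random.default_rng(11)
        fast = sample_cluster_rgs(300, acq, rng, radius_mean=85.0, n_emitters=200)
        slow_rgs = []
        rng2 = np.random.default_rng(12)
        for _ in range(300):
            s = StructureModel(0, [0, 0, 0], radius=85.0, n_emitters=200)
            sim = simulate_localizations([s], acq, rng=rng2)
            slow_rgs.append(radius_of_gyration(sim.table.positions))
        assert fast["rg_nm"].mean() == pytest.approx(np.mean(slow_rgs), rel=0.02)
        assert fast["n_locs"].mean() == pytest.approx(200 * acq.blink_mean, rel=0.05)

    def test_noise_additivity_of_observed_rg(self):
        """E[Rg_obs²] = Rg_nf² + 2σ_xy² + σ_z² over many clusters."""
        acq = AcquisitionParams(seed=0)
        rng = np.random.default_rng(5)
        df = sample_cluster_rgs(200, acq, rng, radius_mean=85.0, n_emitters=300)
        lhs = np.mean(df["rg_nm"] ** 2)
        rhs = np.mean(df["rg_noise_free_nm"] ** 2) + noise_variance_3d(acq)
        assert lhs == pytest.approx(rhs, rel=0.02)

    def test_radius_for_target_inverts_the_additivity_law(self):
        acq = AcquisitionParams(seed=0)
        r = radius_for_target_rg(90.0, acq)
        rng = np.random.default_rng(6)
        df = sample_cluster_rgs(400, acq, rng, radius_mean=r, n_emitters=300)
        assert np.sqrt(np.mean(df["rg_nm"] ** 2)) == pytest.approx(90.0, rel=0.02)

    def test_target_below_noise_floor_rejected(self):
        acq = AcquisitionParams(seed=0)
        with pytest.raises(ValueError, match="noise floor"):
            radius_for_target_rg(10.0, acq)


class TestRenderConventionalImage:
    def test_empty_table_renders_zero_image(self):
        from telostorm.localizations import LocalizationTable

        table = LocalizationTable(
            pd.DataFrame(columns=["x_nm", "y_nm", "z_nm", "frame", "photons"]), n_frames=1
        )
        img, _ = render_conventional_image(table, pixel_size=100.0, psf_sigma=150.0)
        assert np.all(img == 0)

    def test_single_localization_integrates_to_one(self):
        from telostorm.localizations import LocalizationTable

        df = pd.DataFrame(
            {"x_nm": [0.0], "y_nm": [0.0], "z_nm": [0.0], "frame": [0], "photons": [1000]}
        )
        table = LocalizationTable(df, n_frames=1)
        img, _ = render_conventional_image(table, pixel_size=50.0, psf_sigma=100.0)
        assert img.sum() == pytest.approx(1.0, rel=1e-6)

    def test_two_clusters_produce_two_peaks_at_their_centers(self):
        """Peak-finding oracle: rendered maxima sit at the cluster centers of
        mass to within one pixel."""
        from skimage.feature import peak_local_max

        acq = AcquisitionParams(seed=8, **ZERO_NOISE)
        centers = np.array([[0.0, 0.0, 0.0], [2000.0, 0.0, 0.0]])
        structs = [
            StructureModel(i, c, radius=80.0, n_emitters=2000) for i, c in enumerate(centers)
        ]
        sim = simulate_localizations(structs, acq)
        pixel = 100.0
        img, ((x0, _), (y0, _)) = render_conventional_image(sim.table, pixel, psf_sigma=150.0)
        peaks = peak_local_max(img, min_distance=5, num_peaks=2)
        found_x = np.sort(x0 + (peaks[:, 1] + 0.5) * pixel)
        found_y = y0 + (peaks[:, 0] + 0.5) * pixel
        assert np.allclose(found_x, np.sort(centers[:, 0]), atol=pixel)
        assert np.allclose(found_y, centers[:, 1], atol=pixel)


class TestFociScene:
    def test_centroid_outside_mask_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        with pytest.raises(ValueError, match="mask"):
            FociScene((20, 20), 80.0, mask, foci_a=[((1.0, 1.0), 10.0, 1.0)], foci_b=[])

    def test_planned_overlap_fraction_recorded(self):
        scene = FociScene.random(n_a=20, n_overlap=8, seed=0)
        assert scene.planned_overlap_fraction == pytest.approx(0.4)
        imgs = simulate_foci_image(scene)
        assert imgs.overlap_truth.sum() == 8

    def test_zero_noise_determinism(self):
        scene = FociScene.random(n_a=5, n_overlap=2, seed=3)
        a = simulate_foci_image(scene)
        b = simulate_foci_image(scene)
        assert np.array_equal(a.channel_a, b.channel_a)
        assert np.array_equal(a.channel_b, b.channel_b)


class TestGelSimulation:
    def _ladder(self):
        return [(10.0, 50.0), (8.0, 100.0), (4.0, 200.0), (2.0, 300.0), (1.0, 400.0)]

    def test_single_band_truth_is_its_weight(self):
        gel = simulate_gel_profile(
            GelLaneSpec(bands=[(5.0, 100.0, 2.0)], ladder=self._ladder())
        )
        assert gel.true_mean_kb == pytest.approx(5.0)

    def test_two_equal_bands_harmonic_mean(self):
        """Equal intensity at 2 and 8 kb: 2/(1/2 + 1/8) = 3.2 kb."""
        gel = simulate_gel_profile(
            GelLaneSpec(bands=[(2.0, 100.0, 1.0), (8.0, 100.0, 1.0)], ladder=self._ladder())
        )
        assert gel.true_mean_kb == pytest.approx(3.2)
        assert mean_telomere_length(gel.profile, gel.ladder) == pytest.approx(3.2, rel=1e-3)

    def test_intensity_scaling_leaves_truth_unchanged(self):
        lo = simulate_gel_profile(
            GelLaneSpec(bands=[(2.0, 10.0, 1.0), (8.0, 30.0, 1.0)], ladder=self._ladder())
        )
        hi = simulate_gel_profile(
            GelLaneSpec(bands=[(2.0, 100.0, 1.0), (8.0, 300.0, 1.0)], ladder=self._ladder())
        )
        assert lo.true_mean_kb == pytest.approx(hi.true_mean_kb)

    def test_nonmonotone_ladder_rejected(self):
        with pytest.raises(ValueError):
            GelLaneSpec(bands=[(5.0, 1.0, 1.0)], ladder=[(10.0, 50.0), (8.0, 50.0)])


class TestDotBlotSimulation:
    def _spec(self, noise_cv=0.0):
        groups = ["Vonly", "TRF1", "HP1a", "TRF1HP1a"]
        ratio = {(g, "HP1a_ab"): (28.0 if g == "TRF1HP1a" else 1.0) for g in groups}
        ratio.update({(g, "IgG"): 0.02 for g in groups})
        return DotBlotSpec(groups, ["input", "HP1a_ab", "IgG"], ratio, noise_cv=noise_cv, seed=0)

    def test_zero_noise_ratios_exact(self):
        grid = simulate_dot_blot(self._spec())
        out = normalize_dot_blot(grid)
        hp1 = out[(out.group == "TRF1") & (out.antibody == "HP1a_ab")]
        assert hp1["ratio_mean"].iloc[0] == pytest.approx(1.0)

    def test_fold_change_recovered_at_zero_noise(self):
        grid = simulate_dot_blot(self._spec())
        out = normalize_dot_blot(grid, control_groups=["Vonly", "TRF1", "HP1a"])
        fold = out[(out.group == "TRF1HP1a") & (out.antibody == "HP1a_ab")]
        assert fold["fold_vs_control"].iloc[0] == pytest.approx(28.0)

    def test_igg_stays_at_background(self):
        out = normalize_dot_blot(simulate_dot_blot(self._spec()))
        igg = out[out.antibody == "IgG"]
        assert np.allclose(igg["ratio_mean"], 0.02)

    def test_noisy_fold_within_sem_envelope(self):
        grid = simulate_dot_blot(self._spec(noise_cv=0.10))
        out = normalize_dot_blot(grid, control_groups=["Vonly", "TRF1", "HP1a"])
        row = out[(out.group == "TRF1HP1a") & (out.antibody == "HP1a_ab")].iloc[0]
        assert abs(row["fold_vs_control"] - 28.0) <= 28.0 * 0.25

    def test_missing_ratio_entry_rejected(self):
        with pytest.raises(ValueError, match="true_ratio"):
            DotBlotSpec(["a"], ["input", "ab"], {})
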