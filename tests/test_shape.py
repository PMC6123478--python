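"""Radius of gyration, anisotropy, clustering, filters, and group tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from telostorm.localizations import LocalizationTable
from telostorm.shape import (
    ClusterFilterPolicy,
    DegenerateClusterError,
    GroupShapeTable,
    TelomereCluster,
    cluster_anisotropy,
    cluster_localizations,
    filter_clusters,
    fraction_irregular,
    radius_of_gyration,
    rg_count_correlation,
    summarize_shape_distribution,
)

finite_coords = st.floats(-1e4, 1e4, allow_nan=False, width=32)


def brute_force_rg_pairwise(points):
    """Independent oracle: Rg² = (1/(2N²)) Σ_i Σ_j |r_i − r_j|² by double loop."""
    pts = np.asarray(points, float)
    n = len(pts)
    acc = 0.0
    for i in range(n):
        for j in range(n):
            acc += np.sum((pts[i] - pts[j]) ** 2)
    return np.sqrt(acc / (2.0 * n * n))


class TestRadiusOfGyration:
    def test_single_point_is_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_points_give_half_separation(self):
        pts = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        assert radius_of_gyration(pts) == pytest.approx(50.0)

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.empty((0, 3)))

    def test_matches_pairwise_distance_identity(self, random_cluster):
        rg = radius_of_gyration(random_cluster)
        assert rg == pytest.approx(brute_force_rg_pairwise(random_cluster), rel=1e-9)

    def test_2d_mode_ignores_z(self, random_cluster):
        squashed = random_cluster.copy()
        squashed[:, 2] = 0.0
        assert radius_of_gyration(random_cluster, dims=2) == pytest.approx(
            radius_of_gyration(squashed), rel=1e-12
        )

    @given(
        pts=arrays(np.float64, (20, 3), elements=finite_coords),
        shift=arrays(np.float64, (3,), elements=finite_coords),
        scale=st.floats(0.01, 100.0),
        seed=st.integers(0, 2**16),
    )
    def test_rigid_motion_invariance_and_scaling(self, pts, shift, scale, seed):
        """Rg is invariant under rotation+translation and linear under scaling."""
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()
        rg = radius_of_gyration(pts)
        moved = pts @ rot.T + shift
        assert radius_of_gyration(moved) == pytest.approx(rg, rel=1e-8, abs=1e-8)
        assert radius_of_gyration(pts * scale) == pytest.approx(scale * rg, rel=1e-8, abs=1e-8)

    def test_adding_center_of_mass_point_shrinks_by_known_factor(self, random_cluster):
        """Appending a point at the COM multiplies Rg by exactly √(N/(N+1))."""
        n = len(random_cluster)
        com = random_cluster.mean(axis=0)
        grown = np.vstack([random_cluster, com])
        expected = radius_of_gyration(random_cluster) * np.sqrt(n / (n + 1))
        assert radius_of_gyration(grown) == pytest.approx(expected, rel=1e-12)


class TestAnisotropy:
    def test_axis_spreads_square_sum_to_rg_squared(self, random_cluster):
        spreads = cluster_anisotropy(random_cluster)
        assert np.all(np.diff(spreads) <= 0)
        assert np.sum(spreads**2) == pytest.approx(
            radius_of_gyration(random_cluster) ** 2, rel=1e-9
        )

    def test_uniform_ball_is_isotropic(self, rng):
        v = rng.standard_normal((200_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = v * (rng.random(200_000) ** (1 / 3))[:, None] * 100.0
        spreads = cluster_anisotropy(pts)
        assert spreads[0] / spreads[2] == pytest.approx(1.0, rel=0.05)

    def test_planar_cluster_has_zero_third_axis(self, rng):
        pts = rng.normal(size=(100, 3)) * np.array([50.0, 30.0, 0.0])
        spreads = cluster_anisotropy(pts)
        assert spreads[2] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "pts",
        [
            np.array([[0.0, 0, 0], [1.0, 0, 0]]),  # too few points
            np.array([[0.0, 0, 0], [1.0, 1, 1], [2.0, 2, 2], [3.0, 3, 3]]),  # collinear
        ],
    )
    def test_degenerate_clusters_are_flagged(self, pts):
        with pytest.raises(DegenerateClusterError):
            cluster_anisotropy(pts)


def _table_from_points(points, n_frames=100):
    pts = np.asarray(points, float)
    df = pd.DataFrame(
        {
            "x_nm": pts[:, 0],
            "y_nm": pts[:, 1],
            "z_nm": pts[:, 2],
            "frame": np.arange(len(pts)) % n_frames,
            "photons": 1000,
        }
    )
    return LocalizationTable(df, n_frames=n_frames)


class TestClustering:
    def test_empty_table_gives_empty_list(self):
        table = _table_from_points(np.empty((0, 3)))
        assert cluster_localizations(table) == []

    def test_two_separated_clusters_are_recovered_pure(self, rng):
        from telostorm.simulate import AcquisitionParams, StructureModel, simulate_localizations

        acq = AcquisitionParams(seed=0, n_frames=1000, blink_mean=2.0)
        structs = [
            StructureModel(0, [0.0, 0.0, 0.0], radius=80.0, n_emitters=200),
            StructureModel(1, [900.0, 0.0, 0.0], radius=80.0, n_emitters=200),
        ]
        sim = simulate_localizations(structs, acq)
        clusters = cluster_localizations(sim.table)
        assert len(clusters) == 2
        truth = sim.table.df["truth_cluster"].to_numpy()
        for c in clusters:
            labels = truth[c.member_index]
            purity = np.max(np.bincount(labels[labels >= 0])) / len(labels)
            assert purity >= 0.95

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(300, 3)) * 40.0
        a = cluster_localizations(_table_from_points(pts))
        b = cluster_localizations(_table_from_points(pts + 10_000.0))
        assert len(a) == len(b) == 1
        assert a[0].rg == pytest.approx(b[0].rg, rel=1e-12)
        assert a[0].n == b[0].n


def _cluster_of(n, z=0.0, spread=50.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3)) * spread
    pts[:, 2] += z - pts[:, 2].mean()
    return TelomereCluster(pts)


class TestFilterPolicy:
    def test_min_points_is_strictly_greater(self):
        """The localization-count screen keeps clusters with MORE than the
        threshold: exactly 200 points fails, 201 passes."""
        policy = ClusterFilterPolicy(min_points=200, focal_window=1e6)
        at, above = _cluster_of(200), _cluster_of(201)
        assert filter_clusters([at], policy) == []
        assert filter_clusters([above], policy) == [above]

    def test_on_focal_plane_always_retained(self):
        c = _cluster_of(300, z=0.0)
        for window in (1.0, 250.0):
            policy = ClusterFilterPolicy(min_points=0, focal_window=window)
            assert filter_clusters([c], policy, focal_plane_z=0.0) == [c]

    def test_focal_window_excludes_distant_clusters(self):
        far = _cluster_of(300, z=400.0)
        policy = ClusterFilterPolicy(min_points=0, focal_window=250.0)
        assert filter_clusters([far], policy, focal_plane_z=0.0) == []

    @given(lower=st.integers(0, 100), upper=st.integers(100, 300))
    def test_lowering_min_points_never_decreases_retention(self, lower, upper):
        clusters = [_cluster_of(n, seed=n) for n in (50, 150, 201, 250)]
        keep = lambda m: len(
            filter_clusters(clusters, ClusterFilterPolicy(min_points=m, focal_window=1e6))
        )
        assert keep(lower) >= keep(upper)

    def test_reference_mask_gates_xy_center(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        inside = TelomereCluster(np.tile([350.0, 350.0, 0.0], (10, 1)))
        outside = TelomereCluster(np.tile([950.0, 950.0, 0.0], (10, 1)))
        policy = ClusterFilterPolicy(
            min_points=0, focal_window=1e6, reference_mask=mask, mask_pixel_size=100.0
        )
        assert filter_clusters([inside, outside], policy) == [inside]


def _shape_table(records):
    return GroupShapeTable(
        pd.DataFrame(records, columns=["group", "nucleus", "telomere", "rg_nm", "n_locs"])
    )


class TestGroupShapeTable:
    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            _shape_table([("g", 0, 0, 80.0, 300), ("g", 0, 0, 90.0, 300)])

    def test_fraction_cutoff_recomputed_and_inclusive(self):
        """The cutoff is the reference group's mean; Rg exactly at the cutoff
        counts as irregular ('equal or greater')."""
        table = _shape_table(
            [("ref", 0, 0, 80.0, 300), ("ref", 0, 1, 88.0, 300),
             ("test", 0, 0, 84.0, 300), ("test", 0, 1, 50.0, 300)]
        )
        fractions, cutoff = fraction_irregular(table, "ref")
        assert cutoff == pytest.approx(84.0)
        assert fractions["test"] == pytest.approx(0.5)  # the 84.0 counts, the 50 does not
        assert fractions["ref"] == pytest.approx(0.5)

    def test_all_below_cutoff_gives_zero(self):
        table = _shape_table(
            [("ref", 0, 0, 100.0, 300), ("test", 0, 0, 10.0, 300), ("test", 0, 1, 20.0, 300)]
        )
        fractions, _ = fraction_irregular(table, "ref")
        assert fractions["test"] == 0.0

    def test_missing_reference_group_raises(self):
        table = _shape_table([("a", 0, 0, 80.0, 300)])
        with pytest.raises(ValueError):
            fraction_irregular(table, "nope")

    def test_summary_identical_values(self):
        table = _shape_table([("g", 0, i, 75.0, 300) for i in range(5)])
        summary, _ = summarize_shape_distribution(table)
        row = summary.iloc[0]
        assert row["mean_rg_nm"] == row["median_rg_nm"] == 75.0
        assert row["iqr_high_nm"] - row["iqr_low_nm"] == 0.0

    def test_nucleus_means_weighted_average_to_group_mean(self, rng):
        records = [
            ("g", nuc, t, float(rg), 300)
            for nuc, size in enumerate([3, 7, 11])
            for t, rg in enumerate(rng.uniform(50, 150, size))
        ]
        table = _shape_table(records)
        g_summary, n_summary = summarize_shape_distribution(table)
        weighted = np.average(n_summary["mean_rg_nm"], weights=n_summary["n"])
        assert weighted == pytest.approx(g_summary["mean_rg_nm"].iloc[0], rel=1e-12)

    def test_rg_count_correlation_limits(self):
        rgs = [50.0, 60.0, 70.0, 80.0]
        table_pos = _shape_table(
            [("g", 0, i, rg, int(rg)) for i, rg in enumerate(rgs)]
        )
        table_neg = _shape_table(
            [("g", 0, i, rg, int(200 - rg)) for i, rg in enumerate(rgs)]
        )
        assert rg_count_correlation(table_pos)["g"] == pytest.approx(1.0)
        assert rg_count_correlation(table_neg)["g"] == pytest.approx(-1.0)

    def test_zero_variance_correlation_is_missing(self):
        table = _shape_table([("g", 0, i, 80.0, 100 + i) for i in range(5)])
        assert np.isnan(rg_count_correlation(table)["g"])

    def test_csv_roundtrip(self, tmp_path):
        table = _shape_table([("g", 0, 0, 80.0, 300), ("g", 0, 1, 90.0, 250)])
        path = tmp_path / "shape.csv"
        table.to_csv(path)
        back = GroupShapeTable.from_csv(path)
        pd.testing.assert_frame_equal(back.records, table.records)
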