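import math

import numpy as np
import pytest

from stormclust.dbscan_cluster import ClusterAssignment
from stormclust.cluster_metrics import (
    cluster_density,
    cluster_radius,
    image_summary,
    roi_volume,
    summarize_clusters,
)

from conftest import make_table


def _assignment(labels, image_id="test-img"):
    return ClusterAssignment(
        labels=np.asarray(labels), algorithm="test", params={}, image_id=image_id
    )


class TestClusterRadius:
    def test_two_points_half_separation(self):
        coords = [[0, 0, 0], [100, 0, 0]]
        assert cluster_radius(np.asarray(coords)) == pytest.approx(50.0)

    def test_singleton_radius_zero(self):
        assert cluster_radius(np.asarray([[5, 5, 5]])) == 0.0

    def test_uniform_ball_gyration_radius(self, rng):
        # uniform ball of radius R: gyration radius = R * sqrt(3/5)
        R = 200.0
        pts = rng.normal(size=(30_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= R * rng.uniform(0, 1, size=(30_000, 1)) ** (1 / 3)
        expected = R * math.sqrt(3 / 5)
        assert cluster_radius(pts[:10_000]) == pytest.approx(expected, rel=0.01)

    def test_max_definition_dominates_gyration(self, rng):
        pts = rng.normal(0, 30, size=(200, 3))
        assert cluster_radius(pts, "max") >= cluster_radius(pts, "gyration")

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_radius(np.empty((0, 3)))


class TestClusterDensity:
    def test_arithmetic_reference_value(self):
        raw, platform, _ = cluster_density(100, 50.0)
        assert raw == pytest.approx(100 / ((4 / 3) * math.pi * 50**3))
        assert raw == pytest.approx(1.9099e-4, rel=1e-3)
        assert platform == pytest.approx(0.191, rel=1e-2)

    def test_platform_scale_is_exactly_1000x(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 500))
            r = float(rng.uniform(1, 300))
            raw, platform, _ = cluster_density(n, r)
            assert platform == 1000.0 * raw  # exact, not approximate

    def test_density_linear_in_n(self):
        raw1, _, _ = cluster_density(100, 50.0)
        raw2, _, _ = cluster_density(200, 50.0)
        assert raw2 == pytest.approx(2 * raw1)

    def test_coincident_pair_flagged_infinite(self):
        with pytest.warns(UserWarning, match="coincident"):
            raw, platform, d2 = cluster_density(2, 0.0)
        assert math.isinf(raw) and math.isinf(platform)

    def test_2d_projected_density(self):
        _, _, d2 = cluster_density(100, 50.0)
        assert d2 == pytest.approx(100 / (math.pi * 50**2))


class TestSummarizeClusters:
    def test_counts_per_label(self):
        table = make_table([[0, 0, 0], [10, 0, 0], [500, 0, 0], [900, 0, 0]])
        records = summarize_clusters(table, _assignment([0, 0, 1, -1]))
        assert records["n_localizations"].tolist() == [2, 1]
        assert records["radius_nm"].iloc[0] == pytest.approx(5.0)

    def test_all_noise_gives_empty_frame(self):
        table = make_table([[0, 0, 0], [1, 1, 1]])
        records = summarize_clusters(table, _assignment([-1, -1]))
        assert records.empty

    def test_independent_recount_agrees(self, rng):
        coords = rng.uniform(0, 1000, size=(200, 3))
        labels = rng.integers(-1, 5, size=200)
        labels = np.asarray(
            [l if l in set(labels[labels >= 0]) else -1 for l in labels]
        )
        # renumber contiguously for the assignment contract
        uniq = sorted(set(labels[labels >= 0]))
        remap = {l: i for i, l in enumerate(uniq)}
        labels = np.asarray([remap.get(l, -1) for l in labels])
        table = make_table(coords)
        records = summarize_clusters(table, _assignment(labels))
        for cid in uniq:
            members = coords[labels == remap[cid]]
            row = records[records["cluster_id"] == remap[cid]].iloc[0]
            assert row["n_localizations"] == len(members)
            np.testing.assert_allclose(
                [row["centroid_x"], row["centroid_y"], row["centroid_z"]],
                members.mean(axis=0),
            )
            rms = np.sqrt(((members - members.mean(0)) ** 2).sum(1).mean())
            assert row["radius_nm"] == pytest.approx(rms)
        # conservation
        assert records["n_localizations"].sum() == (labels >= 0).sum()

    def test_mismatched_lengths_rejected(self):
        table = make_table([[0, 0, 0]])
        with pytest.raises(ValueError, match="length"):
            summarize_clusters(table, _assignment([0, 0]))

    def test_scale_equivariance(self, rng):
        coords = rng.normal(0, 50, size=(100, 3))
        labels = np.zeros(100, dtype=int)
        s = 3.0
        r1 = summarize_clusters(make_table(coords), _assignment(labels))
        r2 = summarize_clusters(make_table(coords * s), _assignment(labels))
        assert r2["radius_nm"].iloc[0] == pytest.approx(s * r1["radius_nm"].iloc[0])
        assert r2["volume_nm3"].iloc[0] == pytest.approx(
            s**3 * r1["volume_nm3"].iloc[0]
        )
        assert r2["density_raw"].iloc[0] == pytest.approx(
            r1["density_raw"].iloc[0] / s**3
        )


class TestRoiVolume:
    CUBE = [
        [0, 0, 0], [1000, 0, 0], [0, 1000, 0], [0, 0, 1000],
        [1000, 1000, 0], [1000, 0, 1000], [0, 1000, 1000], [1000, 1000, 1000],
    ]

    def test_cube_corners_convex_hull(self):
        assert roi_volume(make_table(self.CUBE), "convex_hull") == pytest.approx(1e9)

    def test_cube_corners_bounding_box(self):
        assert roi_volume(make_table(self.CUBE), "bounding_box") == pytest.approx(1e9)

    def test_hull_never_exceeds_box(self, rng):
        table = make_table(rng.normal(0, 200, size=(300, 3)))
        hull = roi_volume(table, "convex_hull")
        box = roi_volume(table, "bounding_box")
        assert hull <= box

    def test_user_bounds(self):
        table = make_table([[0, 0, 0]])
        bounds = ((0, 100), (0, 200), (0, 50))
        assert roi_volume(table, "user_bounds", bounds) == pytest.approx(1e6)

    def test_degenerate_user_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            roi_volume(make_table([[0, 0, 0]]), "user_bounds", ((0, 0), (0, 1), (0, 1)))

    def test_coplanar_cloud_falls_back_to_box(self, rng):
        coords = rng.uniform(0, 100, size=(50, 3))
        coords[:, 2] = np.linspace(1, 99, 50)  # keep z extent, make x flat
        coords[:, 0] = 7.0
        with pytest.warns(UserWarning, match="bounding box"):
            with pytest.raises(ValueError, match="zero-extent"):
                roi_volume(make_table(coords), "convex_hull")


class TestImageSummary:
    def test_pct_clustered_arithmetic(self, rng):
        coords = rng.uniform(0, 1000, size=(100, 3))
        labels = np.full(100, -1)
        labels[:40] = np.repeat(np.arange(4), 10)
        summary = image_summary(make_table(coords), _assignment(labels))
        assert summary.pct_locs_clustered == pytest.approx(40.0)
        assert summary.n_clusters == 4
        assert summary.mean_locs_per_cluster == pytest.approx(10.0)
        assert summary.locs_per_roi_volume == pytest.approx(
            100 / summary.roi_volume
        )

    def test_no_clusters_null_means(self, rng):
        coords = rng.uniform(0, 1000, size=(50, 3))
        summary = image_summary(make_table(coords), _assignment([-1] * 50))
        assert summary.n_clusters == 0
        assert summary.mean_radius is None
        assert summary.pct_locs_clustered == 0.0

    def test_empty_table_flagged_degenerate(self):
        table = make_table(np.empty((0, 3)))
        summary = image_summary(table, _assignment([]))
        assert summary.degenerate
        assert summary.roi_volume is None
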