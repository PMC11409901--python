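import dataclasses

import numpy as np
import pytest

from stormclust.focal_cluster import (
    FocalParams,
    focal,
    focal_pc,
    sweep_maPC,
    voxelize,
)

from conftest import make_table, random_scene
from _oracles import focal_transcription, same_partition


class TestVoxelize:
    def test_floor_binning_at_voxel_boundary(self):
        table = make_table([[0, 0, 0], [49, 0, 0], [51, 0, 0]])
        grid = voxelize(table, 50.0)
        assert grid.counts == {(0, 0, 0): 2, (1, 0, 0): 1}

    def test_single_point_single_voxel_with_its_pc(self):
        table = make_table([[10, 20, 30]], photon_count=[4321.0])
        grid = voxelize(table, 50.0)
        grid.compute_mean_pc(table.photon_count)
        assert grid.counts == {(0, 0, 0): 1}
        assert grid.mean_pc[(0, 0, 0)] == 4321.0

    def test_uniform_cube_count_conservation(self, rng):
        table = make_table(rng.uniform(0, 1000, size=(10_000, 3)))
        grid = voxelize(table, 100.0)
        assert grid.n_localizations == 10_000
        # ~1000 nm cube at 100 nm voxels: at most 11^3 voxels, around 10^3
        assert 500 <= len(grid.members) <= 11**3

    def test_nonpositive_voxel_size_rejected(self):
        with pytest.raises(ValueError, match="voxel_size"):
            voxelize(make_table([[0, 0, 0]]), 0.0)

    def test_every_localization_in_exactly_one_voxel(self, rng):
        table = make_table(rng.normal(0, 200, size=(500, 3)))
        grid = voxelize(table, 50.0)
        all_members = np.concatenate(list(grid.members.values()))
        assert sorted(all_members) == list(range(500))


class TestFocal:
    def test_empty_table_no_clusters(self):
        out = focal(make_table(np.empty((0, 3))), FocalParams())
        assert len(out) == 0 and out.n_clusters == 0

    def test_single_dense_voxel_blob_forms_one_cluster(self, rng):
        coords = rng.uniform(10, 40, size=(300, 3))  # all inside one voxel
        out = focal(make_table(coords), FocalParams(voxel_size=50, minL=10, minC=1))
        assert out.n_clusters == 1
        assert np.all(out.labels == 0)

    def test_min_c_drops_small_components(self, rng):
        coords = rng.uniform(10, 40, size=(300, 3))
        out = focal(make_table(coords), FocalParams(voxel_size=50, minL=10, minC=2))
        assert out.n_clusters == 0  # one-voxel component < minC

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_literal_transcription(self, seed):
        rng = np.random.default_rng(100 + seed)
        table = random_scene(
            rng,
            n_blobs=int(rng.integers(1, 5)),
            blob_size=int(rng.integers(20, 60)),
            blob_sigma=float(rng.uniform(25, 70)),
            n_noise=int(rng.integers(20, 120)),
        )
        params = FocalParams(
            voxel_size=float(rng.uniform(40, 90)),
            minL=int(rng.integers(4, 14)),
            minC=int(rng.integers(1, 4)),
        )
        mine = focal(table, params)
        ref = focal_transcription(
            table.coords, table.photon_count,
            params.voxel_size, params.minL, params.minC, maPC=0.0,
        )
        assert same_partition(mine.labels, ref)


class TestFocalPc:
    def test_zero_gate_bit_identical_to_focal(self, rng):
        for _ in range(10):
            table = random_scene(rng, n_blobs=3, blob_size=40, n_noise=60)
            params = FocalParams(voxel_size=60, minL=8, minC=2, maPC=0.0)
            np.testing.assert_array_equal(
                focal(table, params).labels, focal_pc(table, params).labels
            )

    def test_gate_keeps_only_bright_voxels_of_candidate(self):
        # 4 voxels in a row; mean PCs 3000, 3000, 900, 800; maPC 2500
        # keeps the two bright voxels as the surviving sub-group.
        coords, pcs = [], []
        for vx, pc in enumerate([3000, 3000, 900, 800]):
            for i in range(10):
                coords.append([vx * 50 + 5 + i * 4, 25, 25])
                pcs.append(float(pc))
        table = make_table(coords, photon_count=pcs)
        params = FocalParams(voxel_size=50, minL=10, minC=2, maPC=2500)
        assert focal(table, dataclasses.replace(params, maPC=0)).n_clusters == 1
        out = focal_pc(table, params)
        assert out.n_clusters == 1
        np.testing.assert_array_equal(out.labels[:20], 0)
        np.testing.assert_array_equal(out.labels[20:], -1)

    def test_gate_is_strict_inequality(self):
        coords = [[5 + i, 25, 25] for i in range(10)]
        table = make_table(coords, photon_count=[2500.0] * 10)
        params = FocalParams(voxel_size=50, minL=5, minC=1, maPC=2500)
        assert focal_pc(table, params).n_clusters == 0  # mean == maPC: gated out
        params_below = dataclasses.replace(params, maPC=2499.9)
        assert focal_pc(table, params_below).n_clusters == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_literal_transcription_with_gate(self, seed):
        rng = np.random.default_rng(300 + seed)
        table = random_scene(rng, n_blobs=4, blob_size=40, n_noise=60)
        params = FocalParams(voxel_size=60, minL=8, minC=2,
                             maPC=float(rng.choice([1000, 2500, 5000])))
        mine = focal_pc(table, params)
        ref = focal_transcription(
            table.coords, table.photon_count,
            params.voxel_size, params.minL, params.minC, maPC=params.maPC,
        )
        assert same_partition(mine.labels, ref)

    def test_clustered_sets_nested_in_maPC(self, rng):
        table = random_scene(rng, n_blobs=5, blob_size=50, n_noise=80)
        params = FocalParams(voxel_size=60, minL=8, minC=2)
        prev = None
        for mapc in [0, 1000, 2500, 5000, 10_000]:
            out = focal_pc(table, dataclasses.replace(params, maPC=mapc))
            clustered = set(np.flatnonzero(out.labels >= 0))
            if prev is not None:
                assert clustered <= prev
            prev = clustered


class TestFocalInvariances:
    def test_translation_by_voxel_multiple_preserves_partition(self, rng):
        table = random_scene(rng, n_blobs=3, blob_size=40, n_noise=50)
        params = FocalParams(voxel_size=50, minL=8, minC=2)
        base = focal(table, params)
        shifted_data = table.data.copy()
        for col, shift in zip("xyz", (500.0, -1500.0, 250.0)):
            shifted_data[col] += shift
        shifted = table.with_data(shifted_data)
        np.testing.assert_array_equal(focal(shifted, params).labels, base.labels)

    def test_conservation_every_localization_labelled_once(self, rng):
        table = random_scene(rng, n_blobs=4, blob_size=30, n_noise=60)
        out = focal(table, FocalParams(voxel_size=60, minL=8, minC=2))
        assert len(out.labels) == len(table)
        assert (out.labels >= 0).sum() + out.n_noise == len(table)

    def test_determinism(self, rng):
        table = random_scene(rng, n_blobs=3, blob_size=40, n_noise=40)
        params = FocalParams(voxel_size=55, minL=9, minC=2, maPC=2000)
        a = focal_pc(table, params)
        b = focal_pc(table, params)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestSweep:
    def test_single_zero_entry_equals_focal_summary(self, rng):
        from stormclust.cluster_metrics import image_summary

        table = random_scene(rng, n_blobs=3, blob_size=40, n_noise=40)
        params = FocalParams(voxel_size=60, minL=8, minC=2)
        df = sweep_maPC(table, params, [0])
        summary = image_summary(table, focal(table, params))
        assert len(df) == 1
        assert df.loc[0, "n_clusters"] == summary.n_clusters
        assert df.loc[0, "pct_locs_clustered"] == summary.pct_locs_clustered

    def test_repeated_values_give_identical_rows(self, rng):
        table = random_scene(rng, n_blobs=2, blob_size=40, n_noise=40)
        df = sweep_maPC(table, FocalParams(voxel_size=60, minL=8, minC=2), [0, 0])
        assert df.iloc[0].equals(df.iloc[1])

    def test_empty_sweep_rejected(self, rng):
        table = random_scene(rng)
        with pytest.raises(ValueError, match="non-empty"):
            sweep_maPC(table, FocalParams(), [])

    def test_negative_maPC_rejected(self, rng):
        table = random_scene(rng)
        with pytest.raises(ValueError, match=">= 0"):
            sweep_maPC(table, FocalParams(), [0, -5])


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        FocalParams(voxel_size=0)
    with pytest.raises(ValueError):
        FocalParams(minL=0)
    with pytest.raises(ValueError):
        FocalParams(maPC=-1)
    with pytest.raises(ValueError):
        FocalParams(connectivity=18)
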