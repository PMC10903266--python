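import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epicount import counting
from epicount.counting import (
    CountingConfig,
    connected_components,
    count_nuclei,
    count_workflow,
    expand_labels_chebyshev,
    filter_small_labels,
    measure_projected_area,
    measure_volumes,
    remap_labels,
    smooth_and_invert,
    watershed_segment,
)
from epicount.volumes import LabelVolume, VolumeImage

from _oracles import (
    bfs_connected_components,
    brute_force_expand,
    brute_force_regional_minima,
    label_tally,
)
from conftest import single_nucleus_image


class TestSmoothAndInvert:
    def test_constant_image_maps_to_complement(self):
        image = VolumeImage(np.full((4, 8, 8), 40.0), bit_depth=8)
        out = smooth_and_invert(image, CountingConfig(gaussian_sigma=2))
        np.testing.assert_allclose(out.data, 215.0)

    def test_sigma_zero_is_pure_inversion(self):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 256, size=(4, 8, 8)).astype(float)
        image = VolumeImage(data, bit_depth=8)
        out = smooth_and_invert(image, CountingConfig(gaussian_sigma=0))
        np.testing.assert_allclose(out.data, 255.0 - data)

    def test_default_sigma_is_two_voxels(self):
        assert CountingConfig().gaussian_sigma == 2.0


class TestWatershed:
    def test_blank_image_yields_empty_labeling(self):
        image = VolumeImage(np.zeros((4, 8, 8)), bit_depth=8)
        prepared = smooth_and_invert(image)  # all 255, above the 250 bound
        labels = watershed_segment(prepared)
        assert labels.max_label == 0

    def test_single_ellipsoid_one_label(self):
        image = single_nucleus_image()
        prepared = smooth_and_invert(image)
        labels = watershed_segment(prepared)
        assert labels.n_labels == 1
        # the label covers the ellipsoid interior
        inside = image.data == 180.0
        assert (labels.data[inside] > 0).all()

    def test_two_separated_ellipsoids_two_labels_and_minima_oracle(self):
        data = np.zeros((16, 20, 30), dtype=np.float64)
        for cx in (8, 21):  # surfaces 3 voxels apart
            zz, yy, xx = np.ogrid[:16, :20, :30]
            inside = ((zz - 7.5) / 4) ** 2 + ((yy - 9.5) / 4) ** 2 + ((xx - cx) / 5) ** 2 <= 1
            data[inside] = 180.0
        image = VolumeImage(data, bit_depth=8)
        prepared = smooth_and_invert(image)
        labels = watershed_segment(prepared)
        assert labels.n_labels == 2
        n_minima = brute_force_regional_minima(
            prepared.data, prepared.data <= 250.0, connectivity=26
        )
        assert labels.n_labels == n_minima

    def test_labels_are_separated_by_divides(self, small_scene):
        """No two distinct labels may be 26-adjacent: basins meet only
        across background divide voxels."""
        from scipy import ndimage as ndi

        _, _, images = small_scene
        result = count_workflow(images["dapi"])
        arr = result.labels.data
        big = arr.max() + 1
        guarded = np.where(arr > 0, arr, big)
        mn = ndi.minimum_filter(
            guarded, footprint=np.ones((3, 3, 3)), mode="constant", cval=big
        )
        # a voxel whose neighborhood holds a smaller non-background label
        # would witness two adjacent labels (the larger voxel sees the
        # smaller one); none may exist
        assert not (mn[arr > 0] < arr[arr > 0]).any()

    def test_count_invariant_under_affine_rescaling(self):
        image = single_nucleus_image(level=200.0, background=10.0)
        cfg = CountingConfig()
        base = count_workflow(image, cfg).count
        a = 0.5
        scaled = VolumeImage(a * image.data, bit_depth=8)
        bound = 255.0 - a * (255.0 - 250.0)
        cfg2 = CountingConfig(watershed_max_intensity=bound)
        assert count_workflow(scaled, cfg2).count == base


class TestConnectedComponents:
    def test_single_voxel(self):
        arr = np.zeros((3, 3, 3), dtype=np.int64)
        arr[1, 1, 1] = 1
        assert connected_components(arr, 26).max() == 1

    def test_corner_touch_depends_on_connectivity(self):
        arr = np.zeros((2, 2, 2), dtype=np.int64)
        arr[0, 0, 0] = 1
        arr[1, 1, 1] = 1
        assert connected_components(arr, 26).max() == 1
        assert connected_components(arr, 6).max() == 2

    @pytest.mark.parametrize("connectivity", [26, 6])
    def test_matches_bfs_oracle_on_random_volumes(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(25):
            density = rng.uniform(0.2, 0.6)
            mask = rng.random((12, 12, 12)) < density
            ours = connected_components(mask.astype(np.int8), connectivity)
            oracle = bfs_connected_components(mask, connectivity)
            assert ours.max() == oracle.max()
            # identical membership: labels agree up to renaming; both are in
            # scan order so they must be exactly equal
            np.testing.assert_array_equal(ours, oracle)


class TestFilterRemapCount:
    def test_size_boundary_at_default_minimum(self):
        arr = np.zeros((4, 10, 10), dtype=np.int64)
        arr[0, 0, :9] = 1  # 9 voxels: removed
        arr[2, 2, :] = 2  # 10 voxels: kept
        out = filter_small_labels(arr, 10)
        assert 1 not in out
        assert (out == 2).sum() == 10

    def test_min_one_is_identity(self):
        rng = np.random.default_rng(3)
        arr = rng.integers(0, 5, size=(6, 6, 6)).astype(np.int64)
        np.testing.assert_array_equal(filter_small_labels(arr, 1), arr)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 30))
    @settings(max_examples=25, deadline=None)
    def test_surviving_labels_match_tally_oracle(self, seed, min_voxels):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 8, size=(8, 8, 8)).astype(np.int64)
        out = filter_small_labels(arr, min_voxels)
        tally = label_tally(arr)
        expected = {lab for lab, count in tally.items() if count >= min_voxels}
        assert set(np.unique(out[out > 0])) == expected

    def test_remap_compacts_sparse_labels(self):
        arr = np.zeros((2, 3, 3), dtype=np.int64)
        arr[0, 0, 0], arr[0, 1, 1], arr[1, 2, 2] = 3, 7, 9
        out = remap_labels(arr)
        assert set(np.unique(out)) == {0, 1, 2, 3}
        # order of first appearance preserved
        assert out[0, 0, 0] == 1 and out[0, 1, 1] == 2 and out[1, 2, 2] == 3

    def test_remap_of_consecutive_labels_is_identity(self):
        arr = np.zeros((2, 4, 4), dtype=np.int64)
        arr[0, 0, 0], arr[1, 1, 1] = 1, 2
        np.testing.assert_array_equal(remap_labels(arr), arr)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_remap_then_count_equals_distinct_cardinality(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 12, size=(6, 6, 6)).astype(np.int64)
        remapped = LabelVolume(remap_labels(arr))
        n_distinct = len(set(np.unique(arr)) - {0})
        assert remapped.max_label == n_distinct
        assert count_nuclei(remapped) == n_distinct

    def test_count_rejects_unremapped_labels(self):
        arr = np.zeros((2, 4, 4), dtype=np.int64)
        arr[0, 0, 0] = 5
        with pytest.raises(ValueError, match="not remapped"):
            count_nuclei(LabelVolume(arr))

    def test_count_of_empty_labeling_is_zero(self):
        assert count_nuclei(LabelVolume(np.zeros((2, 4, 4), dtype=np.int64))) == 0


class TestMorphometry:
    def test_expansion_matches_brute_force_oracle(self):
        from conftest import random_labels

        rng = np.random.default_rng(7)
        for _ in range(6):
            labels = random_labels(rng, shape=(12, 12, 12), n_blobs=4)
            for distance in (1, 2):
                ours = expand_labels_chebyshev(labels, distance)
                oracle = brute_force_expand(labels, distance)
                np.testing.assert_array_equal(ours, oracle)

    def test_isolated_label_volume_includes_one_shell(self):
        arr = np.zeros((7, 7, 7), dtype=np.int64)
        arr[3, 3, 2:5] = 1  # 3 voxels in a row
        labels = LabelVolume(arr, spacing=(0.3, 1.0, 1.0))
        table, total = measure_volumes(labels)
        # Chebyshev expansion of a 1x1x3 row by 1 voxel -> 3x3x5 block
        assert table.loc[0, "voxel_count"] == 3
        assert table.loc[0, "expanded_voxels"] == 45
        assert total == pytest.approx(45 * 0.3)

    def test_gap_filled_without_relabeling(self):
        arr = np.zeros((3, 5, 9), dtype=np.int64)
        arr[1, 2, 1:4] = 1
        arr[1, 2, 5:8] = 2  # one-voxel gap at x=4
        expanded = expand_labels_chebyshev(arr, 1)
        assert expanded[1, 2, 4] == 1  # tie at distance 1 goes to lower id
        assert set(np.unique(expanded)) == {0, 1, 2}

    def test_empty_labeling_zero_volume(self):
        labels = LabelVolume(np.zeros((2, 4, 4), dtype=np.int64))
        table, total = measure_volumes(labels)
        assert total == 0.0 and len(table) == 0

    def test_projected_area_collapses_z(self):
        arr = np.zeros((10, 4, 4), dtype=np.int64)
        arr[:, 1, 1] = 1  # column of 10 voxels
        area_column = measure_projected_area(arr, spacing=(0.3, 0.5, 0.5))
        arr1 = np.zeros((1, 4, 4), dtype=np.int64)
        arr1[0, 1, 1] = 1
        area_single = measure_projected_area(arr1, spacing=(0.3, 0.5, 0.5))
        assert area_column == area_single == pytest.approx(0.25)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_projected_area_equals_2d_tally(self, seed):
        rng = np.random.default_rng(seed)
        arr = (rng.random((5, 8, 8)) < 0.3).astype(np.int64)
        expected = float(arr.max(axis=0).sum())
        assert measure_projected_area(arr, spacing=(1, 1, 1)) == expected


class TestCountWorkflow:
    def test_blank_image_counts_zero(self):
        image = VolumeImage(np.zeros((4, 8, 8)), bit_depth=8)
        result = count_workflow(image)
        assert result.count == 0
        assert len(result.table) == 0

    def test_small_scene_recovers_every_nucleus(self, small_scene):
        _, gt, images = small_scene
        result = count_workflow(images["dapi"])
        assert result.count == gt.n_nuclei

    def test_workflow_is_deterministic(self, small_scene):
        _, _, images = small_scene
        first = count_workflow(images["dapi"])
        second = count_workflow(images["dapi"])
        np.testing.assert_array_equal(first.labels.data, second.labels.data)
        assert first.count == second.count
        assert first.total_volume_um3 == second.total_volume_um3
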