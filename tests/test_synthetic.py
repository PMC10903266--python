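import dataclasses

import numpy as np
import pytest

from epicount import counting, synthetic
from epicount.synthetic import (
    CloneSpec,
    ZygositySpec,
    assign_clones,
    place_nuclei,
    preset_scenes,
    render,
    simulate_scene,
)

from _oracles import pairwise_min_separation
from conftest import small_scene_spec


class TestPlacement:
    def test_single_nucleus_inside_slab(self):
        spec = small_scene_spec(n_nuclei=1)
        gt = place_nuclei(spec, np.random.default_rng(0))
        assert gt.n_nuclei == 1
        z, y, x = gt.centers[0]
        nz, ny, nx = spec.shape
        assert 0 <= z < nz and 0 <= y < ny and 0 <= x < nx
        zmid = (nz - 1) / 2 + spec.slab.fold_amplitude * np.sin(
            2 * np.pi * x / spec.slab.fold_wavelength
        )
        assert abs(z - zmid) <= spec.slab.thickness / 2

    def test_pairwise_separation_respects_min_gap(self):
        spec = small_scene_spec(n_nuclei=40, min_gap=2.0, seed=5)
        gt = place_nuclei(spec, np.random.default_rng(5))
        sep = pairwise_min_separation(gt.centers, gt.radii, spec.nucleus_radii)
        assert sep >= spec.min_gap - 1e-9

    def test_same_seed_reproduces_ground_truth(self):
        spec = small_scene_spec(n_nuclei=30)
        a = place_nuclei(spec, np.random.default_rng(9))
        b = place_nuclei(spec, np.random.default_rng(9))
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_array_equal(a.radii, b.radii)

    def test_impossible_slab_raises(self):
        with pytest.raises(ValueError, match="slab"):
            spec = small_scene_spec(
                slab=synthetic.SlabSpec(thickness=4.0), nucleus_radii=(4.5, 3.0, 3.0)
            )
            place_nuclei(spec, np.random.default_rng(0))


class TestCloneAssignment:
    def _spec(self, **clone_kw):
        return small_scene_spec(
            n_nuclei=60, clone_spec=CloneSpec(**clone_kw), seed=2
        )

    def test_single_clone_exact_size_and_contiguity(self):
        spec = self._spec(n_founders=1, cells_per_clone=5, marked_fraction=1.0)
        gt = assign_clones(place_nuclei(spec, np.random.default_rng(2)), spec,
                           np.random.default_rng(3))
        assert gt.clone_sizes == {1: 5}
        assert (gt.clone_id == 1).sum() == 5

    def test_marked_fraction_zero_leaves_no_marked_clones(self):
        spec = self._spec(n_founders=3, cells_per_clone=4, marked_fraction=0.0)
        gt = assign_clones(place_nuclei(spec, np.random.default_rng(2)), spec,
                           np.random.default_rng(3))
        assert (gt.clone_id == 0).all()
        assert (gt.zygosity == "unmarked").sum() == 12

    def test_requesting_more_cells_than_nuclei_raises(self):
        spec = self._spec(n_founders=4, cells_per_clone=100)
        with pytest.raises(ValueError, match="available"):
            assign_clones(place_nuclei(spec, np.random.default_rng(2)), spec,
                          np.random.default_rng(3))

    def test_clones_are_more_compact_than_random_subsets(self):
        """Over 20 seeds, mean pairwise distance within a clone is smaller
        than within a random subset of equal size."""
        wins = 0
        for seed in range(20):
            spec = self._spec(n_founders=1, cells_per_clone=8, marked_fraction=1.0)
            rng = np.random.default_rng(seed)
            gt = assign_clones(place_nuclei(spec, rng), spec, rng)
            members = np.nonzero(gt.clone_id == 1)[0]
            random_subset = np.random.default_rng(seed + 500).choice(
                gt.n_nuclei, size=members.size, replace=False
            )

            def mean_pairwise(ix):
                pts = gt.centers[ix]
                d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
                return d[np.triu_indices(len(ix), 1)].mean()

            wins += mean_pairwise(members) < mean_pairwise(random_subset)
        assert wins == 20

    def test_twin_pairs_mark_one_clone_per_event(self):
        spec = self._spec(n_founders=6, cells_per_clone=4, twin_pairs=True)
        gt = assign_clones(place_nuclei(spec, np.random.default_rng(2)), spec,
                           np.random.default_rng(3))
        assert len(gt.clone_sizes) == 3
        assert (gt.zygosity == "homozygous").sum() == 12
        assert (gt.zygosity == "unmarked").sum() == 12


class TestRendering:
    def _noise_free(self, **kw):
        return small_scene_spec(
            noise=synthetic.NoiseSpec(enabled=False), psf_sigma=0.0, **kw
        )

    def test_flat_top_levels_without_noise(self):
        spec = self._noise_free(n_nuclei=1)
        gt = place_nuclei(spec, np.random.default_rng(1))
        gt = assign_clones(gt, spec, np.random.default_rng(1))
        image = render(gt, spec, "dapi")
        inside = np.isclose(
            image.data, round(spec.intensity.base + spec.intensity.background)
        )
        assert inside.sum() > 0
        outside_value = round(spec.intensity.background)
        assert (image.data[~inside] == outside_value).all()

    def test_twin_channel_dose_ratio_is_two(self):
        """With a flat field and no noise, homozygous nuclei are exactly
        twice as bright as heterozygous ones."""
        spec = self._noise_free(
            n_nuclei=40,
            clone_spec=CloneSpec(n_founders=4, cells_per_clone=4, twin_pairs=True),
            zygosity_spec=ZygositySpec(field_amplitude=(1.0, 1.0)),
            intensity=synthetic.IntensitySpec(base=180.0, background=0.0),
        )
        rng = np.random.default_rng(4)
        gt = assign_clones(place_nuclei(spec, rng), spec, rng)
        image = render(gt, spec, "twin")
        centers = np.rint(gt.centers).astype(int)
        values = image.data[centers[:, 0], centers[:, 1], centers[:, 2]].astype(float)
        het = values[gt.zygosity == "heterozygous"].mean()
        hom = values[gt.zygosity == "homozygous"].mean()
        assert hom / het == pytest.approx(spec.zygosity_spec.hom_multiplier, rel=0.01)

    def test_channels_render_expected_nucleus_sets(self):
        spec = self._noise_free(
            n_nuclei=40,
            clone_spec=CloneSpec(n_founders=4, cells_per_clone=4, twin_pairs=True),
            intensity=synthetic.IntensitySpec(base=180.0, background=0.0),
        )
        rng = np.random.default_rng(6)
        gt = assign_clones(place_nuclei(spec, rng), spec, rng)
        centers = np.rint(gt.centers).astype(int)
        for channel in ("dapi", "marker", "twin"):
            image = render(gt, spec, channel)
            lit = image.data[centers[:, 0], centers[:, 1], centers[:, 2]] > 0
            assert lit.sum() == len(gt.channel_indices(channel))

    def test_unknown_channel_rejected(self):
        spec = self._noise_free(n_nuclei=2)
        gt = place_nuclei(spec, np.random.default_rng(0))
        with pytest.raises(ValueError, match="channel"):
            render(gt, spec, "gfp")

    def test_marker_channel_requires_clone_assignment(self):
        spec = self._noise_free(n_nuclei=2)
        gt = place_nuclei(spec, np.random.default_rng(0))
        with pytest.raises(ValueError, match="assign_clones"):
            render(gt, spec, "marker")

    def test_identical_seed_renders_identical_images(self):
        gt1, imgs1 = simulate_scene(small_scene_spec(n_nuclei=20), seed=3)
        gt2, imgs2 = simulate_scene(small_scene_spec(n_nuclei=20), seed=3)
        for channel in imgs1:
            np.testing.assert_array_equal(imgs1[channel].data, imgs2[channel].data)

    def test_midpoint_threshold_recovers_component_count(self):
        """Sanity link to the counting module: with min_gap >= 2, PSF <= 1
        and noise off, thresholding at the midpoint intensity gives exactly
        one connected component per nucleus."""
        spec = small_scene_spec(
            n_nuclei=50,
            min_gap=2.0,
            psf_sigma=1.0,
            noise=synthetic.NoiseSpec(enabled=False),
            seed=8,
        )
        gt, images = simulate_scene(spec, channels=("dapi",))
        data = images["dapi"].data
        midpoint = (spec.intensity.base + spec.intensity.background) / 2
        comps = counting.connected_components((data > midpoint).astype(np.int8), 26)
        assert comps.max() == gt.n_nuclei


class TestPresets:
    def test_presets_satisfy_spec_invariants(self):
        for name, spec in preset_scenes().items():
            assert min(spec.nucleus_radii) >= 1
            assert spec.min_gap >= 0
            assert spec.zygosity_spec.hom_multiplier > 1
            lo, hi = spec.zygosity_spec.field_amplitude
            assert lo > 0 and hi >= lo

    def test_regional_field_is_positive_and_spans_amplitude(self):
        rng = np.random.default_rng(0)
        field = synthetic.regional_field((120, 120), (0.5, 1.5), 40.0, rng)
        assert field.min() == pytest.approx(0.5, abs=1e-6)
        assert field.max() == pytest.approx(1.5, abs=1e-6)
        assert (field > 0).all()

    def test_twin_spot_hard_defeats_global_ordering(self):
        """Under the strong regional field, some heterozygous nuclei are
        brighter in absolute terms than some homozygous nuclei."""
        spec = dataclasses.replace(
            preset_scenes()["twin_spot_hard"], shape=(40, 220, 220), n_nuclei=330
        )
        spec = dataclasses.replace(
            spec,
            clone_spec=dataclasses.replace(spec.clone_spec, n_founders=24),
            zygosity_spec=dataclasses.replace(
                spec.zygosity_spec, field_correlation_px=50.0
            ),
        )
        gt, images = simulate_scene(spec, seed=1, channels=("twin",))
        data = images["twin"].data
        centers = np.rint(gt.centers).astype(int)
        values = data[centers[:, 0], centers[:, 1], centers[:, 2]].astype(float)
        het = values[gt.zygosity == "heterozygous"]
        hom = values[gt.zygosity == "homozygous"]
        assert het.max() > hom.min()

    def test_all_presets_generate_with_seed_zero(self):
        for name in preset_scenes():
            spec = preset_scenes()[name]
            # scale down so every preset geometry is exercised quickly
            spec = dataclasses.replace(
                spec,
                shape=(spec.shape[0], spec.shape[1] // 2, spec.shape[2] // 2),
                n_nuclei=max(spec.n_nuclei // 4, 30),
            )
            if spec.clone_spec.n_founders:
                spec = dataclasses.replace(
                    spec,
                    clone_spec=dataclasses.replace(
                        spec.clone_spec,
                        n_founders=max(spec.clone_spec.n_founders // 4, 2),
                        founder_min_separation=min(
                            spec.clone_spec.founder_min_separation, 40.0
                        ),
                    ),
                )
            gt, images = simulate_scene(spec, seed=0, channels=("dapi",))
            assert gt.n_nuclei > 0
            assert images["dapi"].data.max() > 0
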