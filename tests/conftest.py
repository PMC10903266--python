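import numpy as np
import pytest

from epicount import synthetic
from epicount.volumes import VolumeImage


def small_scene_spec(**overrides) -> synthetic.SceneSpec:
    """A scaled-down scene for unit tests: same physics, ~1% of the voxels."""
    defaults = dict(
        shape=(28, 96, 96),
        n_nuclei=70,
        slab=synthetic.SlabSpec(thickness=18.0, fold_amplitude=3.0, fold_wavelength=80.0),
        seed=0,
    )
    defaults.update(overrides)
    return synthetic.SceneSpec(**defaults)


@pytest.fixture(scope="session")
def small_scene():
    """One small rendered scene with clones, shared across unit tests."""
    spec = small_scene_spec(
        clone_spec=synthetic.CloneSpec(
            n_founders=3, cells_per_clone=(3, 6), marked_fraction=1.0,
            founder_min_separation=35.0, max_link_gap=6.0,
        )
    )
    gt, images = synthetic.simulate_scene(spec, seed=11, channels=("dapi", "marker"))
    return spec, gt, images


def single_nucleus_image(level=180.0, background=0.0, shape=(16, 32, 32), radii=(4, 5, 5)):
    """A noise-free flat-top ellipsoid, painted directly."""
    data = np.full(shape, background, dtype=np.float64)
    cz, cy, cx = [(s - 1) / 2 for s in shape]
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    inside = (
        ((zz - cz) / radii[0]) ** 2
        + ((yy - cy) / radii[1]) ** 2
        + ((xx - cx) / radii[2]) ** 2
        <= 1
    )
    data[inside] = level
    return VolumeImage(data=data, spacing=(0.3, 1.0, 1.0), bit_depth=8, name="fixture")


def random_labels(rng, shape=(14, 14, 14), n_blobs=6, r_max=3) -> np.ndarray:
    """Random small labeled blobs for oracle-equivalence tests."""
    labels = np.zeros(shape, dtype=np.int64)
    for lab in range(1, n_blobs + 1):
        c = rng.uniform(0, np.array(shape) - 1)
        r = rng.uniform(1.0, r_max, size=3)
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        inside = (
            ((zz - c[0]) / r[0]) ** 2 + ((yy - c[1]) / r[1]) ** 2 + ((xx - c[2]) / r[2]) ** 2
            <= 1
        )
        labels[inside] = lab
    return labels
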