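"""Total nuclear counting in dense 3D epithelia.

The workflow segments every stained nucleus in a z-stack and counts them:

1. 3D Gaussian blur (default sigma 2 voxels) to suppress shot noise;
2. intensity inversion, so nuclei become catchment basins;
3. classic (unseeded) flooding watershed restricted to voxels at or below
   an intensity bound — on the inverted image the bound excludes the
   bright background — with divide lines left as background;
4. connected-components labeling (26-connectivity by default);
5. removal of objects smaller than a voxel threshold (default 10);
6. consecutive relabeling, after which the maximum label over the stack's
   maximum projection *is* the nucleus count.

Morphometry follows the same segmentation: each label is expanded one
voxel into background (Chebyshev metric, nearer label wins, ties to the
lower id) so that the inter-label divide space is attributed to cells, and
per-label volumes are summed; projected area is the nonzero-pixel count of
the z maximum projection times the pixel area.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from .volumes import LabelVolume, VolumeImage

__all__ = [
    "CountingConfig",
    "CountResult",
    "smooth_and_invert",
    "watershed_segment",
    "connected_components",
    "filter_small_labels",
    "remap_labels",
    "count_nuclei",
    "expand_labels_chebyshev",
    "measure_volumes",
    "measure_projected_area",
    "count_workflow",
]

logger = logging.getLogger(__name__)

_STRUCTS = {
    26: np.ones((3, 3, 3), dtype=bool),
    6: ndi.generate_binary_structure(3, 1),
}
# skimage's connectivity argument counts offset ranks, not neighbours
_SKIMAGE_CONN = {26: 3, 6: 1}


def _structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTS[int(connectivity)]
    except KeyError:
        raise ValueError(f"connectivity must be 26 or 6, got {connectivity!r}") from None


@dataclasses.dataclass
class CountingConfig:
    """Parameters of the nuclear-counting workflow.

    ``watershed_max_intensity`` defaults to 250 for 8-bit input; for
    16-bit input the default scales to ``65535 - 5*256`` with a warning,
    and should be profiled from the image background (set it a few points
    below the inverted background level) for best results.
    """

    gaussian_sigma: float = 2.0
    watershed_max_intensity: Optional[float] = None
    connectivity: int = 26
    min_object_voxels: int = 10
    flooding_connectivity: int = 26
    sigma_in_physical_units: bool = False

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.min_object_voxels < 1:
            raise ValueError("min_object_voxels must be >= 1")
        _structure(self.connectivity)
        _structure(self.flooding_connectivity)

    def resolve_max_intensity(self, bit_depth: int) -> float:
        if self.watershed_max_intensity is not None:
            max_value = (1 << bit_depth) - 1
            if self.watershed_max_intensity >= max_value:
                raise ValueError(
                    f"watershed_max_intensity must be < {max_value} "
                    f"for {bit_depth}-bit data"
                )
            return float(self.watershed_max_intensity)
        if bit_depth == 8:
            return 250.0
        bound = float((1 << 16) - 1 - 5 * 256)
        logger.warning(
            "no watershed bound configured for 16-bit input; using %.0f. "
            "Profile the image background and set the bound a few points "
            "below the inverted background level.",
            bound,
        )
        return bound


def smooth_and_invert(image: VolumeImage, config: Optional[CountingConfig] = None) -> VolumeImage:
    """3D Gaussian blur followed by intensity inversion.

    The sigma is isotropic in voxel units by default (matching a
    pixel-specified blur despite z anisotropy); with
    ``sigma_in_physical_units`` it is interpreted in µm and divided by the
    per-axis spacing.  The result is kept in floating point to avoid
    re-quantization; inversion maps ``v -> (2**bit_depth - 1) - v``.
    """
    config = config or CountingConfig()
    data = np.asarray(image.data, dtype=np.float64)
    if config.gaussian_sigma > 0:
        if config.sigma_in_physical_units:
            sigma = tuple(config.gaussian_sigma / s for s in image.spacing)
        else:
            sigma = config.gaussian_sigma
        data = ndi.gaussian_filter(data, sigma=sigma)
    inverted = float(image.max_value) - data
    return image.with_data(np.clip(inverted, 0.0, image.max_value), "|prepared")


def watershed_segment(prepared: VolumeImage, config: Optional[CountingConfig] = None) -> LabelVolume:
    """Unseeded flooding watershed of the smoothed, inverted image.

    Flooding starts from every regional minimum whose voxels lie at or
    below ``watershed_max_intensity`` (equivalently "one point below the
    image minimum" upward to the bound) and is restricted to that mask;
    voxels above the bound and divide lines where basins meet stay
    background.
    """
    config = config or CountingConfig()
    bound = config.resolve_max_intensity(prepared.bit_depth)
    data = np.asarray(prepared.data, dtype=np.float64)
    mask = data <= bound
    if not mask.any():
        logger.info("watershed: no voxel at or below %.6g — empty labeling", bound)
        return LabelVolume(np.zeros(data.shape, dtype=np.int32), spacing=prepared.spacing)
    # a finite sentinel above the bound keeps out-of-mask voxels from
    # forming or joining minima plateaus
    sentinel = float(data.max()) + 1.0
    guarded = np.where(mask, data, sentinel)
    minima = local_minima(guarded, connectivity=_SKIMAGE_CONN[config.flooding_connectivity])
    minima &= mask
    markers, n_markers = ndi.label(minima, structure=_structure(config.flooding_connectivity))
    if n_markers == 0:  # pragma: no cover - mask.any() implies a minimum exists
        return LabelVolume(np.zeros(data.shape, dtype=np.int32), spacing=prepared.spacing)
    labels = watershed(
        data,
        markers=markers,
        mask=mask,
        connectivity=_structure(config.flooding_connectivity),
    ).astype(np.int64)
    # Carve divide lines where basins meet: at every label-label contact the
    # voxel on the higher-label side becomes background, so no two distinct
    # labels remain adjacent under the flooding connectivity and each pair
    # of basins is separated by a one-voxel divide (deterministic tie-break:
    # the line is taken from the higher-labeled basin).
    sentinel_label = labels.max() + 1
    guarded_labels = np.where(labels > 0, labels, sentinel_label)
    smallest_neighbor = ndi.minimum_filter(
        guarded_labels,
        footprint=_structure(config.flooding_connectivity),
        mode="constant",
        cval=sentinel_label,
    )
    labels[(labels > 0) & (smallest_neighbor < labels)] = 0
    logger.info("watershed: %d basins", n_markers)
    return LabelVolume(labels.astype(np.int32), spacing=prepared.spacing)


def _as_label_array(labels: Union[LabelVolume, np.ndarray]) -> np.ndarray:
    return labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)


def _wrap_like(template, data: np.ndarray):
    if isinstance(template, LabelVolume):
        return template.with_data(data)
    if isinstance(template, VolumeImage):
        return LabelVolume(data, spacing=template.spacing)
    return data


def _scan_order_lut(labels: np.ndarray) -> np.ndarray:
    """LUT renumbering non-zero labels by first appearance in scan order."""
    flat = labels.ravel()
    ids, first = np.unique(flat, return_index=True)
    keep = ids != 0
    ids, first = ids[keep], first[keep]
    order = np.argsort(first, kind="stable")
    lut = np.zeros(int(flat.max(initial=0)) + 1, dtype=np.int64)
    lut[ids[order]] = np.arange(1, ids.size + 1)
    return lut


def connected_components(
    binary_or_labels: Union[LabelVolume, np.ndarray], connectivity: int = 26
):
    """Label maximal connected foreground (non-zero) components.

    Components are numbered 1..K in first-voxel scan order.  Accepts a
    binary mask or an existing labeling (treated as foreground = nonzero);
    returns the same kind of object it was given.
    """
    arr = _as_label_array(binary_or_labels)
    foreground = arr > 0 if arr.dtype != bool else arr
    raw, _ = ndi.label(foreground, structure=_structure(connectivity))
    if raw.max() == 0:
        out = raw.astype(np.int32)
    else:
        out = _scan_order_lut(raw)[raw]
    return _wrap_like(binary_or_labels, out)


def filter_small_labels(labels: Union[LabelVolume, np.ndarray], min_voxels: int):
    """Set every label with fewer than ``min_voxels`` voxels to background.

    Surviving ids are preserved (not yet remapped), matching the
    label-size-filter-then-remap order of the counting workflow.
    """
    arr = _as_label_array(labels)
    if arr.max(initial=0) == 0 or min_voxels <= 1:
        return _wrap_like(labels, arr.copy())
    counts = np.bincount(arr.ravel())
    lut = np.arange(counts.size, dtype=np.int64)
    lut[counts < int(min_voxels)] = 0
    lut[0] = 0
    return _wrap_like(labels, lut[arr])


def remap_labels(labels: Union[LabelVolume, np.ndarray]):
    """Renumber labels to consecutive ``{1..K}`` by first-appearance order."""
    arr = _as_label_array(labels)
    if arr.max(initial=0) == 0:
        return _wrap_like(labels, arr.astype(np.int64))
    return _wrap_like(labels, _scan_order_lut(arr)[arr])


def count_nuclei(labels: LabelVolume) -> int:
    """Nucleus count as the maximum of the z maximum projection.

    Only valid after :func:`remap_labels`; raises if the maximum label
    does not equal the number of distinct labels present.
    """
    arr = _as_label_array(labels)
    projection = arr.max(axis=0) if arr.size else np.zeros((1, 1), dtype=int)
    top = int(projection.max(initial=0))
    n_distinct = int(np.unique(arr[arr > 0]).size)
    if top != n_distinct:
        raise ValueError(
            f"labels are not remapped: max label {top} != {n_distinct} distinct labels"
        )
    return top


def expand_labels_chebyshev(labels: np.ndarray, distance: int = 1) -> np.ndarray:
    """Grow every label ``distance`` voxels into background.

    Growth uses the full 26-neighborhood (Chebyshev metric), so an
    isolated label gains one cubic shell per step.  Labels never overwrite
    other labels; a background voxel reachable from several labels goes to
    the nearer one, with exact ties broken by the lower label id.
    """
    out = np.asarray(labels).astype(np.int64, copy=True)
    if out.max(initial=0) == 0:
        return out
    sentinel = out.max() + 1
    footprint = np.ones((3, 3, 3), dtype=bool)
    for _ in range(int(distance)):
        guarded = np.where(out > 0, out, sentinel)
        nearest = ndi.minimum_filter(guarded, footprint=footprint, mode="constant", cval=sentinel)
        grow = (out == 0) & (nearest < sentinel)
        if not grow.any():
            break
        out[grow] = nearest[grow]
    return out


_TABLE_COLUMNS = [
    "label",
    "voxel_count",
    "expanded_voxels",
    "volume_um3",
    "centroid_z",
    "centroid_y",
    "centroid_x",
    "mean_intensity",
    "max_intensity",
]


def measure_volumes(
    labels: LabelVolume,
    spacing: Optional[Tuple[float, float, float]] = None,
    intensity_image: Optional[np.ndarray] = None,
    expand_px: int = 1,
) -> Tuple[pd.DataFrame, float]:
    """Per-nucleus morphometry table and the summed total volume.

    Each label is expanded ``expand_px`` voxels into background (so the
    divide space between adjacent cells is counted as cell volume, per the
    volume-approximation recipe) and its volume is
    ``expanded voxel count × voxel volume`` in µm³.  Centroids and
    intensity statistics are measured on the *unexpanded* labels.
    """
    spacing = spacing or labels.spacing
    voxel_volume = float(np.prod(spacing))
    arr = labels.data
    ids = labels.label_set()
    if ids.size == 0:
        return pd.DataFrame(columns=_TABLE_COLUMNS), 0.0
    expanded = expand_labels_chebyshev(arr, expand_px) if expand_px > 0 else arr
    counts = np.bincount(arr.ravel(), minlength=int(ids.max()) + 1)
    counts_exp = np.bincount(expanded.ravel(), minlength=int(ids.max()) + 1)

    centroids = np.asarray(ndi.center_of_mass(np.ones(arr.shape), arr, ids))
    if intensity_image is not None:
        src = np.asarray(intensity_image, dtype=np.float64)
        means = ndi.mean(src, labels=arr, index=ids)
        maxima = ndi.maximum(src, labels=arr, index=ids)
    else:
        means = np.full(ids.size, np.nan)
        maxima = np.full(ids.size, np.nan)

    table = pd.DataFrame(
        {
            "label": ids.astype(int),
            "voxel_count": counts[ids].astype(int),
            "expanded_voxels": counts_exp[ids].astype(int),
            "volume_um3": counts_exp[ids] * voxel_volume,
            "centroid_z": centroids[:, 0],
            "centroid_y": centroids[:, 1],
            "centroid_x": centroids[:, 2],
            "mean_intensity": np.asarray(means, dtype=float),
            "max_intensity": np.asarray(maxima, dtype=float),
        },
        columns=_TABLE_COLUMNS,
    )
    total_volume = float(table["volume_um3"].sum())
    return table, total_volume


def measure_projected_area(
    labels_or_mask: Union[LabelVolume, VolumeImage, np.ndarray],
    spacing: Optional[Tuple[float, float, float]] = None,
) -> float:
    """Area (µm²) of the nonzero footprint of the z maximum projection."""
    if isinstance(labels_or_mask, (LabelVolume, VolumeImage)):
        spacing = spacing or labels_or_mask.spacing
        arr = labels_or_mask.data
    else:
        arr = np.asarray(labels_or_mask)
        if spacing is None:
            raise ValueError("spacing required for a bare array")
    projection = arr.max(axis=0)
    return float(np.count_nonzero(projection)) * float(spacing[1]) * float(spacing[2])


@dataclasses.dataclass
class CountResult:
    """Output bundle of :func:`count_workflow`."""

    labels: LabelVolume
    table: pd.DataFrame
    count: int
    total_volume_um3: float
    projected_area_um2: float


def count_workflow(image: VolumeImage, config: Optional[CountingConfig] = None) -> CountResult:
    """Run the full counting workflow: smooth, invert, watershed, label,
    size-filter, remap, count, and measure volumes/areas."""
    config = config or CountingConfig()
    logger.info("counting %s: shape %s, bit depth %d", image.name or "<stack>", image.shape, image.bit_depth)
    prepared = smooth_and_invert(image, config)
    ws = watershed_segment(prepared, config)
    cc = connected_components(ws, config.connectivity)
    logger.info("connected components: %d", cc.max_label)
    filtered = filter_small_labels(cc, config.min_object_voxels)
    remapped = remap_labels(filtered)
    count = count_nuclei(remapped)
    logger.info("nuclei after size filter (<%d voxels removed): %d", config.min_object_voxels, count)
    table, total_volume = measure_volumes(remapped, intensity_image=image.data)
    area = measure_projected_area(remapped)
    logger.info("total volume %.1f um^3, projected area %.1f um^2", total_volume, area)
    return CountResult(
        labels=remapped,
        table=table,
        count=count,
        total_volume_um3=total_volume,
        projected_area_um2=area,
    )
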