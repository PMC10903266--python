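"""Clone segmentation and per-clone statistics.

Clones of cells share a nuclear fluorescent marker, so after nuclear
segmentation of the marker channel the member nuclei of a clone are
separated only by thin watershed divides.  Dilating the nucleus labels by
one voxel closes those divides; connected-components labeling of the
binarized result then yields one component per clone.  Components smaller
than ``min_clone_voxels`` (default 100) are removed as noise, and clones
with fewer than ``min_cells_per_clone`` members (default 5) are flagged as
discarded from summary statistics while remaining in the full table so
that conservation (every segmented nucleus accounted for) stays checkable.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import counting
from .counting import (
    CountingConfig,
    CountResult,
    connected_components,
    count_nuclei,
    expand_labels_chebyshev,
    filter_small_labels,
    remap_labels,
)
from .volumes import LabelVolume, VolumeImage

__all__ = [
    "CloneConfig",
    "CloneResult",
    "dilate_labels",
    "huang_threshold",
    "identify_clones",
    "per_clone_counts",
    "clone_workflow",
]

logger = logging.getLogger(__name__)

CLONE_TABLE_COLUMNS = [
    "clone_id",
    "cell_count",
    "member_ids",
    "voxel_count",
    "volume_um3",
    "projected_area_um2",
    "discarded",
]


@dataclasses.dataclass
class CloneConfig:
    """Parameters of the clone-analysis workflow."""

    dilation_voxels: int = 1
    min_clone_voxels: int = 100
    min_cells_per_clone: int = 5
    binarization: str = "nonzero"

    def __post_init__(self) -> None:
        if self.dilation_voxels < 1:
            raise ValueError("dilation_voxels must be >= 1")
        if self.min_clone_voxels < 1:
            raise ValueError("min_clone_voxels must be >= 1")
        if self.min_cells_per_clone < 1:
            raise ValueError("min_cells_per_clone must be >= 1")
        if self.binarization not in ("nonzero", "huang"):
            raise ValueError("binarization must be 'nonzero' or 'huang'")


def dilate_labels(nuclei: Union[LabelVolume, np.ndarray], voxels: int = 1):
    """Grow each label ``voxels`` steps into background (26-neighborhood
    shells; nearer label wins, ties to the lower id)."""
    arr = nuclei.data if isinstance(nuclei, LabelVolume) else np.asarray(nuclei)
    out = expand_labels_chebyshev(arr, voxels)
    if isinstance(nuclei, LabelVolume):
        return nuclei.with_data(out)
    return out


def huang_threshold(histogram: np.ndarray) -> int:
    """Huang's fuzzy thresholding on an intensity histogram.

    For a candidate threshold ``t`` the gray levels at or below ``t`` form
    the background with mean ``mu0`` and the rest the foreground with mean
    ``mu1``.  Each level ``g`` gets a fuzzy membership
    ``1 / (1 + |g - mu_side| / C)`` with ``C`` the occupied gray range,
    and the threshold minimizing the Shannon entropy of the memberships is
    returned (lowest ``t`` on ties; foreground = values > t).
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size < 1 or hist.sum() <= 0:
        raise ValueError("histogram must be a nonempty 1D array of counts")
    nonzero = np.nonzero(hist)[0]
    first, last = int(nonzero[0]), int(nonzero[-1])
    if first == last:
        logger.info("huang_threshold: single-valued histogram, returning %d", first)
        return first
    levels = np.arange(hist.size, dtype=np.float64)
    span = float(last - first)
    cum_w = np.cumsum(hist)
    cum_s = np.cumsum(hist * levels)
    total_w, total_s = cum_w[-1], cum_s[-1]

    best_t, best_entropy = first, np.inf
    for t in range(first, last):
        w0 = cum_w[t]
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:  # pragma: no cover - t spans [first, last)
            continue
        mu0 = cum_s[t] / w0
        mu1 = (total_s - cum_s[t]) / w1
        mu = np.where(
            levels <= t,
            1.0 / (1.0 + np.abs(levels - mu0) / span),
            1.0 / (1.0 + np.abs(levels - mu1) / span),
        )
        # memberships lie in (1/2, 1]; entropy term vanishes at mu == 1
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -mu * np.log(mu) - (1.0 - mu) * np.log1p(-mu)
        ent[~np.isfinite(ent)] = 0.0
        entropy = float(np.dot(hist, ent))
        if entropy < best_entropy - 1e-12:
            best_entropy = entropy
            best_t = t
    return int(best_t)


def _binarize(dilated: np.ndarray, mode: str) -> np.ndarray:
    if mode == "nonzero":
        return dilated > 0
    # Huang thresholding of the *label* image, for fidelity with macro
    # pipelines that binarize labels via an automatic threshold.  Label ids
    # are not intensities, so low-id nuclei can fall below the threshold;
    # the default 'nonzero' mode avoids that failure mode.
    logger.warning(
        "binarization='huang' thresholds label *ids*; low-id nuclei below the "
        "threshold are silently dropped. Prefer 'nonzero'."
    )
    top = int(dilated.max())
    if top == 0:
        return dilated > 0
    nbins = 256
    scaled = (dilated.astype(np.float64) * (nbins - 1) / top).astype(np.int64)
    hist = np.bincount(scaled.ravel(), minlength=nbins)
    t = huang_threshold(hist)
    return scaled > t


def identify_clones(
    nuclei: LabelVolume, config: Optional[CloneConfig] = None
) -> LabelVolume:
    """Merge watershed-adjacent nuclei into clone components.

    dilate -> binarize -> 26-connected components -> drop components
    smaller than ``min_clone_voxels`` -> remap.
    """
    config = config or CloneConfig()
    dilated = expand_labels_chebyshev(nuclei.data, config.dilation_voxels)
    mask = _binarize(dilated, config.binarization)
    comps = connected_components(mask.astype(np.int8), 26)
    kept = filter_small_labels(comps, config.min_clone_voxels)
    clones = remap_labels(kept)
    out = LabelVolume(clones, spacing=nuclei.spacing)
    logger.info("identified %d clone components", out.max_label)
    return out


def per_clone_counts(
    clones: LabelVolume,
    nuclei: LabelVolume,
    config: Optional[CloneConfig] = None,
    nucleus_table: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Assign nuclei to clones and tabulate per-clone statistics.

    A nucleus joins the clone containing the majority of its voxels
    (ties to the lower clone id).  Clones with fewer than
    ``min_cells_per_clone`` members are flagged ``discarded`` but kept in
    the table.  Nucleus ids with no overlap with any retained clone are
    listed in ``table.attrs['unassigned_nuclei']``.
    """
    config = config or CloneConfig()
    if clones.shape != nuclei.shape:
        raise ValueError(
            f"shape mismatch: clones {clones.shape} vs nuclei {nuclei.shape}"
        )
    n_nuc = nuclei.max_label
    n_clo = clones.max_label
    if n_nuc == 0 or n_clo == 0:
        empty = pd.DataFrame(columns=CLONE_TABLE_COLUMNS)
        empty.attrs["unassigned_nuclei"] = list(range(1, n_nuc + 1))
        return empty

    sel = nuclei.data > 0
    nuc_ids = nuclei.data[sel].astype(np.int64)
    clo_ids = clones.data[sel].astype(np.int64)
    overlap = np.bincount(
        nuc_ids * (n_clo + 1) + clo_ids, minlength=(n_nuc + 1) * (n_clo + 1)
    ).reshape(n_nuc + 1, n_clo + 1)

    # majority vote over real clones only; argmax takes the first (lowest
    # clone id) on ties
    votes = overlap[1:, 1:]
    assigned = np.where(votes.sum(axis=1) > 0, np.argmax(votes, axis=1) + 1, 0)
    unassigned = [int(i + 1) for i in np.nonzero(assigned == 0)[0]]

    if nucleus_table is not None and "volume_um3" in nucleus_table.columns:
        vol_by_label = dict(
            zip(nucleus_table["label"].astype(int), nucleus_table["volume_um3"])
        )
    else:
        table, _ = counting.measure_volumes(nuclei)
        vol_by_label = dict(zip(table["label"].astype(int), table["volume_um3"]))

    clone_voxels = np.bincount(clones.data.ravel(), minlength=n_clo + 1)
    pixel_area = float(clones.spacing[1]) * float(clones.spacing[2])
    slices = ndi.find_objects(clones.data)

    rows = []
    for cid in range(1, n_clo + 1):
        members = [int(i + 1) for i in np.nonzero(assigned == cid)[0]]
        sl = slices[cid - 1]
        if sl is not None:
            footprint = (clones.data[sl] == cid).max(axis=0)
            area = float(np.count_nonzero(footprint)) * pixel_area
        else:  # pragma: no cover - every id 1..max_label is present
            area = 0.0
        rows.append(
            {
                "clone_id": cid,
                "cell_count": len(members),
                "member_ids": ";".join(str(m) for m in members),
                "voxel_count": int(clone_voxels[cid]),
                "volume_um3": float(sum(vol_by_label.get(m, 0.0) for m in members)),
                "projected_area_um2": area,
                "discarded": len(members) < config.min_cells_per_clone,
            }
        )
    table = pd.DataFrame(rows, columns=CLONE_TABLE_COLUMNS)
    table.attrs["unassigned_nuclei"] = unassigned
    if unassigned:
        logger.warning("%d nuclei overlap no retained clone", len(unassigned))
    return table


@dataclasses.dataclass
class CloneResult:
    """Output bundle of :func:`clone_workflow`."""

    nuclei: CountResult
    clone_labels: LabelVolume
    table: pd.DataFrame
    n_clones: int
    total_marked_cells: int
    mean_cells_per_clone: float


def clone_workflow(
    marker_image: VolumeImage,
    counting_config: Optional[CountingConfig] = None,
    clone_config: Optional[CloneConfig] = None,
) -> CloneResult:
    """Count marker-channel nuclei, then group them into clones.

    ``n_clones`` counts every clone component surviving the voxel-size
    filter; clones under ``min_cells_per_clone`` are excluded only from
    ``mean_cells_per_clone``.
    """
    clone_config = clone_config or CloneConfig()
    nuc = counting.count_workflow(marker_image, counting_config)
    clone_labels = identify_clones(nuc.labels, clone_config)
    table = per_clone_counts(clone_labels, nuc.labels, clone_config, nuc.table)
    n_clones = count_nuclei(clone_labels) if clone_labels.max_label else 0
    retained = table[~table["discarded"]] if len(table) else table
    mean_cells = float(retained["cell_count"].mean()) if len(retained) else float("nan")
    total_marked = int(table["cell_count"].sum()) if len(table) else 0
    logger.info(
        "%d clones (%d retained), %d marked cells, %.2f cells/clone",
        n_clones,
        len(retained),
        total_marked,
        mean_cells if mean_cells == mean_cells else 0.0,
    )
    return CloneResult(
        nuclei=nuc,
        clone_labels=clone_labels,
        table=table,
        n_clones=n_clones,
        total_marked_cells=total_marked,
        mean_cells_per_clone=mean_cells,
    )
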