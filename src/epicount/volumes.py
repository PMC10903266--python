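"""Core in-memory containers for 3D intensity stacks and label volumes.

Conventions used throughout the package:

* axis order is ``(z, y, x)`` everywhere; TIFF pages map to ``z``;
* voxel indexing is 0-based, physical coordinates are
  ``voxel index * spacing`` (voxel-center convention);
* label 0 is reserved for background; labels are stored in an integer
  dtype of at least 32 bits regardless of any export-format limit.
"""

from __future__ import annotations

import dataclasses
from typing import Tuple

import numpy as np

__all__ = ["VolumeImage", "LabelVolume", "DEFAULT_SPACING"]

#: Fallback physical voxel size (z, y, x) in micrometres when a file carries
#: no calibration: a 0.3 µm optical-section step and unit pixels in-plane.
DEFAULT_SPACING: Tuple[float, float, float] = (0.3, 1.0, 1.0)


def _check_spacing(spacing) -> Tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components (z, y, x), got {spacing!r}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be strictly positive, got {spacing!r}")
    return spacing


@dataclasses.dataclass
class VolumeImage:
    """A single-channel 3D fluorescence stack.

    Parameters
    ----------
    data :
        3D scalar grid indexed ``(z, y, x)``. May be integer or floating
        point; values must lie in ``[0, 2**bit_depth - 1]``.
    spacing :
        Physical voxel size ``(z, y, x)`` in µm.
    bit_depth :
        Nominal acquisition depth, 8 or 16.  This is metadata about the
        intensity scale; intermediate processing may hold float data.
    name :
        Source identifier (file path or synthetic-channel tag).
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = DEFAULT_SPACING
    bit_depth: int = 8
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.data.ndim}")
        z, y, x = self.data.shape
        if z < 1 or y < 2 or x < 2:
            raise ValueError(f"volume too small: shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.data.size:
            lo = float(self.data.min())
            hi = float(self.data.max())
            if lo < 0 or hi > self.max_value:
                raise ValueError(
                    f"intensities [{lo}, {hi}] outside [0, {self.max_value}] "
                    f"for bit depth {self.bit_depth}"
                )

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, name_suffix: str = "") -> "VolumeImage":
        """Return a copy carrying new voxel data and the same calibration."""
        return VolumeImage(
            data=data,
            spacing=self.spacing,
            bit_depth=self.bit_depth,
            name=self.name + name_suffix,
        )


@dataclasses.dataclass
class LabelVolume:
    """A 3D segmentation: 0 = background, positive integers identify objects.

    ``max_label`` is recomputed from the data; after :func:`remap_labels`
    the set of labels present is exactly ``{1..max_label}``.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = DEFAULT_SPACING
    max_label: int = dataclasses.field(init=False, default=0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype {self.data.dtype}")
        if self.data.size and int(self.data.min()) < 0:
            raise ValueError("labels must be non-negative")
        if self.data.dtype.itemsize < 4:
            self.data = self.data.astype(np.int32)
        self.spacing = _check_spacing(self.spacing)
        self.max_label = int(self.data.max()) if self.data.size else 0

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def label_set(self) -> np.ndarray:
        """Sorted array of distinct non-zero labels present."""
        labels = np.unique(self.data)
        return labels[labels > 0]

    @property
    def n_labels(self) -> int:
        return int(self.label_set().size)

    @property
    def is_remapped(self) -> bool:
        """True when labels present are exactly ``{1..max_label}``."""
        return self.n_labels == self.max_label

    def with_data(self, data: np.ndarray) -> "LabelVolume":
        return LabelVolume(data=data, spacing=self.spacing)
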