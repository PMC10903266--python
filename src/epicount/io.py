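"""Reading and writing image stacks, label volumes and result tables.

Supported on-disk formats:

* multi-page grayscale TIFF (8/16-bit images; 16/32-bit label exports),
  pages are z-slices;
* HDF5 with a single 3D ``(z, y, x)`` dataset (default name ``"data"``),
  used as the interchange format with external object classifiers;
* CSV result tables with a header row.

Spacing is read from ImageJ-style TIFF metadata when present (``spacing``
for the z-step, X/YResolution for the pixel size), from HDF5 attributes,
or from an explicit override; otherwise it falls back to
:data:`epicount.volumes.DEFAULT_SPACING` with a warning, since counts are
spacing-independent but volumes and areas are not.
"""

from __future__ import annotations

import logging
import os
import warnings
from typing import Optional, Tuple, Union

import h5py
import numpy as np
import pandas as pd
import tifffile

from .volumes import DEFAULT_SPACING, LabelVolume, VolumeImage

__all__ = [
    "read_stack",
    "read_label_volume",
    "write_stack",
    "write_label_volume",
    "write_h5",
    "write_table",
]

logger = logging.getLogger(__name__)

_H5_SUFFIXES = (".h5", ".hdf5", ".he5")


class MultiChannelError(ValueError):
    """Raised for RGB / multi-channel inputs: split channels first."""


def _bit_depth_for(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise ValueError(
        f"unsupported intensity dtype {dtype}; expected uint8 or uint16"
    )


def _spacing_from_tiff(tif: tifffile.TiffFile) -> Optional[Tuple[float, float, float]]:
    z = y = x = None
    meta = tif.imagej_metadata or {}
    if "spacing" in meta:
        z = float(meta["spacing"])
    page = tif.pages[0]
    try:
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        # a (1, 1) resolution is the writer default, not a calibration
        if xres is not None:
            num, den = xres.value
            if num and den / num != 1.0:
                x = den / num
        if yres is not None:
            num, den = yres.value
            if num and den / num != 1.0:
                y = den / num
    except Exception:  # pragma: no cover - defensive against odd TIFFs
        pass
    if z is None and y is None and x is None:
        return None
    return (z if z else DEFAULT_SPACING[0], y if y else 1.0, x if x else 1.0)


def _read_h5_array(path: str, dataset_name: str = "data"):
    with h5py.File(path, "r") as fh:
        if dataset_name in fh:
            ds = fh[dataset_name]
        else:
            keys = [k for k in fh.keys() if isinstance(fh[k], h5py.Dataset)]
            if not keys:
                raise ValueError(f"no dataset found in {path}")
            ds = fh[keys[0]]
        data = ds[()]
        spacing = ds.attrs.get("spacing")
        spacing = tuple(float(s) for s in spacing) if spacing is not None else None
        bit_depth = ds.attrs.get("bit_depth")
        bit_depth = int(bit_depth) if bit_depth is not None else None
    return data, spacing, bit_depth


def read_stack(
    path: Union[str, os.PathLike],
    spacing_override: Optional[Tuple[float, float, float]] = None,
    dataset_name: str = "data",
) -> VolumeImage:
    """Read a single-channel 3D stack from TIFF or HDF5.

    Raises
    ------
    MultiChannelError
        For RGB or multi-channel files ("split channels first").
    """
    path = os.fspath(path)
    file_spacing = None
    file_bit_depth = None
    if path.lower().endswith(_H5_SUFFIXES):
        data, file_spacing, file_bit_depth = _read_h5_array(path, dataset_name)
    else:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            axes = series.axes.upper()
            if "S" in axes or "C" in axes:
                raise MultiChannelError(
                    f"{path} has axes {axes!r}: split channels first"
                )
            data = series.asarray()
            file_spacing = _spacing_from_tiff(tif)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise MultiChannelError(
            f"{path} is {data.ndim}-D; expected a single-channel z-stack — "
            "split channels first"
        )
    if 0 in data.shape:
        raise ValueError(f"{path} has a zero-sized axis: shape {data.shape}")

    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    elif file_spacing is not None:
        spacing = file_spacing
    else:
        warnings.warn(
            f"{path}: no voxel-spacing metadata; assuming {DEFAULT_SPACING} µm "
            "(z-step 0.3 µm). Volumes/areas will be wrong if this is inaccurate.",
            stacklevel=2,
        )
        spacing = DEFAULT_SPACING

    bit_depth = file_bit_depth or _bit_depth_for(data.dtype)
    return VolumeImage(data=data, spacing=spacing, bit_depth=bit_depth, name=path)


def read_label_volume(
    path: Union[str, os.PathLike],
    spacing: Optional[Tuple[float, float, float]] = None,
    dataset_name: str = "data",
) -> LabelVolume:
    """Read a label volume written by :func:`write_label_volume` / :func:`write_h5`."""
    path = os.fspath(path)
    file_spacing = None
    if path.lower().endswith(_H5_SUFFIXES):
        data, file_spacing, _ = _read_h5_array(path, dataset_name)
    else:
        with tifffile.TiffFile(path) as tif:
            data = tif.series[0].asarray()
            file_spacing = _spacing_from_tiff(tif)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis]
    return LabelVolume(
        data=data.astype(np.int64),
        spacing=spacing or file_spacing or DEFAULT_SPACING,
    )


def write_stack(image: VolumeImage, path: Union[str, os.PathLike]) -> str:
    """Write a VolumeImage as a multi-page grayscale TIFF with ImageJ calibration."""
    path = os.fspath(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    data = np.asarray(np.rint(image.data), dtype=dtype)
    _write_calibrated_tiff(data, path, image.spacing)
    return path


def _write_calibrated_tiff(data: np.ndarray, path: str, spacing) -> None:
    sz, sy, sx = spacing
    if data.dtype in (np.dtype(np.uint8), np.dtype(np.uint16)):
        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
        )
    else:  # 32-bit label exports exceed the ImageJ-TIFF dtype set
        tifffile.imwrite(
            path,
            data,
            photometric="minisblack",
            resolution=(1.0 / sx, 1.0 / sy),
        )


def write_label_volume(
    labels: LabelVolume, path: Union[str, os.PathLike], force_16bit: bool = False
) -> str:
    """Export a label volume as TIFF.

    The file is 16-bit when ``max_label <= 65535`` (the paper-era plugin
    format), 32-bit otherwise.  With ``force_16bit`` an overflow raises
    instead of silently wrapping labels.
    """
    path = os.fspath(path)
    if labels.max_label > 65535:
        if force_16bit:
            raise OverflowError(
                f"max label {labels.max_label} does not fit a 16-bit export"
            )
        dtype = np.uint32
    else:
        dtype = np.uint16
    _write_calibrated_tiff(labels.data.astype(dtype), path, labels.spacing)
    return path


def write_h5(
    image: Union[VolumeImage, LabelVolume],
    path: Union[str, os.PathLike],
    dataset_name: str = "data",
) -> str:
    """Write a volume (image or labels) to HDF5 as one ``(z, y, x)`` dataset."""
    path = os.fspath(path)
    if not path:
        raise ValueError("empty output path")
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset(dataset_name, data=image.data, compression="gzip")
        ds.attrs["spacing"] = np.asarray(image.spacing, dtype=float)
        ds.attrs["axes"] = "zyx"
        if isinstance(image, VolumeImage):
            ds.attrs["bit_depth"] = image.bit_depth
            ds.attrs["kind"] = "intensity"
        else:
            ds.attrs["kind"] = "labels"
    return path


def write_table(records, path: Union[str, os.PathLike]) -> str:
    """Write a result table (DataFrame or list of dicts) as CSV with a header.

    Column order is preserved as given; an empty table yields a header-only
    file when column names are known.
    """
    path = os.fspath(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    df.to_csv(path, index=False)
    logger.info("wrote %d rows to %s", len(df), path)
    return path
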