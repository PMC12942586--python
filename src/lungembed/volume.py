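"""Volumetric CT domain types, file I/O and optional preprocessing filters.

Conventions
-----------
* Voxel arrays are indexed ``(x, y, z)`` with ``z`` the slice axis, 0-based.
  File readers permute into this order (SimpleITK/pydicom buffers are
  ``(z, y, x)``).
* Intensities are signed-integer Hounsfield units.  −5000 is reserved as the
  fill sentinel of segmentation outputs; valid values lie in [−5000, 32767].
* Non-integer intensities arising from format scale factors are rounded
  half-away-from-zero, because downstream histograms are exact integer-HU maps.
* Preprocessing (median/Gaussian) is off by default: the segmentation
  algorithm is specified on raw HU.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pydicom
import SimpleITK as sitk
from scipy import ndimage

from lungembed.errors import FormatError, GeometryError, ParameterError

HU_MIN = -5000  # reserved fill sentinel; nothing below this is a valid voxel
HU_MAX = 32767

_READ_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd", ".nrrd")
_WRITE_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


def _round_half_away_from_zero(a: np.ndarray) -> np.ndarray:
    return np.sign(a) * np.floor(np.abs(a) + 0.5)


def _check_geometry(data: np.ndarray, spacing_mm, origin_mm) -> None:
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D volume, got {data.ndim}D")
    if any(d < 1 for d in data.shape):
        raise GeometryError(f"all dims must be >= 1, got {data.shape}")
    if len(spacing_mm) != 3 or any(s <= 0 for s in spacing_mm):
        raise GeometryError(f"spacing must be 3 positive lengths, got {spacing_mm}")
    if len(origin_mm) != 3:
        raise GeometryError(f"origin must have 3 components, got {origin_mm}")


@dataclass
class CTVolume:
    """A 3D grid of integer HU values with physical geometry metadata.

    Attributes
    ----------
    data : ndarray
        Signed-integer HU values, indexed ``(x, y, z)``.
    spacing_mm : tuple of float
        Voxel edge lengths along (x, y, z) in millimetres.
    origin_mm : tuple of float
        Physical coordinates of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ParameterError(
                f"HU data must be an integer array, got dtype {self.data.dtype}; "
                "round explicitly before constructing a CTVolume"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        _check_geometry(self.data, self.spacing_mm, self.origin_mm)
        lo, hi = int(self.data.min()), int(self.data.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ParameterError(
                f"HU values out of range [{HU_MIN}, {HU_MAX}]: data spans [{lo}, {hi}]"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class SeedPoint:
    """A single 0-based (x, y, z) voxel index, typically placed in the trachea."""

    index: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.index = tuple(int(i) for i in self.index)
        if len(self.index) != 3:
            raise ParameterError(f"seed must have 3 components, got {self.index}")

    def check_in_bounds(self, dims: Sequence[int]) -> None:
        for k in range(3):
            if not (0 <= self.index[k] < dims[k]):
                raise ParameterError(
                    f"seed {self.index} out of bounds for volume of dims {tuple(dims)}"
                )


@dataclass
class LabeledVolume:
    """A segmentation output: original HU at foreground voxels, sentinel elsewhere.

    ``background_value`` marks non-segmented voxels (−5000 for this tool's
    outputs, −3000 in the reference tool's exports).  The foreground mask is
    ``data != background_value``.
    """

    data: np.ndarray
    background_value: int = -5000
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ParameterError("labeled data must be an integer array")
        self.background_value = int(self.background_value)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        _check_geometry(self.data, self.spacing_mm, self.origin_mm)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def foreground(self) -> np.ndarray:
        """Boolean mask of segmented voxels."""
        return self.data != self.background_value

    @property
    def foreground_count(self) -> int:
        return int(self.foreground.sum())


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def read_dicom_series(directory_path: str | os.PathLike) -> CTVolume:
    """Read a single CT DICOM series of 2D slices from a directory.

    Slices are sorted by position along the slice normal; stored values are
    converted to HU via RescaleSlope/RescaleIntercept (both tags required).

    Raises
    ------
    FormatError
        Empty directory, unreadable files, more than one series, or missing
        rescale tags.
    GeometryError
        Slices disagree on shape, pixel spacing or inter-slice distance.
    """
    directory_path = os.fspath(directory_path)
    if not os.path.isdir(directory_path):
        raise FormatError(f"not a directory: {directory_path}")
    datasets = []
    for name in sorted(os.listdir(directory_path)):
        path = os.path.join(directory_path, name)
        if not os.path.isfile(path):
            continue
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue  # non-DICOM files in the directory are ignored
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise FormatError(f"no DICOM image slices found in {directory_path}")

    series_uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series_uids) > 1:
        raise FormatError(
            f"directory contains {len(series_uids)} series; expected exactly one"
        )

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise GeometryError(f"slices have inconsistent shapes: {sorted(shapes)}")

    spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) > 1:
        raise GeometryError(f"slices have inconsistent pixel spacing: {sorted(spacings)}")
    row_spacing, col_spacing = spacings.pop()  # PixelSpacing is (row, col) = (y, x)

    def z_position(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        if hasattr(ds, "SliceLocation"):
            return float(ds.SliceLocation)
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_position)
    positions = [z_position(ds) for ds in datasets]

    if len(datasets) > 1:
        gaps = np.diff(positions)
        if np.any(gaps <= 0):
            raise GeometryError("duplicate or non-monotonic slice positions")
        if not np.allclose(gaps, gaps[0], rtol=1e-3, atol=1e-3):
            raise GeometryError(f"non-uniform inter-slice distances: {gaps.tolist()}")
        z_spacing = float(gaps[0])
    else:
        z_spacing = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    slices = []
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise FormatError(
                "RescaleSlope/RescaleIntercept missing; refusing to guess the HU conversion"
            )
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        slices.append(_round_half_away_from_zero(hu).astype(np.int32))

    stack = np.stack(slices, axis=0)  # (z, y, x)
    data = np.ascontiguousarray(stack.transpose(2, 1, 0))  # -> (x, y, z)

    first = datasets[0]
    if hasattr(first, "ImagePositionPatient"):
        origin = tuple(float(v) for v in first.ImagePositionPatient)
    else:
        origin = (0.0, 0.0, positions[0])

    return CTVolume(
        data=_shrink_int_dtype(data),
        spacing_mm=(col_spacing, row_spacing, z_spacing),
        origin_mm=origin,
    )


# ---------------------------------------------------------------------------
# NIfTI / MetaImage / NRRD
# ---------------------------------------------------------------------------

def _matched_extension(path: str, allowed: Iterable[str]) -> str:
    lower = path.lower()
    for ext in sorted(allowed, key=len, reverse=True):
        if lower.endswith(ext):
            return ext
    raise FormatError(
        f"unsupported file extension for {path!r}; expected one of {tuple(allowed)}"
    )


def _shrink_int_dtype(data: np.ndarray) -> np.ndarray:
    """Store as int16 when the value range permits, else int32."""
    lo, hi = int(data.min()), int(data.max())
    if lo >= np.iinfo(np.int16).min and hi <= np.iinfo(np.int16).max:
        return data.astype(np.int16)
    return data.astype(np.int32)


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a NIfTI (.nii/.nii.gz), MetaImage (.mha/.mhd) or NRRD volume.

    Values are rounded half-away-from-zero to integer HU if the on-disk
    representation applies non-integer scaling.
    """
    path = os.fspath(path)
    _matched_extension(path, _READ_EXTENSIONS)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # pragma: no cover - sitk error text varies
        raise FormatError(f"could not read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise GeometryError(f"expected a 3D image, got {img.GetDimension()}D in {path}")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if not np.issubdtype(arr.dtype, np.integer):
        arr = _round_half_away_from_zero(arr.astype(np.float64)).astype(np.int32)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return CTVolume(
        data=_shrink_int_dtype(data),
        spacing_mm=tuple(img.GetSpacing()),
        origin_mm=tuple(img.GetOrigin()),
    )


def read_labeled(path: str | os.PathLike, background_value: int = -5000) -> LabeledVolume:
    """Read a labeled volume, interpreting ``background_value`` as the sentinel."""
    vol = read_volume(path)
    return LabeledVolume(
        data=vol.data,
        background_value=background_value,
        spacing_mm=vol.spacing_mm,
        origin_mm=vol.origin_mm,
    )


def write_volume(volume: CTVolume | LabeledVolume, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    Values are stored as int16 when the range permits (−5000 fits), else int32;
    spacing and origin are preserved so that ``read_volume`` round-trips
    bit-exactly.
    """
    path = os.fspath(path)
    _matched_extension(path, _WRITE_EXTENSIONS)
    data = _shrink_int_dtype(np.asarray(volume.data))
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(volume.spacing_mm))
    img.SetOrigin(tuple(volume.origin_mm))
    try:
        sitk.WriteImage(img, path)
    except Exception as exc:  # pragma: no cover
        raise IOError(f"could not write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Preprocessing filters (off by default in the segmentation pipeline)
# ---------------------------------------------------------------------------

def median_filter(volume: CTVolume, radius_voxels: int) -> CTVolume:
    """Median-filter with a cubic (2r+1)³ neighbourhood, edge-replicated."""
    radius_voxels = int(radius_voxels)
    if radius_voxels < 1:
        raise ParameterError(f"median radius must be >= 1, got {radius_voxels}")
    size = 2 * radius_voxels + 1
    out = ndimage.median_filter(volume.data, size=size, mode="nearest")
    return CTVolume(out.astype(volume.data.dtype), volume.spacing_mm, volume.origin_mm)


def gaussian_filter(volume: CTVolume, sigma_mm: float) -> CTVolume:
    """Separable Gaussian smoothing with sigma in physical millimetres.

    The per-axis sigma in voxels is ``sigma_mm / spacing_mm``; output is
    rounded back to integer HU.
    """
    sigma_mm = float(sigma_mm)
    if not math.isfinite(sigma_mm) or sigma_mm <= 0:
        raise ParameterError(f"gaussian sigma must be > 0, got {sigma_mm}")
    sigma_vox = [sigma_mm / s for s in volume.spacing_mm]
    smoothed = ndimage.gaussian_filter(
        volume.data.astype(np.float64), sigma=sigma_vox, mode="nearest"
    )
    out = _round_half_away_from_zero(smoothed).astype(volume.data.dtype)
    return CTVolume(out, volume.spacing_mm, volume.origin_mm)
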