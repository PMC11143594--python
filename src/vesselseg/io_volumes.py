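"""Volume and mask containers plus NIfTI / DICOM-series I/O.

The whole package uses one canonical axis order ``(k, i, j)``: ``k`` indexes
slices, ``i`` rows and ``j`` columns within a slice.  Coordinates are 0-based
integer voxel indices.  NIfTI files store data ``(x, y, z)`` = ``(j, i, k)``,
so arrays are transposed on read/write; DICOM series are stacked slice by
slice after sorting by physical slice position.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

__all__ = [
    "VolumeImage",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
]


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with optional per-axis spacing in mm.

    ``data`` is indexed ``[k, i, j]`` (slice, row, column); ``spacing`` is
    ``(dk, di, dj)`` when known, else ``None``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
            if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
                raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A {0,1} grid with the same shape as its companion volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("mask values must be 0 or 1")
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def check_companion(self, volume: VolumeImage) -> None:
        if self.shape != volume.shape:
            raise ValueError(f"mask shape {self.shape} != volume shape {volume.shape}")


def _from_nifti(img: nib.Nifti1Image) -> VolumeImage:
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {arr.shape}")
    data = np.ascontiguousarray(arr.T)  # (x,y,z) -> (k,i,j)
    zooms = img.header.get_zooms()[:3]
    spacing: tuple[float, float, float] | None
    if all(z > 0 for z in zooms):
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    else:
        warnings.warn("NIfTI header has non-positive zooms; spacing left unset")
        spacing = None
    return VolumeImage(data=data, spacing=spacing)


def _read_dicom_dir(path: str) -> VolumeImage:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - pydicom is a hard dep here
        raise RuntimeError("pydicom is required to read DICOM series") from exc

    files = [os.path.join(path, f) for f in sorted(os.listdir(path))]
    slices = []
    for f in files:
        if not os.path.isfile(f):
            continue
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {path!r}")

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return float(ipp[2])
        loc = getattr(ds, "SliceLocation", None)
        if loc is not None:
            return float(loc)
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    data = np.stack([ds.pixel_array for ds in slices], axis=0)

    spacing = None
    ps = getattr(slices[0], "PixelSpacing", None)
    if ps is not None and len(ps) == 2:
        if len(slices) >= 2:
            dz = abs(sort_key(slices[1]) - sort_key(slices[0]))
        else:
            dz = float(getattr(slices[0], "SliceThickness", 0) or 0)
        if dz > 0:
            spacing = (dz, float(ps[0]), float(ps[1]))
        else:
            warnings.warn("DICOM slice spacing could not be determined; spacing left unset")
    else:
        warnings.warn("DICOM PixelSpacing missing; spacing left unset")
    return VolumeImage(data=data, spacing=spacing)


def read_volume(path: str, format: str = "nifti") -> VolumeImage:
    """Read a volume from a NIfTI file or a DICOM series directory.

    Intensities are passed through untouched; interpretation of the scale
    (raw HU vs. rescaled gray) is deferred to calibration.
    """
    if format == "nifti":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        try:
            img = nib.load(path)
        except Exception as exc:
            raise ValueError(f"could not parse {path!r} as NIfTI: {exc}") from exc
        return _from_nifti(img)
    if format == "dicom-dir":
        if not os.path.isdir(path):
            raise FileNotFoundError(path)
        return _read_dicom_dir(path)
    raise ValueError(f"unknown format {format!r}; expected 'nifti' or 'dicom-dir'")


def _to_nifti(data: np.ndarray, spacing) -> nib.Nifti1Image:
    affine = np.eye(4)
    if spacing is not None:
        affine[0, 0], affine[1, 1], affine[2, 2] = spacing[2], spacing[1], spacing[0]
    img = nib.Nifti1Image(np.ascontiguousarray(data.T), affine)
    if spacing is not None:
        img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    return img


def write_volume(volume: VolumeImage, path: str) -> None:
    """Write a volume as NIfTI; integer data round-trips bitwise."""
    nib.save(_to_nifti(volume.data, volume.spacing), path)


def write_mask(mask: BinaryMask, path: str, format: str = "nifti") -> None:
    """Write a binary mask as a uint8 NIfTI file."""
    if format != "nifti":
        raise ValueError(f"masks are written as NIfTI only, got format {format!r}")
    nib.save(_to_nifti(mask.data.astype(np.uint8), mask.spacing), path)


def read_mask(path: str, format: str = "nifti") -> BinaryMask:
    """Read a binary mask; any nonzero voxel is treated as 1."""
    vol = read_volume(path, format=format)
    return BinaryMask(data=(vol.data > 0).astype(np.uint8), spacing=vol.spacing)
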