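"""Volumetric image containers and file I/O.

All in-memory grids use a single fixed axis convention:

    array axis 0 = z (axial, slice direction)
    array axis 1 = y (coronal)
    array axis 2 = x (sagittal)

``spacing`` and ``origin`` are stored in the same (z, y, x) order, in
millimetres.  SimpleITK's (x, y, z) metadata order is converted at the I/O
boundary, so everything downstream (Hessian derivatives, surface distances)
can treat index axes and physical axes consistently.

CT intensities are kept in Hounsfield units exactly as stored on disk
(DICOM rescale slope/intercept applied by the reader, nothing else).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "SeedVolume",
    "read_volume",
    "write_volume",
    "GridMismatchError",
    "VolumeFormatError",
    "SEED_UNLABELLED",
    "SEED_FOREGROUND",
    "SEED_BACKGROUND",
]

# On-disk label encoding for seed images.
SEED_UNLABELLED = 0
SEED_FOREGROUND = 1
SEED_BACKGROUND = 2


class VolumeFormatError(RuntimeError):
    """Raised when a file cannot be read/written as a volumetric image."""


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


def _as_tuple3(v, name: str) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar field with physical grid metadata.

    Parameters
    ----------
    data:
        3D array, (z, y, x).  HU for CT input; dimensionless in [-1, 1]
        for boneness maps.
    spacing:
        Physical voxel size per array axis (z, y, x), mm.  Strictly positive.
    origin:
        Physical position of voxel (0, 0, 0) per array axis (z, y, x), mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        self.spacing = _as_tuple3(self.spacing, "spacing")
        self.origin = _as_tuple3(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume data contains NaN/Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume | BinaryMask | SeedVolume",
                  atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other, what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} grid mismatch: shape/spacing/origin "
                f"{other.shape}/{other.spacing}/{other.origin} vs reference "
                f"{self.shape}/{self.spacing}/{self.origin}"
            )


@dataclass
class BinaryMask:
    """A boolean grid aligned to a source :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError(f"mask values must be two-valued 0/1, got {uniq}")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = _as_tuple3(self.spacing, "spacing")
        self.origin = _as_tuple3(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    shape = ImageVolume.shape
    same_grid = ImageVolume.same_grid
    require_same_grid = ImageVolume.require_same_grid

    @classmethod
    def like(cls, ref: "ImageVolume | BinaryMask | SeedVolume",
             data: np.ndarray) -> "BinaryMask":
        return cls(data=data, spacing=ref.spacing, origin=ref.origin)

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class SeedVolume:
    """Trinary per-voxel labels: 0 unlabelled, 1 foreground, 2 background."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D seed image, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (SEED_UNLABELLED, SEED_FOREGROUND, SEED_BACKGROUND)).all():
            raise ValueError(
                f"seed labels must be in {{0,1,2}} "
                f"(unlabelled/foreground/background), got {uniq}"
            )
        self.data = arr.astype(np.uint8)
        self.spacing = _as_tuple3(self.spacing, "spacing")
        self.origin = _as_tuple3(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    shape = ImageVolume.shape
    same_grid = ImageVolume.same_grid
    require_same_grid = ImageVolume.require_same_grid

    @property
    def foreground(self) -> np.ndarray:
        return self.data == SEED_FOREGROUND

    @property
    def background(self) -> np.ndarray:
        return self.data == SEED_BACKGROUND

    @classmethod
    def like(cls, ref, data: np.ndarray) -> "SeedVolume":
        return cls(data=data, spacing=ref.spacing, origin=ref.origin)


# ---------------------------------------------------------------------------
# File I/O (SimpleITK backend: NIfTI, MetaImage, DICOM series)
# ---------------------------------------------------------------------------

_KNOWN_EXT = (".nii", ".nii.gz", ".mha", ".mhd", ".nrrd")


def _sitk_to_arrays(img: sitk.Image):
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))  # sitk is (x, y, z)
    origin = tuple(reversed(img.GetOrigin()))
    return data, spacing, origin


def read_volume(path: str | os.PathLike, format_hint: str | None = None) -> ImageVolume:
    """Read a volumetric image (NIfTI, MetaImage/NRRD, or DICOM series dir).

    HU values are preserved bit-faithfully for integer inputs; the DICOM
    reader applies rescale slope/intercept (GDCM default) and nothing else.

    Raises
    ------
    VolumeFormatError
        If the path is unreadable or not a recognized format.
    ValueError
        If the stored data contains NaN/Inf or the spacing is non-positive.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file or directory: {path}")
    try:
        if os.path.isdir(path) or format_hint == "dicom":
            reader = sitk.ImageSeriesReader()
            names = reader.GetGDCMSeriesFileNames(path)
            if not names:
                raise VolumeFormatError(f"no DICOM series found in directory: {path}")
            reader.SetFileNames(names)
            img = reader.Execute()
        else:
            img = sitk.ReadImage(path)
    except VolumeFormatError:
        raise
    except Exception as exc:  # sitk raises bare RuntimeError
        raise VolumeFormatError(f"cannot read volume from {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D image, got {img.GetDimension()}D"
        )
    data, spacing, origin = _sitk_to_arrays(img)
    if any(s <= 0 for s in spacing):
        raise VolumeFormatError(
            f"{path}: non-positive voxel spacing {spacing} in metadata; "
            "refusing to default to 1 mm"
        )
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: volume contains non-finite voxels after ingestion")
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def read_mask(path: str | os.PathLike, reference: ImageVolume | None = None) -> BinaryMask:
    """Read a binary mask; optionally validate its grid against a reference."""
    vol = read_volume(path)
    mask = BinaryMask(data=vol.data, spacing=vol.spacing, origin=vol.origin)
    if reference is not None:
        reference.require_same_grid(mask, "mask")
    return mask


def write_volume(vol: ImageVolume | BinaryMask | SeedVolume,
                 path: str | os.PathLike,
                 reference: ImageVolume | None = None) -> None:
    """Write a volume/mask/seed image with its grid metadata.

    Masks are serialized as unsigned 8-bit 0/1, seeds as 0/1/2; scalar
    volumes keep their array dtype.  ``read_volume(write_volume(v))`` is the
    identity on data, spacing and origin for integer and 8-bit payloads.
    """
    path = os.fspath(path)
    if reference is not None and not reference.same_grid(vol):
        raise GridMismatchError(
            f"refusing to write {path}: grid disagrees with declared reference"
        )
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    elif isinstance(vol, SeedVolume):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data
    img = sitk.GetImageFromArray(data)
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    try:
        sitk.WriteImage(img, path)
    except Exception as exc:
        raise VolumeFormatError(f"cannot write volume to {path}: {exc}") from exc
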