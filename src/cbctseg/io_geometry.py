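"""Volumes with physical geometry: reading, writing and resampling.

A scan is a 3-D scalar grid plus the metadata that places it in patient
space: per-axis spacing in millimetres, the world position of voxel
(0, 0, 0), and a 3x3 orthonormal direction matrix.  World coordinates
follow the LPS convention of the ITK/DICOM ecosystem and voxel indices
are 0-based.  Arrays are indexed ``[i, j, k]`` along the (x, y, z)
geometry axes, i.e. ``spacing[0]`` belongs to axis 0 of ``voxels``.

File IO and grid resampling are delegated to SimpleITK; NIfTI-1
(``.nii``/``.nii.gz``) and NRRD files are read and written, DICOM series
directories are read-only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeImage",
    "LabelMap",
    "FormatError",
    "GeometryError",
    "read_volume",
    "write_volume",
    "resample_to_spacing",
    "resample_to_reference",
]

_WRITE_EXTENSIONS = (".nii", ".nii.gz", ".nrrd")


class FormatError(ValueError):
    """Unreadable file, unsupported extension, or non-3D payload."""


class GeometryError(ValueError):
    """Invalid spacing/direction or degenerate reference grid."""


def _validate_geometry(spacing, origin, direction) -> None:
    spacing = np.asarray(spacing, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise GeometryError(f"spacing must be 3 positive finite values, got {spacing}")
    if np.asarray(origin, dtype=float).shape != (3,):
        raise GeometryError("origin must be a 3-vector")
    if direction.shape != (3, 3) or not np.allclose(
        direction.T @ direction, np.eye(3), atol=1e-6
    ):
        raise GeometryError("direction must be a 3x3 orthonormal matrix")


@dataclass(frozen=True)
class VolumeImage:
    """A 3-D intensity grid with physical geometry.

    Parameters
    ----------
    voxels : ndarray
        3-D scalar array indexed ``[i, j, k]`` along the (x, y, z) axes.
    spacing : ndarray
        Voxel edge lengths in mm, one per axis; all > 0.
    origin : ndarray
        World (LPS) coordinates of voxel (0, 0, 0), mm.
    direction : ndarray
        3x3 orthonormal matrix mapping index axes to world axes.
    """

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise FormatError(f"expected a 3-D grid, got shape {vox.shape}")
        _validate_geometry(self.spacing, self.origin, self.direction)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def same_geometry(self, other: "VolumeImage | LabelMap", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_voxels(self, voxels: np.ndarray):
        return replace(self, voxels=voxels)


@dataclass(frozen=True)
class LabelMap(VolumeImage):
    """An integer class-label grid sharing :class:`VolumeImage` geometry."""

    def __post_init__(self):
        super().__post_init__()
        vox = np.asarray(self.voxels)
        if not np.issubdtype(vox.dtype, np.integer):
            if not np.array_equal(vox, np.round(vox)):
                raise FormatError("label map voxels must be integers")
            vox = vox.astype(np.int32)
        if vox.size and vox.min() < 0:
            raise FormatError("label values must be nonnegative")
        object.__setattr__(self, "voxels", vox)


def _from_sitk(img: sitk.Image, as_label: bool):
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 1:
        raise FormatError(
            f"expected a scalar 3-D volume, got dimension {img.GetDimension()} "
            f"with {img.GetNumberOfComponentsPerPixel()} components per voxel"
        )
    # SimpleITK arrays come back [z, y, x]; store [x, y, z].
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    cls = LabelMap if as_label else VolumeImage
    return cls(
        voxels=arr,
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=np.array(img.GetDirection()).reshape(3, 3),
    )


def _to_sitk(img: VolumeImage) -> sitk.Image:
    out = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(img.voxels, (2, 1, 0))))
    out.SetSpacing(tuple(float(s) for s in img.spacing))
    out.SetOrigin(tuple(float(o) for o in img.origin))
    out.SetDirection(tuple(img.direction.ravel()))
    return out


def read_volume(path: str | os.PathLike, as_label: bool = False) -> VolumeImage | LabelMap:
    """Read a NIfTI/NRRD file or a DICOM series directory.

    Geometry is taken from the header unmodified.  ``as_label=True``
    returns a :class:`LabelMap` (the payload must be integral).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file or directory: {path}")
    try:
        if os.path.isdir(path):
            reader = sitk.ImageSeriesReader()
            files = reader.GetGDCMSeriesFileNames(path)
            if not files:
                raise FormatError(f"no DICOM series found in directory: {path}")
            reader.SetFileNames(files)
            img = reader.Execute()
        else:
            img = sitk.ReadImage(path)
    except FormatError:
        raise
    except RuntimeError as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    return _from_sitk(img, as_label)


def write_volume(img: VolumeImage | LabelMap, path: str | os.PathLike) -> None:
    """Write to NIfTI (.nii/.nii.gz) or NRRD; round-trips voxels bit-exactly."""
    path = os.fspath(path)
    if not path.endswith(_WRITE_EXTENSIONS):
        raise FormatError(
            f"unsupported extension on {path!r}; use one of {_WRITE_EXTENSIONS}"
        )
    vox = img.voxels
    if isinstance(img, LabelMap):
        img = replace(img, voxels=vox.astype(np.uint16 if vox.max(initial=0) < 2**16 else np.int32))
    elif vox.dtype == np.float64:
        pass  # NIfTI/NRRD store float64 natively
    sitk.WriteImage(_to_sitk(img), path)


def _resample(img, size, spacing, origin, direction, mode, default):
    interp = sitk.sitkNearestNeighbor if mode == "nearest" else sitk.sitkLinear
    src = _to_sitk(img)
    res = sitk.Resample(
        src,
        [int(s) for s in size],
        sitk.Transform(),
        interp,
        [float(o) for o in origin],
        [float(s) for s in spacing],
        [float(d) for d in np.asarray(direction).ravel()],
        float(default),
        src.GetPixelID(),
    )
    return _from_sitk(res, isinstance(img, LabelMap))


def resample_to_spacing(
    img: VolumeImage | LabelMap,
    target_spacing,
    mode: str | None = None,
) -> VolumeImage | LabelMap:
    """Resample onto a grid with the given mm spacing.

    The output size is ``ceil(size * spacing / target_spacing)`` per axis,
    so the physical extent is never cropped.  Origin and direction are
    preserved.  Label maps require (and default to) nearest-neighbour
    interpolation; images default to linear.  Out-of-domain voxels are
    filled with the input minimum (images) or 0 (labels), mimicking the
    air background.
    """
    target_spacing = np.asarray(target_spacing, dtype=float)
    if np.isscalar(target_spacing) or target_spacing.ndim == 0:
        target_spacing = np.full(3, float(target_spacing))
    if target_spacing.shape != (3,) or np.any(target_spacing <= 0):
        raise GeometryError(f"target spacing must be 3 positive values, got {target_spacing}")
    is_label = isinstance(img, LabelMap)
    if mode is None:
        mode = "nearest" if is_label else "linear"
    if is_label and mode != "nearest":
        raise ValueError("label maps must be resampled with mode='nearest'")
    size = np.ceil(np.asarray(img.shape) * img.spacing / target_spacing - 1e-9).astype(int)
    size = np.maximum(size, 1)
    default = 0 if is_label else float(np.min(img.voxels))
    return _resample(img, size, target_spacing, img.origin, img.direction, mode, default)


def resample_to_reference(
    img: VolumeImage | LabelMap, reference: VolumeImage, mode: str | None = None
) -> VolumeImage | LabelMap:
    """Map a grid onto a reference geometry.

    The output geometry equals the reference's exactly.  Label maps use
    nearest-neighbour interpolation (their value set stays a subset of
    the input's); intensity images default to linear.
    """
    _validate_geometry(reference.spacing, reference.origin, reference.direction)
    is_label = isinstance(img, LabelMap)
    if mode is None:
        mode = "nearest" if is_label else "linear"
    if is_label and mode != "nearest":
        raise ValueError("label maps must be resampled with mode='nearest'")
    default = 0 if is_label else float(np.min(img.voxels))
    return _resample(
        img,
        reference.shape,
        reference.spacing,
        reference.origin,
        reference.direction,
        mode,
        default,
    )
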