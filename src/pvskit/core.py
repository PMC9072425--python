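"""Volume containers, NIfTI I/O, isotropic reslicing and mask geometry.

The detector operates on a 0.5 mm isotropic working grid. This module holds
the pieces every stage shares: a light 3D volume container with physical
voxel spacing, NIfTI-1 round-trip I/O, trilinear / nearest reslicing to the
working grid, the dilate-fill-erode conditioning of the white-matter mask
that guards against partial-volume effects at the WM boundary, and the
integer sphere-offset sets used for local neighborhood statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Acquisition voxel size of the source MPRAGE protocol, mm.
ACQUISITION_SPACING_MM = (0.488, 0.488, 0.9)

#: Working grid spacing after reslicing, mm (isotropic).
WORKING_SPACING_MM = 0.5


class VolumeFormatError(ValueError):
    """Raised for files or arrays that are not valid 3D volumes."""


@dataclass
class IntensityVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities, arbitrary units.
    spacing : tuple of float
        Per-axis voxel size in mm; all components must be positive.
    origin_note : str
        Free-text provenance tag (e.g. source filename or "phantom").
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin_note: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected 3D volume, got {self.data.ndim}D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"non-positive spacing {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeFormatError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class VoxelMask:
    """A binary mask on the same grid as a paired :class:`IntensityVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeFormatError(f"expected 3D mask, got {arr.ndim}D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise VolumeFormatError("mask values must be 0/1")
        self.data = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing
        )


@dataclass
class SphereOffsets:
    """Integer voxel displacements within a physical radius of the origin.

    ``offsets`` contains exactly the integer 3-vectors d with
    ``||d * spacing||_2 <= radius_mm`` (inclusive boundary); it always
    contains (0, 0, 0) and is symmetric under negation.
    """

    radius_mm: float
    spacing: tuple[float, float, float]
    offsets: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.offsets)


def read_volume(path) -> IntensityVolume:
    """Read a 3D NIfTI-1 volume (optionally .nii.gz).

    Spacing is taken from the header pixdim. Rejects non-3D images and
    non-positive spacings with :class:`VolumeFormatError`.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"expected 3D volume, got {data.ndim}D in {path}"
        )
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise VolumeFormatError(f"non-positive spacing {zooms} in {path}")
    return IntensityVolume(
        data=np.asarray(data, dtype=np.float64),
        spacing=tuple(float(z) for z in zooms),
        origin_note=str(path),
    )


def write_volume(vol: IntensityVolume, path) -> None:
    """Write an :class:`IntensityVolume` as NIfTI-1 (float32)."""
    _write_nifti(vol.data.astype(np.float32), vol.spacing, path)


def read_mask(path) -> VoxelMask:
    """Read a binary mask volume; values are thresholded at 0.5."""
    vol = read_volume(path)
    return VoxelMask(data=(vol.data > 0.5).astype(np.uint8), spacing=vol.spacing)


def write_mask(mask: VoxelMask, path) -> None:
    """Write a :class:`VoxelMask` as an unsigned 8-bit NIfTI-1 volume."""
    _write_nifti(mask.data.astype(np.uint8), mask.spacing, path)


def _write_nifti(data: np.ndarray, spacing, path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def reslice_isotropic(
    vol: IntensityVolume, target_mm: float = WORKING_SPACING_MM,
    mode: str = "linear",
) -> IntensityVolume:
    """Reslice a volume to an isotropic grid.

    Output size per axis is ``round(n_in * spacing_in / target_mm)`` with the
    grid aligned to the input's first voxel center. ``mode="linear"`` uses
    trilinear interpolation (exact on constants); ``mode="nearest"`` must be
    used for masks so labels stay binary.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    in_shape = np.array(vol.shape)
    in_sp = np.array(vol.spacing)
    out_shape = np.maximum(
        1, np.round(in_shape * in_sp / target_mm).astype(int)
    )
    # voxel-center coordinates of the output grid in input index units
    coords = np.meshgrid(
        *[np.arange(n) * target_mm / s for n, s in zip(out_shape, in_sp)],
        indexing="ij",
    )
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=np.float64),
        np.stack(coords),
        order=order,
        mode="nearest",
    )
    return IntensityVolume(
        data=out,
        spacing=(target_mm,) * 3,
        origin_note=vol.origin_note + f"|resliced@{target_mm}mm",
    )


def reslice_mask(mask: VoxelMask, target_mm: float = WORKING_SPACING_MM) -> VoxelMask:
    """Nearest-neighbor reslice of a binary mask to an isotropic grid."""
    vol = IntensityVolume(
        data=mask.data.astype(np.float64), spacing=mask.spacing
    )
    out = reslice_isotropic(vol, target_mm, mode="nearest")
    return VoxelMask(data=(out.data > 0.5).astype(np.uint8), spacing=out.spacing)


# Structuring element for "by two voxels": two iterations of the
# 6-connected (face-adjacent) unit ball. Configurable via `iterations`
# because the source procedure does not pin down the element.
_FACE_BALL = ndimage.generate_binary_structure(3, 1)


def condition_wm_mask(wm: VoxelMask, iterations: int = 2) -> VoxelMask:
    """Condition a white-matter mask: dilate, fill holes, erode.

    Dilates by ``iterations`` face-connected voxels, flood-fills any interior
    cavity not 6-connected to the volume border, then erodes back. The net
    effect is a morphological closing plus hole fill, which removes the
    partial-volume pocks and slivers a tissue segmentation leaves at the WM
    boundary.
    """
    data = wm.data
    if not data.any():
        warnings.warn("empty white-matter mask", stacklevel=2)
        return VoxelMask(data=data.astype(np.uint8), spacing=wm.spacing)
    dil = ndimage.binary_dilation(data, _FACE_BALL, iterations=iterations)
    filled = ndimage.binary_fill_holes(dil, _FACE_BALL)
    ero = ndimage.binary_erosion(filled, _FACE_BALL, iterations=iterations)
    return VoxelMask(data=ero.astype(np.uint8), spacing=wm.spacing)


def sphere_offsets(radius_mm: float, spacing) -> SphereOffsets:
    """Integer voxel offsets within ``radius_mm`` (physical, inclusive).

    Membership uses voxel-center Euclidean distance with the per-axis
    physical spacing; boundary voxels exactly at the radius are included.
    """
    if radius_mm < 0:
        raise ValueError(f"radius_mm must be >= 0, got {radius_mm}")
    sp = np.asarray(spacing, dtype=np.float64)
    reach = np.floor(radius_mm / sp).astype(int)
    ax = [np.arange(-r, r + 1) for r in reach]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij")
    d2 = (dx * sp[0]) ** 2 + (dy * sp[1]) ** 2 + (dz * sp[2]) ** 2
    inside = d2 <= radius_mm**2 + 1e-12
    offs = np.stack([dx[inside], dy[inside], dz[inside]], axis=1)
    return SphereOffsets(
        radius_mm=float(radius_mm),
        spacing=tuple(float(s) for s in sp),
        offsets=offs.astype(np.int64),
    )
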