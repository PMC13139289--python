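"""CT volumes and binary masks with axis-aligned voxel geometry.

Volumes are 3D grids of Hounsfield units (HU).  Geometry is the simple
axial-scan convention: world position of voxel ``(i, j, k)`` is
``origin + index * spacing`` with all three spacing components positive.
Oblique affines are rejected on read rather than silently resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

#: tolerance (mm) when comparing the geometry of two grids
GEOMETRY_TOL = 1e-4


class GeometryError(ValueError):
    """Raised when two grids that must share geometry do not."""


@dataclass(frozen=True)
class CtVolume:
    """A 3D CT volume in Hounsfield units.

    Parameters
    ----------
    data : ndarray
        3D float array of HU values (header slope/intercept already applied).
    spacing : tuple of float
        Voxel size in mm per axis; all components positive.
    origin : tuple of float
        World-mm position of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.size == 0:
            raise ValueError(f"not a 3D volume: shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite voxels")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    def same_geometry(self, other, tol: float = GEOMETRY_TOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal spacing, translation origin)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} grid sharing a reference volume's geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3 or data.size == 0:
            raise ValueError(f"not a 3D mask: shape {data.shape}")
        data = (data != 0).astype(np.uint8)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    shape = CtVolume.shape
    voxel_volume = CtVolume.voxel_volume
    same_geometry = CtVolume.same_geometry
    affine = CtVolume.affine

    def count(self) -> int:
        return int(self.data.sum())


def _geometry_from_affine(affine: np.ndarray):
    """Extract (spacing, origin) from an axis-aligned affine; reject oblique."""
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > GEOMETRY_TOL:
        raise ValueError(
            "oblique affine not supported; volumes must be axis-aligned "
            f"(rotation/shear part:\n{rot})"
        )
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise ValueError(
            "affine with negative or zero diagonal not supported; reorient "
            f"the image to a positive axis-aligned affine (diagonal {diag})"
        )
    return tuple(float(d) for d in diag), tuple(float(o) for o in affine[:3, 3])


def read_volume(path) -> CtVolume:
    """Read a NIfTI CT volume; HU scaling (slope/intercept) is applied.

    Raises on missing files, non-3D images, non-finite voxels, and
    oblique affines.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.get_fdata(dtype=np.float64))
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: not a 3D volume (shape {data.shape})")
    spacing, origin = _geometry_from_affine(img.affine)
    return CtVolume(data, spacing, origin)


def write_volume(vol: CtVolume, path) -> None:
    """Write a volume as NIfTI-1 with its axis-aligned affine."""
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine())
    nib.save(img, str(path))


def read_mask(path, reference: CtVolume) -> BinaryMask:
    """Read a label image as a binary mask co-registered to ``reference``.

    Any nonzero label maps to 1.  The file's grid geometry must match the
    reference within ``GEOMETRY_TOL`` mm.
    """
    img = nib.load(str(path))
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 3:
        raise ValueError(f"{path}: not a 3D mask (shape {data.shape})")
    spacing, origin = _geometry_from_affine(img.affine)
    mask = BinaryMask(data, spacing, origin)
    if not mask.same_geometry(reference):
        raise GeometryError(
            f"mask geometry (shape {mask.shape}, spacing {spacing}, origin "
            f"{origin}) does not match reference (shape {reference.shape}, "
            f"spacing {reference.spacing}, origin {reference.origin})"
        )
    return mask


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine())
    nib.save(img, str(path))


def _resample_grid(data, spacing, target_spacing, order):
    new_shape = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(data.shape, spacing, target_spacing)
    )
    coords = np.meshgrid(
        *[
            np.arange(n) * t / s
            for n, s, t in zip(new_shape, spacing, target_spacing)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        np.asarray(data, dtype=float), coords, order=order, mode="nearest"
    )


def resample_volume(vol, target_spacing, method: str = "linear"):
    """Resample a volume (or mask) to a new voxel spacing.

    The output grid is aligned to the original origin and its extent matches
    the original within one target voxel.  HU volumes should use
    ``method="linear"``; masks must use ``method="nearest"`` (they stay
    binary).  Returns the same type as the input.
    """
    target_spacing = tuple(float(t) for t in np.broadcast_to(target_spacing, (3,)))
    if any(t <= 0 for t in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if method not in ("linear", "nearest"):
        raise ValueError(f"unknown method {method!r}; use 'linear' or 'nearest'")
    order = 1 if method == "linear" else 0
    out = _resample_grid(vol.data, vol.spacing, target_spacing, order)
    if isinstance(vol, BinaryMask):
        if method != "nearest":
            raise ValueError("masks must be resampled with method='nearest'")
        return BinaryMask(out > 0.5, target_spacing, vol.origin)
    return CtVolume(out, target_spacing, vol.origin)
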