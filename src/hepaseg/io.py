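"""Core containers and NRRD volume I/O.

The unit every stage of the pipeline consumes and produces is a 3D
gray-scale voxel stack with physical spacing metadata, plus binary masks
aligned to it.  Axis convention throughout the package: ``(slice, row,
col)`` i.e. ``(z, y, x)``, 0-based, row 0 at the top of the slice.  NRRD
files store spacing in ``(x, y, z)`` order; the mapping is handled here and
nowhere else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageStack",
    "validate_binary_mask",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
]


@dataclass
class ImageStack:
    """A 3D gray-scale voxel array with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (slices, rows, cols)
        Gray values.  Finite; nominally in ``value_range``.
    spacing : tuple of float
        Voxel spacing in micrometres, ``(z, y, x)`` order.
    value_range : tuple of float
        Nominal intensity domain of ``voxels`` (default unit interval).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (9.0, 9.0, 9.0)
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (slices, rows, cols), got ndim={self.voxels.ndim}")
        if self.voxels.size == 0:
            raise ValueError("voxels must be non-empty")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats (z, y, x), got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy_with(self, voxels: np.ndarray | None = None,
                  spacing: tuple[float, float, float] | None = None) -> "ImageStack":
        return ImageStack(
            voxels=self.voxels.copy() if voxels is None else voxels,
            spacing=self.spacing if spacing is None else spacing,
            value_range=self.value_range,
        )


def validate_binary_mask(mask: np.ndarray, shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Check that ``mask`` holds only {0, 1} (any integer/bool/float dtype)
    and optionally matches ``shape``; return it as uint8."""
    mask = np.asarray(mask)
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match expected {tuple(shape)}")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask is not binary; found values {vals[:10]}")
    return mask.astype(np.uint8)


def _to_sitk(voxels: np.ndarray, spacing_zyx: tuple[float, float, float]) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels))
    img.SetSpacing(tuple(float(s) for s in spacing_zyx[::-1]))  # sitk wants (x, y, z)
    return img


def write_stack(stack: ImageStack, path: str | os.PathLike, compress: bool = False) -> str:
    """Serialize a stack to NRRD. Raw encoding by default so files stay
    byte-inspectable; round-trip reads reproduce voxel values exactly."""
    path = os.fspath(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise IOError(f"cannot write NRRD: directory not writable: {parent!r}")
    writer = sitk.ImageFileWriter()
    writer.SetFileName(path)
    writer.SetUseCompression(bool(compress))
    writer.Execute(_to_sitk(stack.voxels, stack.spacing))
    return path


def read_stack(path: str | os.PathLike) -> ImageStack:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such NRRD file: {path!r}")
    img = sitk.ReadImage(path)
    voxels = sitk.GetArrayFromImage(img)
    if voxels.ndim != 3:
        raise ValueError(f"expected a 3D volume in {path!r}, got ndim={voxels.ndim}")
    spacing = tuple(img.GetSpacing())[::-1]  # (x, y, z) -> (z, y, x)
    lo, hi = float(voxels.min()), float(voxels.max())
    vr = (0.0, 1.0) if hi <= 1.0 and lo >= 0.0 else (lo, hi)
    return ImageStack(voxels=voxels, spacing=spacing, value_range=vr)


def write_mask(mask: np.ndarray, spacing_zyx: tuple[float, float, float],
               path: str | os.PathLike) -> str:
    """Serialize a binary mask as a uint8 {0,1} NRRD aligned to its stack."""
    mask = validate_binary_mask(mask)
    return write_stack(ImageStack(voxels=mask, spacing=spacing_zyx, value_range=(0.0, 1.0)), path)


def read_mask(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    stack = read_stack(path)
    return validate_binary_mask(stack.voxels), stack.spacing
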