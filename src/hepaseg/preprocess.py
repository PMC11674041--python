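"""Preprocessing chain from raw micro-CT stack to network-ready slices.

The fixed pipeline order is: axial 1:2 downsampling (retain one slice out
of two, 9 µm -> 18 µm), per-slice 2-pixel median filtering, gray-scale
single-channel conversion with normalization to [0, 1] by dtype maximum,
centered zero-padding to 512x512, and a 5x5 Gaussian blur.  Before
metastasis-oriented segmentation an optional cleaning mask (spine, marrow,
support cradle, spleen) is zeroed out of the stack.

Ground-truth masks follow the same *geometric* operations (downsampling
stride and padding) but are never median-filtered or blurred: reference
labels must stay crisp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageStack, validate_binary_mask

__all__ = [
    "PreprocessConfig",
    "downsample_axial",
    "median_filter_slices",
    "to_single_channel",
    "pad_to_square",
    "crop_from_pad",
    "pad_mask_stack",
    "export_slice_images",
    "gaussian_blur",
    "apply_cleaning_mask",
    "preprocess_stack",
]


@dataclass
class PreprocessConfig:
    """Constants of the preprocessing chain.

    axial_keep_stride: keep one slice out of ``stride`` along z (default 2).
    median_radius_px: median filter radius in pixels; radius 2 means a 5x5
        window, the common reading of an ImageJ "2 pixel" median setting.
    target_size_px: square padded size fed to the networks (default 512).
    blur_kernel_px: Gaussian window side (odd, default 5); sigma is
        ``blur_kernel_px / 5`` so the default 5x5 blur uses sigma 1.0.
    """

    axial_keep_stride: int = 2
    median_radius_px: int = 2
    target_size_px: int = 512
    blur_kernel_px: int = 5

    def __post_init__(self) -> None:
        for name in ("axial_keep_stride", "median_radius_px", "target_size_px", "blur_kernel_px"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.axial_keep_stride < 1 or self.target_size_px < 1 or self.blur_kernel_px < 1:
            raise ValueError("axial_keep_stride, target_size_px and blur_kernel_px must be >= 1")
        if self.blur_kernel_px % 2 == 0:
            raise ValueError(f"blur_kernel_px must be odd, got {self.blur_kernel_px}")


def downsample_axial(stack: ImageStack, stride: int) -> ImageStack:
    """Retain slices 0, stride, 2*stride, ... and scale z-spacing by the
    stride. Slice content is bit-identical to the retained source slices."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    voxels = stack.voxels[::stride].copy()
    z, y, x = stack.spacing
    return stack.copy_with(voxels=voxels, spacing=(z * stride, y, x))


def median_filter_slices(stack: ImageStack, radius_px: int) -> ImageStack:
    """Per-slice 2D median with a (2r+1)x(2r+1) window; edges replicated."""
    if radius_px < 0:
        raise ValueError(f"radius_px must be >= 0, got {radius_px}")
    if radius_px == 0:
        return stack.copy_with()
    size = 2 * radius_px + 1
    out = np.empty_like(stack.voxels)
    for k in range(stack.voxels.shape[0]):
        out[k] = ndimage.median_filter(stack.voxels[k], size=size, mode="nearest")
    return stack.copy_with(voxels=out)


def to_single_channel(stack_or_array: ImageStack | np.ndarray) -> ImageStack:
    """Collapse to one gray channel and rescale to [0, 1] by the nominal
    dtype maximum (255 for uint8, 65535 for uint16); float input already in
    [0, 1] passes through unchanged.

    Per-image min-max scaling is deliberately avoided: it would break
    cross-slice comparability of the contrast-enhanced liver signal.
    """
    if isinstance(stack_or_array, ImageStack):
        voxels, spacing = stack_or_array.voxels, stack_or_array.spacing
    else:
        voxels, spacing = np.asarray(stack_or_array), (9.0, 9.0, 9.0)

    if voxels.ndim == 4:  # (slices, rows, cols, channels)
        if not np.all(voxels == voxels[..., :1]):
            raise ValueError("multi-channel input with disagreeing channels is not gray-scale")
        voxels = voxels[..., 0]
    elif voxels.ndim != 3:
        raise ValueError(f"expected 3D or 4D input, got ndim={voxels.ndim}")

    if np.issubdtype(voxels.dtype, np.integer):
        denom = float(np.iinfo(voxels.dtype).max)
        out = voxels.astype(np.float32) / denom
    else:
        out = voxels.astype(np.float32)
        if out.min() < 0.0 or out.max() > 1.0:
            raise ValueError("float input must already lie in [0, 1]")
    return ImageStack(voxels=out, spacing=spacing, value_range=(0.0, 1.0))


def pad_to_square(slice_img: np.ndarray, target_px: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Center ``slice_img`` on a black ``target_px`` square.

    Odd margins put the extra pixel on the bottom/right (floor-division
    offsets).  Returns ``(padded, (row_offset, col_offset))`` so that masks
    can be padded identically and predictions un-padded with
    :func:`crop_from_pad`.  A slice larger than the target is an explicit
    failure — no silent rescale.
    """
    slice_img = np.asarray(slice_img)
    h, w = slice_img.shape
    if h > target_px or w > target_px:
        raise ValueError(f"slice {h}x{w} exceeds target {target_px}x{target_px}")
    top, left = (target_px - h) // 2, (target_px - w) // 2
    out = np.zeros((target_px, target_px), dtype=slice_img.dtype)
    out[top : top + h, left : left + w] = slice_img
    return out, (top, left)


def crop_from_pad(padded: np.ndarray, offset: tuple[int, int],
                  original_shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`pad_to_square` given the recorded offset."""
    top, left = offset
    h, w = original_shape
    return padded[top : top + h, left : left + w]


def pad_mask_stack(mask: np.ndarray, target_px: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Pad every slice of a binary mask stack with the image geometry."""
    mask = validate_binary_mask(mask)
    out = np.zeros((mask.shape[0], target_px, target_px), dtype=np.uint8)
    offset = (0, 0)
    for k in range(mask.shape[0]):
        out[k], offset = pad_to_square(mask[k], target_px)
    return out, offset


def gaussian_blur(slice_img: np.ndarray, kernel_px: int) -> np.ndarray:
    """2D Gaussian smoothing on a kernel_px x kernel_px window (odd size),
    sigma = kernel_px / 5, truncated at the kernel bounds."""
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError(f"kernel_px must be odd and >= 1, got {kernel_px}")
    if kernel_px == 1:
        return np.asarray(slice_img).copy()
    sigma = kernel_px / 5.0
    radius = (kernel_px - 1) // 2
    return ndimage.gaussian_filter(
        np.asarray(slice_img, dtype=np.float32), sigma=sigma, radius=radius, mode="nearest"
    )


def export_slice_images(stack: ImageStack, directory: str, fmt: str = "png") -> list[str]:
    """Write each slice as an 8-bit gray PNG/TIFF for visual inspection."""
    import os

    if fmt not in ("png", "tiff"):
        raise ValueError(f"fmt must be 'png' or 'tiff', got {fmt!r}")
    os.makedirs(directory, exist_ok=True)
    lo, hi = stack.value_range
    scaled = np.clip((stack.voxels - lo) / max(hi - lo, 1e-12), 0, 1)
    img8 = (scaled * 255).round().astype(np.uint8)
    paths = []
    for k in range(img8.shape[0]):
        path = os.path.join(directory, f"slice_{k:04d}.{fmt}")
        if fmt == "png":
            from matplotlib.image import imsave

            imsave(path, img8[k], cmap="gray", vmin=0, vmax=255)
        else:
            import tifffile

            tifffile.imwrite(path, img8[k])
        paths.append(path)
    return paths


def apply_cleaning_mask(stack: ImageStack, cleaning: np.ndarray) -> ImageStack:
    """Zero the voxels flagged by the cleaning mask (spine, marrow, cradle,
    spleen); every other voxel is untouched."""
    cleaning = validate_binary_mask(cleaning, shape=stack.shape)
    voxels = stack.voxels.copy()
    voxels[cleaning == 1] = 0
    return stack.copy_with(voxels=voxels)


def preprocess_stack(stack: ImageStack, config: PreprocessConfig | None = None,
                     cleaning: np.ndarray | None = None,
                     ) -> tuple[ImageStack, tuple[int, int], tuple[int, int]]:
    """Run the full chain in its fixed order.

    Returns ``(preprocessed, pad_offset, original_slice_shape)``; the offset
    and shape let predictions be un-padded back to pre-padding geometry.
    ``cleaning`` (if given) is aligned to the *input* stack and is
    downsampled with the same stride before removal.
    """
    cfg = config or PreprocessConfig()
    original = stack
    stack = downsample_axial(stack, cfg.axial_keep_stride)
    if cleaning is not None:
        cleaning = validate_binary_mask(cleaning, shape=original.shape)[:: cfg.axial_keep_stride]
    stack = median_filter_slices(stack, cfg.median_radius_px)
    stack = to_single_channel(stack)

    n = stack.voxels.shape[0]
    orig_shape = stack.voxels.shape[1:]
    padded = np.zeros((n, cfg.target_size_px, cfg.target_size_px), dtype=np.float32)
    offset = (0, 0)
    for k in range(n):
        padded[k], offset = pad_to_square(stack.voxels[k], cfg.target_size_px)
        padded[k] = gaussian_blur(padded[k], cfg.blur_kernel_px)
    out = ImageStack(voxels=padded, spacing=stack.spacing, value_range=(0.0, 1.0))

    if cleaning is not None:
        padded_clean, _ = pad_mask_stack(cleaning, cfg.target_size_px)
        out = apply_cleaning_mask(out, padded_clean)
    return out, offset, orig_shape
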