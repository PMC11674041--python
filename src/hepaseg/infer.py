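"""Inference: probability maps, binarized predicted masks, combined masks.

A trained network outputs a per-pixel probability map per slice.  The map
is binarized with a fixed threshold tau = 5/255 (kept as the exact rational
on the probability scale): a pixel is positive iff its probability is
*strictly greater* than tau.  The threshold is low because the networks
assign low probabilities to the structures of interest.

The metastatic-liver-area (MLA) and lesion (LM) predictions are merged into
a single label map for visualization — 0 background, 1 metastatic liver
only, 2 metastasis — with the lesion taking precedence where both are
positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .io import ImageStack, validate_binary_mask
from .models import UNet
from .preprocess import crop_from_pad

__all__ = [
    "TAU_DEFAULT",
    "BinarizationConfig",
    "predict_stack",
    "binarize",
    "combine_masks",
    "split_combined",
    "write_overlay_png",
    "unpad_predictions",
]

TAU_DEFAULT = Fraction(5, 255)

LABEL_BACKGROUND = 0
LABEL_METASTATIC_LIVER = 1
LABEL_METASTASIS = 2


@dataclass
class BinarizationConfig:
    """Probability threshold for turning maps into binary masks."""

    tau: float = float(TAU_DEFAULT)

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau < 1.0):
            raise ValueError(f"tau must be in [0, 1), got {self.tau}")


def predict_stack(network: UNet, stack: ImageStack | np.ndarray,
                  batch_size: int = 4) -> np.ndarray:
    """Per-slice probability maps for a preprocessed stack, shape
    (slices, H, W), deterministic in inference mode."""
    voxels = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    if voxels.ndim != 3:
        raise ValueError(f"expected a (slices, rows, cols) stack, got shape {voxels.shape}")
    size = network.spec.input_size
    if voxels.shape[1] != size or voxels.shape[2] != size:
        raise ValueError(
            f"slices are {voxels.shape[1]}x{voxels.shape[2]} but the network "
            f"expects {size}x{size}; run the preprocessing chain first"
        )
    maps = np.empty(voxels.shape, dtype=np.float32)
    for start in range(0, voxels.shape[0], batch_size):
        xb = voxels[start : start + batch_size][:, None].astype(np.float32)
        maps[start : start + batch_size] = network.forward(xb, train=False)[:, 0]
    return maps


def binarize(prob_map: np.ndarray, config: BinarizationConfig | None = None) -> np.ndarray:
    """Binarized predicted mask: positive iff probability strictly exceeds
    tau (a probability exactly equal to tau is negative)."""
    cfg = config or BinarizationConfig()
    prob_map = np.asarray(prob_map)
    if prob_map.min() < 0.0 or prob_map.max() > 1.0:
        raise ValueError("probability map has values outside [0, 1]")
    return (prob_map > cfg.tau).astype(np.uint8)


def combine_masks(mla: np.ndarray, lm: np.ndarray) -> np.ndarray:
    """Merge MLA and LM binary masks into a label map: 2 where the lesion
    mask is positive (lesion precedence), 1 where only the metastatic liver
    area is positive, 0 elsewhere."""
    mla = validate_binary_mask(mla)
    lm = validate_binary_mask(lm, shape=mla.shape)
    out = np.zeros(mla.shape, dtype=np.uint8)
    out[mla == 1] = LABEL_METASTATIC_LIVER
    out[lm == 1] = LABEL_METASTASIS
    return out


def split_combined(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a combined label map back into (mla, lm) binary masks.
    The liver-area mask includes lesion pixels (lesions lie in the liver)."""
    labels = np.asarray(labels)
    lm = (labels == LABEL_METASTASIS).astype(np.uint8)
    mla = (labels >= LABEL_METASTATIC_LIVER).astype(np.uint8)
    return mla, lm


def write_overlay_png(labels: np.ndarray, path: str) -> str:
    """Color rendering of one combined-mask slice: metastatic liver in blue,
    metastases in yellow on black."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError(f"expected a single 2D label slice, got shape {labels.shape}")
    from matplotlib.image import imsave

    rgb = np.zeros((*labels.shape, 3), dtype=np.float32)
    rgb[labels == LABEL_METASTATIC_LIVER] = (0.1, 0.3, 0.9)
    rgb[labels == LABEL_METASTASIS] = (1.0, 0.9, 0.1)
    imsave(path, rgb)
    return path


def unpad_predictions(maps: np.ndarray, offset: tuple[int, int],
                      original_shape: tuple[int, int]) -> np.ndarray:
    """Crop per-slice maps back to pre-padding geometry using the offset
    recorded by the padding step, so predictions align with the original
    ground truth coordinates."""
    maps = np.asarray(maps)
    return np.stack([crop_from_pad(maps[k], offset, original_shape)
                     for k in range(maps.shape[0])])
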