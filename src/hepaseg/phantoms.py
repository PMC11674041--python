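"""Synthetic micro-CT-like phantom stacks with exact ground truth.

Real preclinical scans of contrast-enhanced mouse livers show a bright,
contiguous, irregular organ (the nanoparticulate contrast agent is taken up
by hepatic macrophages, so healthy parenchyma lights up), darker metastatic
lesions inside it, and bright confounders outside it: the spine with its
darker marrow channel and the polystyrene support cradle at the image
boundary.  The phantoms emulate exactly that geometry so the whole pipeline
— preprocessing, training, inference, cleaning-mask removal, evaluation —
can run end to end with voxel-exact ground truth.

The liver is a union of 2–4 overlapping ellipsoids whose indicator is
Gaussian-smoothed and re-thresholded, giving organ-like nonconvex outlines.
Lesions are jittered ellipsoids (per-axis jitter <= 30 %) placed fully
inside the liver, darker by a fractional contrast.  All randomness flows
from a single ``numpy.random.Generator`` seeded once, so generation is
bit-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageStack, write_mask, write_stack

__all__ = [
    "PhantomConfig",
    "PhantomOutput",
    "PlacementError",
    "generate_phantom",
    "write_phantom",
]


class PlacementError(RuntimeError):
    """Raised when a lesion cannot be placed inside the liver after the
    bounded number of rejection-sampling retries."""


@dataclass
class PhantomConfig:
    """Parameters of one synthetic stack.

    Intensities are on the unit gray scale.  Defaults describe an advanced
    metastatic burden: a strongly enhancing liver (mean 0.75 versus a ~0.05
    soft-tissue background) carrying several hypointense lesions that lose
    half the parenchymal signal, with mild additive noise.
    """

    shape: tuple[int, int, int] = (40, 96, 96)
    liver_intensity: float = 0.75
    lesion_count: int = 4
    lesion_radius_range: tuple[float, float] = (3.0, 7.0)
    lesion_contrast: float = 0.5
    spine: bool = True
    marrow: bool = True
    cradle: bool = True
    spleen: bool = False
    noise_sd: float = 0.02
    background_intensity: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape entries must all be >= 1, got {self.shape}")
        if not (0.0 < self.lesion_contrast <= 1.0):
            raise ValueError(f"lesion_contrast must be in (0, 1], got {self.lesion_contrast}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.lesion_count < 0:
            raise ValueError(f"lesion_count must be >= 0, got {self.lesion_count}")
        rmin, rmax = self.lesion_radius_range
        if rmin > rmax or rmin <= 0:
            raise ValueError(f"invalid lesion_radius_range {self.lesion_radius_range}")
        if not (0.0 < self.liver_intensity <= 1.0):
            raise ValueError(f"liver_intensity must be in (0, 1], got {self.liver_intensity}")


@dataclass
class PhantomOutput:
    """One generated case: the stack plus exact masks.

    Invariants: ``lesion_mask`` is a subset of ``liver_mask``;
    ``confounder_mask`` is disjoint from ``liver_mask``; all masks share the
    stack shape.
    """

    stack: ImageStack
    liver_mask: np.ndarray
    lesion_mask: np.ndarray
    confounder_mask: np.ndarray


def _ellipsoid_mask(shape: tuple[int, int, int], center: np.ndarray,
                    radii: np.ndarray) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d = (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    )
    return d <= 1.0


def _make_liver(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    nz, ny, nx = shape
    n_lobes = int(rng.integers(2, 5))
    base_center = np.array([nz / 2, ny * 0.55, nx * 0.45])
    base_radii = np.array([nz * 0.38, ny * 0.26, nx * 0.26])
    ind = np.zeros(shape, dtype=bool)
    for _ in range(n_lobes):
        jitter = rng.uniform(-0.35, 0.35, size=3) * base_radii
        radii = base_radii * rng.uniform(0.6, 1.0, size=3)
        radii = np.maximum(radii, 2.0)
        ind |= _ellipsoid_mask(shape, base_center + jitter, radii)
    # smooth the indicator and re-threshold -> irregular but connected organ
    smooth = ndimage.gaussian_filter(ind.astype(np.float32), sigma=1.5)
    mask = smooth > 0.5
    # keep the largest connected component so the liver is one region
    labels, n = ndimage.label(mask)
    if n == 0:
        return ind  # degenerate tiny shapes: fall back to the raw union
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def _place_lesions(liver: np.ndarray, config: PhantomConfig,
                   rng: np.random.Generator, max_retries: int = 200) -> np.ndarray:
    shape = liver.shape
    lesions = np.zeros(shape, dtype=bool)
    rmin, rmax = config.lesion_radius_range
    # candidate centers: liver voxels eroded by the max radius keep small
    # lesions fully interior most of the time
    interior = ndimage.binary_erosion(liver, iterations=max(1, int(rmin)))
    centers = np.argwhere(interior)
    if config.lesion_count > 0 and centers.size == 0:
        raise PlacementError("liver interior too small to host any lesion")
    for k in range(config.lesion_count):
        placed = False
        for _ in range(max_retries):
            c = centers[rng.integers(len(centers))]
            r = rng.uniform(rmin, rmax)
            radii = r * rng.uniform(0.7, 1.3, size=3)  # per-axis jitter <= 30 %
            cand = _ellipsoid_mask(shape, c.astype(float), radii)
            if not cand.any():
                continue
            if np.all(liver[cand]):  # fully inside the liver
                lesions |= cand
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place lesion {k + 1}/{config.lesion_count} inside the "
                f"liver after {max_retries} retries; shrink lesion_radius_range "
                f"or enlarge the stack"
            )
    return lesions


def _make_confounders(shape: tuple[int, int, int], liver: np.ndarray,
                      config: PhantomConfig, rng: np.random.Generator,
                      intensity: np.ndarray) -> np.ndarray:
    """Paint spine (+marrow), cradle and optional spleen into ``intensity``
    and return their union mask. Regions overlapping the liver are clipped
    out so confounder_mask ∩ liver_mask = ∅."""
    nz, ny, nx = shape
    conf = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[:ny, :nx]

    if config.spine:
        # bright vertebral column running through all slices, near the top edge
        cy, cx = ny * 0.12, nx * 0.5 + rng.uniform(-0.05, 0.05) * nx
        r_spine = max(2.0, 0.06 * min(ny, nx))
        spine2d = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_spine**2
        spine = np.broadcast_to(spine2d, shape).copy()
        spine &= ~liver
        intensity[spine] = 0.9
        if config.marrow:
            r_marrow = max(1.0, r_spine * 0.45)
            marrow2d = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_marrow**2
            marrow = np.broadcast_to(marrow2d, shape).copy()
            marrow &= ~liver
            intensity[marrow] = 0.35  # darker central channel
        conf |= spine

    if config.cradle:
        # polystyrene support: a circular arc band hugging the bottom boundary
        cy, cx = ny * 1.35, nx * 0.5
        rr = np.hypot(yy - cy, xx - cx)
        band_r = ny * 0.55
        cradle2d = (rr >= band_r) & (rr <= band_r + max(2.0, ny * 0.04)) & (yy > ny * 0.6)
        cradle = np.broadcast_to(cradle2d, shape).copy()
        cradle &= ~liver
        intensity[cradle] = 0.45
        conf |= cradle

    if config.spleen:
        center = np.array([nz * 0.5, ny * 0.4, nx * 0.85])
        radii = np.array([nz * 0.2, ny * 0.12, nx * 0.08])
        spleen = _ellipsoid_mask(shape, center, radii)
        spleen &= ~liver
        intensity[spleen] = config.liver_intensity  # spleen also takes up contrast
        conf |= spleen

    return conf


def generate_phantom(config: PhantomConfig) -> PhantomOutput:
    """Generate one seeded phantom stack with exact ground truth.

    The liver is a single bright connected region spanning multiple slices;
    lesions are darker quasi-spherical regions fully inside it; spine and
    cradle lie outside it.  Intensities are in [0, 1] before noise and
    clipped after.  Deterministic given ``config.seed``.

    Raises
    ------
    PlacementError
        If a lesion cannot be placed inside the liver after bounded retries.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.shape

    liver = _make_liver(shape, rng)
    lesions = (
        _place_lesions(liver, config, rng)
        if config.lesion_count > 0
        else np.zeros(shape, dtype=bool)
    )

    intensity = np.full(shape, config.background_intensity, dtype=np.float32)
    conf = _make_confounders(shape, liver, config, rng, intensity)
    intensity[liver] = config.liver_intensity
    intensity[lesions] = config.liver_intensity * (1.0 - config.lesion_contrast)
    np.clip(intensity, 0.0, 1.0, out=intensity)

    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)
        np.clip(intensity, 0.0, 1.0, out=intensity)

    stack = ImageStack(voxels=intensity.astype(np.float32), spacing=(18.0, 9.0, 9.0))
    return PhantomOutput(
        stack=stack,
        liver_mask=liver.astype(np.uint8),
        lesion_mask=lesions.astype(np.uint8),
        confounder_mask=conf.astype(np.uint8),
    )


def write_phantom(output: PhantomOutput, directory: str | os.PathLike) -> dict[str, str]:
    """Serialize a phantom case to ``<dir>/stack.nrrd`` plus the three mask
    NRRDs; headers share sizes and spacing, and round-trip reads reproduce
    voxel values exactly."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    if not os.access(directory, os.W_OK):
        raise IOError(f"directory not writable: {directory!r}")
    sp = output.stack.spacing
    paths = {"stack": write_stack(output.stack, os.path.join(directory, "stack.nrrd"))}
    for name, mask in (
        ("mask_liver", output.liver_mask),
        ("mask_lesions", output.lesion_mask),
        ("mask_confounders", output.confounder_mask),
    ):
        paths[name] = write_mask(mask, sp, os.path.join(directory, f"{name}.nrrd"))
    return paths
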