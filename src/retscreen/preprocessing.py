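"""Deterministic image standardisation and patch extraction.

The pipeline follows the fixed order: per-channel normalisation with
training-set moments, field-of-view (FOV) masking by element-wise
multiplication, bilinear resize to the working resolution, and row-major
extraction of non-overlapping square patches flattened to vectors of
length P^2*C.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, transform


@dataclass(frozen=True)
class ChannelStats:
    """Pooled per-channel moments of the training partition."""

    means: np.ndarray  # (C,)
    sds: np.ndarray    # (C,)
    n_images: int

    def to_json(self) -> str:
        return json.dumps({"means": self.means.tolist(),
                           "sds": self.sds.tolist(),
                           "n_images": self.n_images})

    @classmethod
    def from_json(cls, text: str) -> "ChannelStats":
        d = json.loads(text)
        return cls(means=np.asarray(d["means"], dtype=float),
                   sds=np.asarray(d["sds"], dtype=float),
                   n_images=int(d["n_images"]))


@dataclass(frozen=True)
class PatchGrid:
    """Geometry of the non-overlapping patch tiling of an H x W x C image."""

    target_size: int
    patch_size: int
    n_channels: int = 3

    def __post_init__(self) -> None:
        if self.target_size % self.patch_size != 0:
            raise ValueError(
                f"target size {self.target_size} not divisible by patch size "
                f"{self.patch_size}")

    @property
    def grid_rows(self) -> int:
        return self.target_size // self.patch_size

    @property
    def grid_cols(self) -> int:
        return self.target_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def patch_dim(self) -> int:
        return self.patch_size ** 2 * self.n_channels


def fit_channel_stats(images) -> ChannelStats:
    """Pooled per-channel mean/sd over all pixels of all training images.

    Raises if any channel has zero variance (normalisation undefined).
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one training image")
    n_channels = images[0].shape[-1]
    if any(img.shape[-1] != n_channels for img in images):
        raise ValueError("all images must share the channel count")
    pixels = np.concatenate([img.reshape(-1, n_channels) for img in images], axis=0)
    means = pixels.mean(axis=0)
    sds = pixels.std(axis=0)
    for c in range(n_channels):
        if sds[c] <= 1e-12:
            raise ValueError(f"channel {c} has zero variance across the training set")
    return ChannelStats(means=means, sds=sds, n_images=len(images))


def normalize_channels(image: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """(x - mu_c) / sigma_c per channel; spatial resolution unchanged."""
    if image.shape[-1] != stats.means.shape[0]:
        raise ValueError("image channel count does not match stats")
    return (image - stats.means) / stats.sds


def denormalize_channels(image: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Inverse of :func:`normalize_channels` (the map is affine)."""
    return image * stats.sds + stats.means


def apply_fov_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Element-wise multiplication by the binary FOV mask, broadcast over
    channels; masked-out pixels become exactly 0."""
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape must equal the image spatial shape")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("FOV mask must be binary (0/1)")
    return image * np.asarray(mask, dtype=image.dtype)[..., None]


def estimate_fov_mask(raw_image: np.ndarray) -> np.ndarray:
    """Estimate the circular FOV from a raw colour image.

    Pixels whose mean-channel intensity exceeds 5% of the 99th-percentile
    intensity are kept; the largest connected component is morphologically
    closed (radius 3) and hole-filled.  Robust to illumination gradients.
    """
    if raw_image.ndim != 3 or raw_image.shape[-1] != 3:
        raise ValueError("expected a 3-channel image")
    mean_channel = raw_image.mean(axis=-1)
    thresh = 0.05 * np.percentile(mean_channel, 99)
    fg = mean_channel > thresh
    if not fg.any():
        raise ValueError("FOV estimation failed: threshold removed every pixel")
    labels = measure.label(fg)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = labels == np.argmax(counts)
    closed = morphology.closing(largest, morphology.disk(3))
    filled = ndimage.binary_fill_holes(closed)
    return filled


def resize_with_mask(image: np.ndarray, mask: np.ndarray, target_size: int):
    """Bilinear resize of the image; the mask is resized alongside and
    re-binarised at 0.5."""
    if image.shape[0] == target_size and image.shape[1] == target_size:
        return image, np.asarray(mask, dtype=bool)
    resized = transform.resize(image, (target_size, target_size, image.shape[-1]),
                               order=1, preserve_range=True, anti_aliasing=False)
    mask_r = transform.resize(mask.astype(float), (target_size, target_size),
                              order=1, preserve_range=True, anti_aliasing=False)
    return resized, mask_r >= 0.5


def extract_patches(image: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Flatten the image into N = (H/P)*(W/P) row-major patch vectors of
    length P^2*C.  Exactly invertible by :func:`reassemble_patches`."""
    H, W = image.shape[:2]
    P = grid.patch_size
    if H != grid.target_size or W != grid.target_size:
        raise ValueError("image does not match the grid's target size")
    C = image.shape[2]
    rows, cols = grid.grid_rows, grid.grid_cols
    tiled = image.reshape(rows, P, cols, P, C).transpose(0, 2, 1, 3, 4)
    return tiled.reshape(grid.n_patches, P * P * C)


def reassemble_patches(patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Inverse of :func:`extract_patches` (bit-exact round trip)."""
    P = grid.patch_size
    rows, cols = grid.grid_rows, grid.grid_cols
    C = patches.shape[1] // (P * P)
    tiled = patches.reshape(rows, cols, P, P, C).transpose(0, 2, 1, 3, 4)
    return tiled.reshape(rows * P, cols * P, C)


def preprocess(image: np.ndarray, stats: ChannelStats, grid: PatchGrid,
               fov_mask: np.ndarray | None = None):
    """Full deterministic pipeline: normalise -> mask -> resize -> patch.

    If no FOV mask is supplied it is estimated from the raw image.
    Returns (patches, resized_mask).
    """
    if fov_mask is None:
        fov_mask = estimate_fov_mask(image)
    normed = normalize_channels(image, stats)
    masked = apply_fov_mask(normed, np.asarray(fov_mask, dtype=float))
    resized, mask_r = resize_with_mask(masked, fov_mask, grid.target_size)
    return extract_patches(resized, grid), mask_r
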