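"""CT preprocessing: resampling, HU windowing, normalization, patching."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import VolumeImage

__all__ = ["preprocess_volume", "resample_mask", "random_patch"]

HU_WINDOW = (-1200.0, 600.0)   # lung-tissue density window
TARGET_SPACING = (1.0, 1.0, 1.0)


def preprocess_volume(raw: np.ndarray, spacing, hu_window=HU_WINDOW,
                      target_spacing=TARGET_SPACING) -> VolumeImage:
    """Trilinear resample to target spacing, clip to the HU window, map to [0,1]."""
    raw = np.asarray(raw, dtype=np.float64)
    if not np.isfinite(raw).all():
        raise ValueError("volume contains non-finite voxels")
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    lo, hi = hu_window
    factors = [s / t for s, t in zip(spacing, target_spacing)]
    if not np.allclose(factors, 1.0):
        raw = ndimage.zoom(raw, factors, order=1)
    clipped = np.clip(raw, lo, hi)
    return VolumeImage((clipped - lo) / (hi - lo), target_spacing)


def resample_mask(mask: np.ndarray, spacing, target_spacing=TARGET_SPACING) -> np.ndarray:
    """Nearest-neighbour resampling for label maps."""
    factors = [s / t for s, t in zip(spacing, target_spacing)]
    if np.allclose(factors, 1.0):
        return np.asarray(mask)
    return ndimage.zoom(np.asarray(mask), factors, order=0)


def random_patch(volume: VolumeImage, mask: np.ndarray, patch_size=(128, 128, 96),
                 seed: int = 0, noise_sd: float = 0.0):
    """Aligned random crop; Gaussian noise goes on the image only, never the mask."""
    shape = volume.data.shape
    patch_size = tuple(int(p) for p in patch_size)
    if any(p > s for p, s in zip(patch_size, shape)):
        raise ValueError(f"patch {patch_size} larger than volume {shape}")
    rng = np.random.default_rng(seed)
    start = [int(rng.integers(0, s - p + 1)) for s, p in zip(shape, patch_size)]
    sl = tuple(slice(a, a + p) for a, p in zip(start, patch_size))
    img = volume.data[sl].copy()
    m = np.asarray(mask)[sl].copy()
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return VolumeImage(np.clip(img, 0.0, 1.0), volume.spacing), m
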