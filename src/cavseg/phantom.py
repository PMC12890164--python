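"""Synthetic cavity phantoms.

Generates CT-like volumes containing hollow ellipsoidal cavities with
bright walls (optionally interrupted by angular gaps, mimicking wall
discontinuities), the matching ground-truth masks, the image-level
class of the case (a 5-way rubric over cavity count and maximum
diameter), and corrupted class-activation maps that emulate the weak
localization a classifier provides: partial coverage of the most
discriminative core, blur, and activation spill into background.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import CAMVolume, VolumeImage

__all__ = [
    "PhantomConfig",
    "CamCorruption",
    "classify_case",
    "generate_phantom",
    "corrupt_cam",
    "make_fixture_suite",
]

_MAX_PLACEMENT_TRIES = 500


@dataclass
class PhantomConfig:
    shape: tuple = (48, 48, 48)
    n_cavities: int = 2
    cavity_radius_range: tuple = (4.0, 8.0)
    wall_thickness: float = 2.0
    wall_gap_fraction: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise ValueError("shape must be three integers >= 16")
        if self.n_cavities < 0:
            raise ValueError("n_cavities must be non-negative")
        lo, hi = self.cavity_radius_range
        if not (0 < lo <= hi):
            raise ValueError("cavity_radius_range must satisfy 0 < min <= max")
        if not (0.0 <= self.wall_gap_fraction <= 1.0):
            raise ValueError("wall_gap_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CamCorruption:
    keep_fraction: float = 0.5
    blur_sigma: float = 1.0
    leak_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.keep_fraction <= 1.0):
            raise ValueError("keep_fraction must be in (0, 1]")
        if not np.isfinite([self.keep_fraction, self.blur_sigma, self.leak_sigma]).all():
            raise ValueError("corruption parameters must be finite")


def classify_case(n_cavities: int, max_diameter_mm: float) -> int:
    """5-way image-level class from cavity count and largest diameter.

    1: no cavities; 2/3: 1-3 cavities below/above 25 mm;
    4/5: more than 3 cavities below/above 25 mm.
    """
    if n_cavities == 0:
        return 1
    small = max_diameter_mm < 25.0
    if n_cavities <= 3:
        return 2 if small else 3
    return 4 if small else 5


def _ellipsoid_mask(shape, center, radii):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def generate_phantom(config: PhantomConfig):
    """Return ``(VolumeImage, mask, image_level_class)`` for one phantom.

    The mask is binary (1 = cavity lesion, wall included).  Deterministic
    for a fixed config/seed; raises ``RuntimeError`` if the requested
    cavities cannot be placed without overlap after bounded retries.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.shape

    # lung-parenchyma-like background: smoothed noise around a dark base
    bg = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    bg = 0.25 + 0.08 * (bg - bg.mean()) / (bg.std() + 1e-12)
    volume = bg

    mask = np.zeros(shape, dtype=np.int16)
    placed = []  # (center, outer_radii)
    max_diam_mm = 0.0
    for _ in range(config.n_cavities):
        ok = False
        for _try in range(_MAX_PLACEMENT_TRIES):
            radii = rng.uniform(*config.cavity_radius_range, size=3)
            outer = radii + config.wall_thickness
            if any(shape[a] - outer[a] - 1 <= outer[a] + 1 for a in range(3)):
                continue  # cavity too large for the volume; redraw radii
            center = np.array([
                rng.uniform(outer[a] + 1, shape[a] - outer[a] - 1) for a in range(3)
            ])
            if all(
                np.linalg.norm(center - c0) > (max(outer) + max(o0) + 1.0)
                for c0, o0 in placed
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {config.n_cavities} non-overlapping cavities "
                f"in shape {shape} after {_MAX_PLACEMENT_TRIES} tries"
            )
        placed.append((center, outer))

        inner = _ellipsoid_mask(shape, center, radii)
        full = _ellipsoid_mask(shape, center, outer)
        wall = full & ~inner
        if config.wall_gap_fraction > 0:
            # remove a random azimuthal sector of the wall (intensity only)
            gi, gj, _gk = np.ogrid[tuple(slice(0, s) for s in shape)]
            theta = np.arctan2(gj - center[1], gi - center[0])  # [-pi, pi]
            theta0 = rng.uniform(-np.pi, np.pi)
            width = config.wall_gap_fraction * 2 * np.pi
            dtheta = np.angle(np.exp(1j * (theta - theta0)))
            wall = wall & ~(np.abs(dtheta) <= width / 2)
        volume = np.where(inner, 0.05, volume)
        volume = np.where(wall, 0.9, volume)
        mask[full] = 1
        diam_mm = 2.0 * float(np.max(radii * np.asarray(config.spacing)))
        max_diam_mm = max(max_diam_mm, diam_mm)

    if config.noise_sd > 0:
        volume = volume + rng.normal(0.0, config.noise_sd, size=shape)
    volume = np.clip(volume, 0.0, 1.0)
    image_class = classify_case(config.n_cavities, max_diam_mm)
    return VolumeImage(volume, config.spacing), mask, image_class


def corrupt_cam(mask: np.ndarray, corruption: CamCorruption, n_classes: int = 2) -> CAMVolume:
    """Degrade a label mask into a weak CAM.

    ``keep_fraction`` retains only the core of each lesion (the voxels
    nearest its centroid) as high activation; ``blur_sigma`` smears it;
    ``leak_sigma`` adds smoothed half-normal activation spill everywhere.
    The identity corruption (1, 0, 0) reproduces the mask exactly.
    """
    mask = np.asarray(mask)
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if mask.max(initial=0) >= n_classes:
        raise ValueError("mask contains class ids >= n_classes")
    rng = np.random.default_rng(corruption.seed)
    cam = np.zeros(mask.shape + (n_classes,), dtype=np.float64)

    for cls in range(1, n_classes):
        cls_mask = mask == cls
        chan = np.zeros(mask.shape, dtype=np.float64)
        labels, n_comp = ndimage.label(cls_mask)
        for comp in range(1, n_comp + 1):
            comp_idx = np.argwhere(labels == comp)
            n_keep = int(round(corruption.keep_fraction * len(comp_idx)))
            n_keep = max(n_keep, 1)
            centroid = comp_idx.mean(axis=0)
            d = np.linalg.norm(comp_idx - centroid, axis=1)
            order = np.argsort(d, kind="stable")
            kept = comp_idx[order[:n_keep]]
            chan[tuple(kept.T)] = 1.0
        if corruption.blur_sigma > 0:
            chan = ndimage.gaussian_filter(chan, corruption.blur_sigma)
            peak = chan.max()
            if peak > 0:
                chan = chan / peak
        if corruption.leak_sigma > 0:
            leak = np.abs(rng.normal(0.0, corruption.leak_sigma, size=mask.shape))
            chan = chan + ndimage.gaussian_filter(leak, 1.0)
        cam[..., cls] = np.clip(chan, 0.0, 1.0)

    cam[..., 0] = 1.0 - cam[..., 1:].max(axis=-1)
    names = ["background"] + [f"class_{c}" for c in range(1, n_classes)]
    return CAMVolume(cam, class_names=names)


def make_fixture_suite(n_cases: int, out_dir, seed: int = 0,
                       config: PhantomConfig | None = None,
                       corruption: CamCorruption | None = None) -> dict:
    """Write `n_cases` NIfTI volume/mask/CAM triplets plus a JSON manifest."""
    import nibabel as nib

    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base_cfg = config or PhantomConfig()
    base_cor = corruption or CamCorruption()
    rng = np.random.default_rng(seed)

    entries = []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        n_cav = int(rng.integers(0, 4))
        while True:  # drop cavities that cannot be placed in this volume
            cfg = PhantomConfig(
                shape=base_cfg.shape, n_cavities=n_cav,
                cavity_radius_range=base_cfg.cavity_radius_range,
                wall_thickness=base_cfg.wall_thickness,
                wall_gap_fraction=base_cfg.wall_gap_fraction,
                noise_sd=base_cfg.noise_sd, seed=case_seed, spacing=base_cfg.spacing,
            )
            try:
                vol, mask, cls = generate_phantom(cfg)
                break
            except RuntimeError:
                if n_cav == 0:
                    raise
                n_cav -= 1
        cor = CamCorruption(base_cor.keep_fraction, base_cor.blur_sigma,
                            base_cor.leak_sigma, seed=case_seed + 1)
        cam = corrupt_cam(mask, cor, n_classes=2)

        affine = np.diag(list(cfg.spacing) + [1.0])
        case_id = f"case_{i:03d}"
        paths = {}
        for name, arr in (("volume", vol.data.astype(np.float32)),
                          ("mask", mask.astype(np.int16)),
                          ("cam", cam.values.astype(np.float32))):
            p = out_dir / f"{case_id}_{name}.nii.gz"
            nib.save(nib.Nifti1Image(arr, affine), p)
            paths[name] = p.name
        entries.append({
            "case_id": case_id, "paths": paths, "class": cls,
            "seed": case_seed, "spacing": list(cfg.spacing),
            "patient_id": f"patient_{i:03d}",
        })

    manifest = {"n_cases": n_cases, "seed": seed, "cases": entries}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    digest = hashlib.sha256(manifest_path.read_bytes()).hexdigest()
    manifest["sha256"] = digest
    return manifest
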