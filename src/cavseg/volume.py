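"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["VolumeImage", "CAMVolume"]


@dataclass
class VolumeImage:
    """A 3D scalar field with voxel spacing in mm.

    After preprocessing, intensities live in [0, 1].
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("VolumeImage requires a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive floats")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class CAMVolume:
    """Per-voxel, per-class activation field ``M`` of shape (h, w, d, C) in [0, 1]."""

    values: np.ndarray
    class_names: Sequence[str] = field(default_factory=list)
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError("CAMVolume requires a 4D (h,w,d,C) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CAM values must be finite")
        if not self.class_names:
            self.class_names = [f"class_{c}" for c in range(self.values.shape[-1])]
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_classes(self) -> int:
        return self.values.shape[-1]

    @property
    def grid_shape(self):
        return self.values.shape[:3]
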