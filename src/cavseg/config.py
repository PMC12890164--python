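"""Pipeline configuration: one JSON-serializable object holding every knob.

Defaults follow the method's reference operating point: dual thresholds
(0.32, 0.46), (7,7,7) affinity window, 4 attention layers of width 256,
EMA (delta=0.2, gamma=8), loss weights (0.6, 0.5, 0.5, 0.7, 0.5), kNN
k=10, HU window [-1200, 600] at 1 mm isotropic, 128x128x96 patches.
Desk-scale runs override the size-bearing knobs (see ``reduced``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # pseudo-label thresholds
    phi_l: float = 0.32
    phi_h: float = 0.46
    # graph construction
    n_segments: int = 2000
    compactness: float = 0.1
    k: int = 10
    # edge-inference network
    n_layers: int = 4
    feature_dim: int = 256
    ganet_steps: int = 200
    ganet_lr: float = 1e-2
    # voxel affinity
    window: tuple = (7, 7, 7)
    aff_head_steps: int = 50
    aff_pairs: int = 2000
    # propagation
    eta: float = 4.0
    block_size: tuple = (32, 32, 32)
    overlap_fraction: float = 0.5
    use_region_graph: bool = True
    n_iterations: int = 1
    # classifier
    n_classes: int = 5
    classifier_steps: int = 200
    classifier_lr: float = 1e-2
    cam_source: str = "manifest"      # "manifest" (precomputed) or "classifier"
    # segmentation
    seg_steps: int = 200
    seg_channels: tuple = (8, 16)
    delta: float = 0.2
    gamma: int = 8
    epsilon: float = 0.15
    scribble_stride: int = 4
    scribble_band: int = 1
    # loss weights (lambda1..lambda5)
    lambda1: float = 0.6
    lambda2: float = 0.5
    lambda3: float = 0.5
    lambda4: float = 0.7
    lambda5: float = 0.5
    # ablation switches
    use_struct: bool = True
    use_aff: bool = True
    use_smooth: bool = True
    use_pce: bool = True
    # preprocessing
    hu_window: tuple = (-1200.0, 600.0)
    target_spacing: tuple = (1.0, 1.0, 1.0)
    patch_size: tuple = (128, 128, 96)
    preprocess: bool = False          # phantom manifests ship normalized volumes
    # global
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.phi_l < self.phi_h < 1):
            raise ValueError("need 0 < phi_l < phi_h < 1")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.cam_source not in ("manifest", "classifier"):
            raise ValueError("cam_source must be 'manifest' or 'classifier'")
        for name in ("window", "block_size", "patch_size", "target_spacing",
                     "hu_window", "seg_channels"):
            setattr(self, name, tuple(getattr(self, name)))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def reduced(cls, **overrides) -> "PipelineConfig":
        """Desk-scale configuration for small phantom volumes."""
        base = dict(
            n_segments=80, k=6, feature_dim=16, ganet_steps=100,
            window=(5, 5, 5), block_size=(16, 16, 16), classifier_steps=100,
            seg_steps=100, aff_head_steps=25, aff_pairs=1000,
            # at ~80 superpixels per volume the region-graph broadcast blends
            # the CAM core below phi_h; the region stage needs finer partitions
            use_region_graph=False,
        )
        base.update(overrides)
        return cls(**base)
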