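"""Pseudo-supervised segmentation training.

A small 3D encoder-decoder learns a foreground probability field from
refined pseudo labels (smoothed cross-entropy on labeled voxels) plus
sparse scribbles derived from pseudo-label contours (partial
cross-entropy on scribbled voxels only).  Per-case predictions are
stabilized by exponential moving averaging, updated every ``gamma``
visits of the case with smoothing factor ``delta``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import ndimage

from ._nn import AdamW, Conv3d, avgpool2, upsample2
from ._tensor import Tensor, gather
from .pseudolabel import IGNORE, PseudoLabel
from .volume import VolumeImage

__all__ = [
    "UNLABELED",
    "EmaState",
    "ScribbleSet",
    "LossWeights",
    "SegmenterConfig",
    "seg_loss",
    "ema_update",
    "extract_scribbles",
    "partial_ce",
    "total_loss",
    "SegNet",
    "train_segmenter",
]

log = logging.getLogger(__name__)

UNLABELED = -1      # scribble sentinel in memory; 255 in exported NIfTI
_CLAMP = 1e-7


@dataclass
class EmaState:
    y: np.ndarray               # (D, H, W, K) averaged probability field
    delta: float = 0.2
    gamma: int = 8
    update_count: int = 0

    def __post_init__(self):
        if not (0 < self.delta <= 1):
            raise ValueError("delta must be in (0, 1]")
        if self.gamma < 1:
            raise ValueError("gamma must be a positive integer")


@dataclass
class ScribbleSet:
    labels: np.ndarray          # {0, 1, UNLABELED}
    provenance: str = ""

    def __post_init__(self):
        vals = np.unique(self.labels)
        if not np.isin(vals, [0, 1, UNLABELED]).all():
            raise ValueError("scribble labels must be 0, 1 or UNLABELED")

    @property
    def support(self) -> np.ndarray:
        return self.labels != UNLABELED

    @property
    def n_scribbled(self) -> int:
        return int(self.support.sum())


@dataclass
class LossWeights:
    lambda1: float = 0.6   # structural consistency
    lambda2: float = 0.5   # smoothness prior
    lambda3: float = 0.5   # focal affinity
    lambda4: float = 0.7   # partial cross-entropy (scribbles)
    lambda5: float = 0.5   # pseudo-supervised segmentation

    def __post_init__(self):
        vals = [self.lambda1, self.lambda2, self.lambda3, self.lambda4, self.lambda5]
        if not np.isfinite(vals).all() or any(v < 0 for v in vals):
            raise ValueError("loss weights must be finite and >= 0")


@dataclass
class SegmenterConfig:
    channels: tuple = (8, 16)
    steps: int = 200
    lr: float = 1e-2
    weight_decay: float = 0.05
    epsilon: float = 0.15
    delta: float = 0.2
    gamma: int = 8
    lambda_pce: float = 0.7
    lambda_seg: float = 0.5
    seed: int = 0


def seg_loss(predictions: np.ndarray, pseudo: PseudoLabel,
             epsilon: float = 0.15, n_classes: int | None = None) -> float:
    """Smoothed cross-entropy over the pseudo label's non-IGNORE support.

    ``predictions`` has shape grid + (K,); the per-voxel target is
    ``(1 - eps) * onehot + eps / K``.
    """
    p = np.clip(np.asarray(predictions, dtype=np.float64), _CLAMP, 1 - _CLAMP)
    K = n_classes or p.shape[-1]
    lab = pseudo.values
    support = lab != IGNORE
    if not support.any():
        raise ValueError("pseudo label has empty labeled support")
    labs = lab[support]
    t = (1 - epsilon) * np.eye(K)[labs] + epsilon / K
    return float(-(t * np.log(p[support])).sum(axis=1).mean())


def ema_update(state: EmaState, prediction: np.ndarray, iteration: int) -> EmaState:
    """EMA step ``y_n = delta * f + (1 - delta) * y_{n-1}``.

    Applied only when ``iteration`` is a multiple of ``gamma``; other
    iterations return the state unchanged.
    """
    prediction = np.asarray(prediction, dtype=np.float64)
    if prediction.shape != state.y.shape:
        raise ValueError("prediction shape mismatch with EMA state")
    if iteration % state.gamma != 0:
        return state
    y = state.delta * prediction + (1 - state.delta) * state.y
    return replace(state, y=y, update_count=state.update_count + 1)


def extract_scribbles(pseudo: PseudoLabel, stride: int = 4, band: int = 1) -> ScribbleSet:
    """Sparse boundary scribbles from pseudo-label contours.

    Foreground scribbles subsample the inner contour (erosion residue of
    width ``band``) of each foreground component; background scribbles
    subsample a shell at distance ``band`` outside the component,
    restricted to reliably-background voxels.  Empty masks yield an
    empty (flagged) scribble set.
    """
    if stride < 1 or band < 1:
        raise ValueError("stride and band must be >= 1")
    lab = pseudo.values
    fg = lab > 0
    out = np.full(lab.shape, UNLABELED, dtype=np.int16)
    if not fg.any():
        log.warning("extract_scribbles: no foreground component; empty scribble set")
        return ScribbleSet(out, provenance="empty")

    inner = fg & ~ndimage.binary_erosion(fg, iterations=band)
    dil_b = ndimage.binary_dilation(fg, iterations=band)
    dil_b1 = ndimage.binary_dilation(fg, iterations=band - 1) if band > 1 else fg
    outer = dil_b & ~dil_b1 & (lab == 0)

    for value, contour in ((1, inner), (0, outer)):
        idx = np.argwhere(contour)
        keep = idx[::stride]
        out[tuple(keep.T)] = value
    sparsity = (out != UNLABELED).mean()
    log.info("extract_scribbles: %.4f%% of voxels scribbled", 100 * sparsity)
    return ScribbleSet(out, provenance="pseudo-label contours")


def partial_ce(predictions: np.ndarray, scribbles: ScribbleSet) -> float:
    """Binary cross-entropy restricted to scribbled voxels."""
    if scribbles.n_scribbled == 0:
        raise ValueError("empty scribble support")
    p = np.clip(np.asarray(predictions, dtype=np.float64), _CLAMP, 1 - _CLAMP)
    s = scribbles.support
    y = scribbles.labels[s].astype(np.float64)
    pv = p[s]
    return float(-(y * np.log(pv) + (1 - y) * np.log(1 - pv)).mean())


def total_loss(l_cls: float, l_struct: float, l_smooth: float, l_aff: float,
               l_pce: float, l_seg: float, weights: LossWeights = LossWeights()) -> float:
    """Weighted combination of the six pipeline loss components."""
    return float(l_cls + weights.lambda1 * l_struct + weights.lambda2 * l_smooth
                 + weights.lambda3 * l_aff + weights.lambda4 * l_pce
                 + weights.lambda5 * l_seg)


class SegNet:
    """3-level U-style encoder-decoder emitting a foreground probability."""

    def __init__(self, config: SegmenterConfig):
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.channels
        self.config = config
        self.enc1 = Conv3d(rng, 1, c1)
        self.enc2 = Conv3d(rng, c1, c2)
        self.dec1 = Conv3d(rng, c2, c1)
        self.out = Conv3d(rng, c1, 1, k=1)

    def params(self):
        return (self.enc1.params() + self.enc2.params()
                + self.dec1.params() + self.out.params())

    def forward(self, volume: np.ndarray) -> Tensor:
        x = Tensor(volume[None])
        e1 = self.enc1(x).relu()
        e2 = self.enc2(avgpool2(e1)).relu()
        d1 = self.dec1(upsample2(e2)).relu()
        logits = self.out(d1 + e1)
        return logits.reshape(*volume.shape).sigmoid()

    def predict(self, volume: VolumeImage) -> np.ndarray:
        return np.asarray(self.forward(volume.data).data)


def _dsc(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = np.logical_and(pred, truth).sum()
    denom = pred.sum() + truth.sum()
    return 1.0 if denom == 0 else 2.0 * inter / denom


def train_segmenter(volumes: Sequence[VolumeImage], pseudolabels: Sequence[PseudoLabel],
                    scribbles: Sequence[ScribbleSet], config: SegmenterConfig = SegmenterConfig(),
                    truth_masks: Optional[Sequence[np.ndarray]] = None):
    """Train the segmenter with smoothed CE + partial CE under EMA ensembling.

    Returns ``(model, ema_states, history)``; ``ema_states[i].y`` holds
    the ensembled (background, foreground) probability field for case i.
    """
    n = len(volumes)
    model = SegNet(config)
    opt = AdamW(model.params(), lr=config.lr, weight_decay=config.weight_decay)
    eps = config.epsilon
    rng = np.random.default_rng(config.seed + 1)
    ema: Dict[int, EmaState] = {}
    visits = np.zeros(n, dtype=int)
    history: List[dict] = []

    for step in range(config.steps):
        i = int(rng.integers(n))
        p = model.forward(volumes[i].data).clip(_CLAMP, 1 - _CLAMP)
        flat = p.reshape(-1)

        lab = pseudolabels[i].values.ravel()
        support = np.where(lab != IGNORE)[0]
        if len(support) == 0:
            raise ValueError(f"case {i}: empty pseudo-label support")
        y = (lab[support] > 0).astype(np.float64)
        t = (1 - eps) * y + eps / 2.0
        pv = gather(flat, support)
        l_seg = -(Tensor(t) * pv.log() + Tensor(1 - t) * (1 - pv).log()).mean()

        scr = scribbles[i]
        if scr.n_scribbled > 0:
            sidx = np.where(scr.labels.ravel() != UNLABELED)[0]
            sy = (scr.labels.ravel()[sidx] > 0).astype(np.float64)
            sv = gather(flat, sidx)
            l_pce = -(Tensor(sy) * sv.log() + Tensor(1 - sy) * (1 - sv).log()).mean()
        else:
            l_pce = Tensor(0.0)

        loss = config.lambda_seg * l_seg + config.lambda_pce * l_pce
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite segmentation loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()

        pred_field = np.stack([1 - p.data, p.data], axis=-1)
        if i not in ema:
            ema[i] = EmaState(pred_field, delta=config.delta, gamma=config.gamma)
        else:
            ema[i] = ema_update(ema[i], pred_field, int(visits[i]))
        visits[i] += 1

        rec = {"step": step, "case": i, "loss_seg": float(l_seg.data),
               "loss_pce": float(l_pce.data)}
        if truth_masks is not None:
            rec["val_dsc"] = _dsc(p.data > 0.5, np.asarray(truth_masks[i]) > 0)
        history.append(rec)

    return model, ema, history
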