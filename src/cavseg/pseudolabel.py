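"""CAM-driven pseudo-label generation.

Covers the weak-supervision front end: a small convolutional classifier
trained on image-level labels with label-smoothing cross-entropy, CAM
extraction from its global-average-pooled head, dual-threshold
partitioning of the CAM into reliable foreground / background / ignored
voxels, the voxel-level affinity converter (normalized cosine within a
local 3D window), affinity-target derivation from reliable label pairs,
and the focal affinity loss in logit space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from ._nn import AdamW, Conv3d, Linear, avgpool2
from ._tensor import Tensor, gather as gather_rows
from .volume import CAMVolume, VolumeImage

__all__ = [
    "IGNORE",
    "PseudoLabel",
    "SparseAffinity",
    "AffinityTargets",
    "ClassifierConfig",
    "CamClassifier",
    "classification_loss",
    "train_classifier_and_cam",
    "cam_from_features",
    "cavity_foreground_cam",
    "dual_threshold",
    "voxel_affinity",
    "affinity_to_logit",
    "derive_affinity_targets",
    "focal_affinity_loss",
    "intensity_embedding",
    "train_affinity_head",
]

log = logging.getLogger(__name__)

IGNORE = -1          # in-memory sentinel; 255 in exported NIfTI label maps
_CLAMP = 1e-7


@dataclass
class PseudoLabel:
    """Per-voxel status: 0 background, 1..C foreground class, IGNORE."""

    values: np.ndarray
    legend: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("pseudo-label values must be integers")
        bad = (self.values < 0) & (self.values != IGNORE)
        if bad.any():
            raise ValueError("negative label other than the IGNORE sentinel")
        if not self.legend:
            classes = sorted(int(v) for v in np.unique(self.values) if v > 0)
            self.legend = {0: "background", IGNORE: "ignore",
                           **{c: f"class_{c}" for c in classes}}

    def status_counts(self) -> Tuple[int, int, int]:
        fg = int((self.values > 0).sum())
        bg = int((self.values == 0).sum())
        ign = int((self.values == IGNORE).sum())
        return fg, bg, ign


@dataclass
class SparseAffinity:
    """Symmetric voxel-pair affinity restricted to a local window.

    ``entries[offset]`` holds A(v, v + offset) for every voxel v whose
    partner lies in bounds; only lexicographically positive offsets are
    stored (symmetry supplies the rest) and the self-affinity is 1 by
    definition.  ``is_logit`` marks containers holding pre-sigmoid
    log-odds instead of [0,1] affinities.
    """

    grid_shape: tuple
    window: tuple                       # full window size per axis, odd
    entries: Dict[tuple, np.ndarray]
    is_logit: bool = False

    def __post_init__(self):
        if any(w % 2 != 1 or w < 1 for w in self.window):
            raise ValueError("window sizes must be odd positive integers")
        if not self.is_logit:
            for off, arr in self.entries.items():
                sl = _overlap_slices(self.grid_shape, off)[0]
                vals = arr[sl]
                if ((vals < 0) | (vals > 1)).any():
                    raise ValueError(f"affinity out of [0,1] at offset {off}")

    @property
    def half_extent(self) -> tuple:
        return tuple(w // 2 for w in self.window)

    def get(self, u: tuple, v: tuple) -> float:
        if u == v:
            return 0.0 if self.is_logit else 1.0
        off = tuple(b - a for a, b in zip(u, v))
        if off in self.entries:
            return float(self.entries[off][u])
        neg = tuple(-o for o in off)
        if neg in self.entries:
            return float(self.entries[neg][v])
        raise KeyError(f"pair offset {off} outside the window")


@dataclass
class AffinityTargets:
    """Reliable same/different-label voxel pairs within the window."""

    grid_shape: tuple
    window: tuple
    positive_masks: Dict[tuple, np.ndarray]
    negative_masks: Dict[tuple, np.ndarray]
    n_positive: int
    n_negative: int

    def __post_init__(self):
        for off in self.positive_masks:
            if (self.positive_masks[off] & self.negative_masks[off]).any():
                raise ValueError("positive and negative pair sets overlap")
        np_ = sum(int(m.sum()) for m in self.positive_masks.values())
        nn = sum(int(m.sum()) for m in self.negative_masks.values())
        if np_ != self.n_positive or nn != self.n_negative:
            raise ValueError("counts inconsistent with masks")


# ---------------------------------------------------------------------------
# classifier + CAM

@dataclass
class ClassifierConfig:
    n_classes: int = 5
    channels: tuple = (8, 16)
    steps: int = 200
    batch_size: int = 4         # cases per gradient step (accumulated)
    lr: float = 1e-2
    weight_decay: float = 0.05
    epsilon: float = 0.15       # label smoothing
    seed: int = 0


def classification_loss(probabilities: np.ndarray, labels: Sequence[int],
                        epsilon: float = 0.15, n_classes: int | None = None) -> float:
    """Label-smoothing one-vs-rest cross-entropy, averaged over cases.

    Targets are smoothed to ``(1 - eps) * onehot + eps / K``.
    """
    p = np.clip(np.atleast_2d(np.asarray(probabilities, dtype=np.float64)),
                _CLAMP, 1 - _CLAMP)
    labels = np.asarray(labels, dtype=np.int64)
    K = n_classes or p.shape[1]
    if not (0 <= epsilon < 1):
        raise ValueError("epsilon must be in [0, 1)")
    onehot = np.eye(K)[labels]
    t = (1 - epsilon) * onehot + epsilon / K
    ce = -(t * np.log(p) + (1 - t) * np.log(1 - p))
    return float(ce.sum(axis=1).mean())


class CamClassifier:
    """3-level convolutional encoder with a GAP-linear classification head."""

    def __init__(self, config: ClassifierConfig):
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.channels
        self.config = config
        self.conv1 = Conv3d(rng, 1, c1)
        self.conv2 = Conv3d(rng, c1, c2)
        self.conv3 = Conv3d(rng, c2, c2)
        self.head = Linear(rng, c2, config.n_classes)

    def params(self):
        return (self.conv1.params() + self.conv2.params()
                + self.conv3.params() + self.head.params())

    def forward(self, volume: np.ndarray):
        x = Tensor(volume[None])           # (1, D, H, W)
        f1 = self.conv1(x).relu()
        f2 = self.conv2(avgpool2(f1)).relu()
        f3 = self.conv3(avgpool2(f2)).relu()
        pooled = f3.reshape(f3.shape[0], -1).mean(axis=1)
        probs = self.head(pooled).sigmoid()
        return probs, f3, f1

    def encoder_features(self, volume: VolumeImage) -> np.ndarray:
        """Full-resolution per-voxel feature field (first conv level)."""
        _, _, f1 = self.forward(volume.data)
        return np.moveaxis(f1.data, 0, -1)

    def cam(self, volume: VolumeImage) -> CAMVolume:
        """Per-class CAM, min-max normalized, upsampled to the input grid."""
        _, f3, _ = self.forward(volume.data)
        raw = cam_from_features(np.moveaxis(f3.data, 0, -1), self.head.weight.data)
        full = np.empty(volume.data.shape + (self.config.n_classes,))
        for k in range(raw.shape[-1]):
            zoom = [t / s for t, s in zip(volume.data.shape, raw.shape[:3])]
            chan = ndimage.zoom(raw[..., k], zoom, order=1)
            lo, hi = chan.min(), chan.max()
            chan = (chan - lo) / (hi - lo) if hi > lo else np.zeros_like(chan)
            full[..., k] = np.clip(chan, 0, 1)
        names = [f"class_{k + 1}" for k in range(self.config.n_classes)]
        return CAMVolume(full, class_names=names, spacing=volume.spacing)


def cam_from_features(features: np.ndarray, class_weights: np.ndarray) -> np.ndarray:
    """Raw CAM: class-weight-weighted sum of feature maps (no normalization).

    ``features`` is (d, h, w, C_feat); ``class_weights`` is (C_feat, K).
    """
    return np.tensordot(features, class_weights, axes=([-1], [0]))


def train_classifier_and_cam(volumes: List[VolumeImage], labels: Sequence[int],
                             config: ClassifierConfig = ClassifierConfig()):
    """Train the classifier on image-level classes (1-based) and emit CAMs.

    Returns ``(classifier, cams, history)`` where ``cams`` holds one
    normalized per-class CAMVolume per case.
    """
    labels0 = np.asarray(labels, dtype=np.int64) - 1
    if len(np.unique(labels0)) < 2:
        raise ValueError("training manifest must contain at least two classes")
    if (labels0 < 0).any() or (labels0 >= config.n_classes).any():
        raise ValueError("labels outside 1..n_classes")
    model = CamClassifier(config)
    opt = AdamW(model.params(), lr=config.lr, weight_decay=config.weight_decay)
    eps, K = config.epsilon, config.n_classes
    n = len(volumes)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    batch = max(1, min(config.batch_size, n))
    for step in range(config.steps):
        opt.zero_grad()
        batch_loss = 0.0
        for i in rng.choice(n, size=batch, replace=False):
            probs, _, _ = model.forward(volumes[i].data)
            p = probs.clip(_CLAMP, 1 - _CLAMP)
            t = (1 - eps) * np.eye(K)[labels0[i]] + eps / K
            loss = -(Tensor(t) * p.log() + Tensor(1 - t) * (1 - p).log()).sum() * (1.0 / batch)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite classification loss at step {step}")
            loss.backward()
            batch_loss += float(loss.data)
        opt.step()
        history.append({"step": step, "loss_cls": batch_loss})
    cams = [model.cam(v) for v in volumes]
    return model, cams, history


def cavity_foreground_cam(cam: CAMVolume) -> CAMVolume:
    """Collapse a multi-class CAM to (background, cavity) channels.

    Cavity activation is the max over the cavity-bearing classes
    (every class channel after the first, 'no cavities', one).
    """
    fg = cam.values[..., 1:].max(axis=-1)
    out = np.stack([1.0 - fg, fg], axis=-1)
    return CAMVolume(out, class_names=["background", "cavity"], spacing=cam.spacing)


# ---------------------------------------------------------------------------
# dual-threshold pseudo labels

def dual_threshold(cam: CAMVolume, phi_l: float = 0.32, phi_h: float = 0.46) -> PseudoLabel:
    """Partition the CAM into foreground / background / IGNORE.

    The maximum is taken over the foreground class channels (channel 0
    is background): >= phi_h assigns the argmax class, <= phi_l assigns
    background, the uncertainty band in between is ignored.
    """
    if not (0 < phi_l < phi_h < 1):
        raise ValueError("thresholds must satisfy 0 < phi_l < phi_h < 1")
    fg = cam.values[..., 1:]
    max_act = fg.max(axis=-1)
    arg = fg.argmax(axis=-1) + 1
    out = np.full(cam.grid_shape, IGNORE, dtype=np.int16)
    out[max_act <= phi_l] = 0
    hi = max_act >= phi_h
    out[hi] = arg[hi].astype(np.int16)
    legend = {0: "background", IGNORE: "ignore",
              **{c + 1: cam.class_names[c + 1] for c in range(fg.shape[-1])}}
    return PseudoLabel(out, legend)


# ---------------------------------------------------------------------------
# voxel affinity

def _positive_offsets(half: tuple):
    offs = []
    for di in range(-half[0], half[0] + 1):
        for dj in range(-half[1], half[1] + 1):
            for dk in range(-half[2], half[2] + 1):
                if (di, dj, dk) > (0, 0, 0):
                    offs.append((di, dj, dk))
    return offs


def _overlap_slices(shape, off):
    """Slices (for the base voxel and its partner) where v + off stays in bounds."""
    src, dst = [], []
    for s, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, s - o))
            dst.append(slice(o, s))
        else:
            src.append(slice(-o, s))
            dst.append(slice(0, s + o))
    return tuple(src), tuple(dst)


def voxel_affinity(features: np.ndarray, window: tuple = (7, 7, 7)) -> SparseAffinity:
    """Affinity converter: normalized cosine ``(cos + 1) / 2`` per voxel pair.

    Zero-norm feature vectors get uninformative affinity 0.5 (logged).
    """
    features = np.asarray(features, dtype=np.float64)
    shape = features.shape[:3]
    norms = np.linalg.norm(features, axis=-1)
    zero = norms < 1e-12
    if zero.any():
        log.warning("voxel_affinity: %d zero-norm feature vectors set to 0.5", zero.sum())
    unit = features / np.where(zero, 1.0, norms)[..., None]
    half = tuple(w // 2 for w in window)
    entries = {}
    for off in _positive_offsets(half):
        src, dst = _overlap_slices(shape, off)
        cos = np.sum(unit[src] * unit[dst], axis=-1)
        aff = np.clip((cos + 1.0) / 2.0, 0.0, 1.0)
        aff[zero[src] | zero[dst]] = 0.5
        full = np.zeros(shape)
        full[src] = aff
        entries[off] = full
    return SparseAffinity(shape, tuple(window), entries)


def affinity_to_logit(affinity: SparseAffinity, clamp: float = 1e-4) -> SparseAffinity:
    """Log-odds transform of a [0,1] affinity container."""
    if affinity.is_logit:
        return affinity
    entries = {}
    for off, arr in affinity.entries.items():
        a = np.clip(arr, clamp, 1 - clamp)
        entries[off] = np.log(a / (1 - a))
    return SparseAffinity(affinity.grid_shape, affinity.window, entries, is_logit=True)


def derive_affinity_targets(pseudo: PseudoLabel, window: tuple = (7, 7, 7)) -> AffinityTargets:
    """Reliable voxel pairs: same non-IGNORE label -> positive, different -> negative."""
    lab = pseudo.values
    half = tuple(w // 2 for w in window)
    pos, neg = {}, {}
    n_pos = n_neg = 0
    for off in _positive_offsets(half):
        src, dst = _overlap_slices(lab.shape, off)
        a, b = lab[src], lab[dst]
        reliable = (a != IGNORE) & (b != IGNORE)
        p = reliable & (a == b)
        q = reliable & (a != b)
        pm = np.zeros(lab.shape, dtype=bool)
        nm = np.zeros(lab.shape, dtype=bool)
        pm[src], nm[src] = p, q
        pos[off], neg[off] = pm, nm
        n_pos += int(p.sum())
        n_neg += int(q.sum())
    if n_pos + n_neg == 0:
        raise ValueError("no reliable voxel pairs (all-IGNORE pseudo label?)")
    return AffinityTargets(lab.shape, tuple(window), pos, neg, n_pos, n_neg)


def intensity_embedding(volume: np.ndarray, anchors=(0.05, 0.25, 0.5, 0.75, 0.95),
                        sigma: float = 0.12, smooth: float = 1.0) -> np.ndarray:
    """Soft-assignment appearance descriptor for cosine affinity.

    Raw intensities are near-collinear as 1D vectors (cosine cannot
    separate them); encoding each voxel by RBF responses to a few
    intensity anchors (raw and smoothed) turns tissue classes into
    distinct directions.
    """
    volume = np.asarray(volume, dtype=np.float64)
    s = ndimage.gaussian_filter(volume, smooth)
    feats = [np.exp(-((x - c) ** 2) / (2 * sigma**2)) for x in (volume, s) for c in anchors]
    return np.stack(feats, axis=-1)


def _balanced_pairs(targets: AffinityTargets, labels: np.ndarray,
                    n_per_group: int, rng: np.random.Generator):
    """Index pairs split into fg-fg / bg-bg positives and negatives.

    Foreground-foreground positives are ~10^2 rarer than background
    ones; uniform sampling would teach the head nothing about lesions.
    """
    shape = labels.shape
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    flat_lab = labels.ravel()
    groups = {"pos_fg": [], "pos_bg": [], "neg": []}
    for off, m in targets.positive_masks.items():
        idx = np.argwhere(m)
        if len(idx) == 0:
            continue
        s = idx @ strides
        d = (idx + np.array(off)) @ strides
        fg = flat_lab[s] > 0
        groups["pos_fg"].append((s[fg], d[fg]))
        groups["pos_bg"].append((s[~fg], d[~fg]))
    for off, m in targets.negative_masks.items():
        idx = np.argwhere(m)
        if len(idx) == 0:
            continue
        groups["neg"].append((idx @ strides, (idx + np.array(off)) @ strides))
    out = {}
    for name, parts in groups.items():
        if not parts:
            out[name] = (np.empty(0, np.int64), np.empty(0, np.int64))
            continue
        s = np.concatenate([a for a, _ in parts])
        d = np.concatenate([b for _, b in parts])
        if len(s) > n_per_group:
            sel = rng.choice(len(s), n_per_group, replace=False)
            s, d = s[sel], d[sel]
        out[name] = (s, d)
    return out


def train_affinity_head(features: np.ndarray, targets: AffinityTargets,
                        pseudo: PseudoLabel | None = None,
                        n_pairs: int = 2000, steps: int = 50, lr: float = 1e-2,
                        hidden: int = 16, scale: float = 4.0, seed: int = 0):
    """Fit a small MLP head on voxel features with the focal affinity loss.

    Voxel pairs are subsampled from the targets with class balancing
    (fg-fg, bg-bg, fg-bg quotas when ``pseudo`` is given); the pairwise
    logit is ``scale * cos`` of the projected features.  Returns
    ``(projected_features, history)``; the projected field feeds
    ``voxel_affinity``.
    """
    features = np.asarray(features, dtype=np.float64)
    shape = features.shape[:3]
    F = features.shape[-1]
    rng = np.random.default_rng(seed)
    labels = pseudo.values if pseudo is not None else np.zeros(shape, dtype=np.int16)
    n_per = max(1, n_pairs // 3)
    pairs = _balanced_pairs(targets, labels, n_per, rng)

    rng2 = np.random.default_rng(seed + 1)
    l1 = Linear(rng2, F, hidden)
    l2 = Linear(rng2, hidden, hidden)
    opt = AdamW(l1.params() + l2.params(), lr=lr)
    x = Tensor(features.reshape(-1, F))
    history = []
    for step in range(steps):
        z = l2(l1(x).relu())
        inv_norm = ((z * z).sum(axis=1, keepdims=True) + 1e-12) ** -0.5
        zn = z * inv_norm
        loss = Tensor(0.0)
        for name, (s, d) in pairs.items():
            if len(s) == 0:
                continue
            cos = (gather_rows(zn, s) * gather_rows(zn, d)).sum(axis=1)
            sign = scale if name == "neg" else -scale
            loss = loss + (cos * sign).softplus().mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append({"step": step, "loss_aff": float(loss.data)})
    z = l2(l1(x).relu()).data
    return z.reshape(shape + (hidden,)), history


def focal_affinity_loss(w_aff: SparseAffinity, targets: AffinityTargets) -> float:
    """Softplus affinity loss on logits.

    ``(1/N+) sum softplus(-W) over positive pairs + (1/N-) sum
    softplus(W) over negative pairs``; a term with an empty pair set is
    skipped.
    """
    if not w_aff.is_logit:
        raise ValueError("focal_affinity_loss consumes logits; use affinity_to_logit")
    if targets.n_positive == 0 and targets.n_negative == 0:
        raise ValueError("both pair sets are empty")
    loss = 0.0
    for off in targets.positive_masks:
        W = w_aff.entries[off]
        pm, nm = targets.positive_masks[off], targets.negative_masks[off]
        if targets.n_positive:
            loss += np.logaddexp(0.0, -W[pm]).sum() / targets.n_positive
        if targets.n_negative:
            loss += np.logaddexp(0.0, W[nm]).sum() / targets.n_negative
    return float(loss)
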