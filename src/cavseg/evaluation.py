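"""Segmentation/classification metrics and the paired statistical protocol.

DSC, IoU and the 95th-percentile symmetric Hausdorff surface distance
(mm, spacing-aware) per case; macro-averaged classification metrics
with one-vs-rest AUC; patient-level paired Wilcoxon signed-rank testing
(exact for small n, Pratt handling of zero differences); and
patient-level fold construction for cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricReport",
    "overlap_metrics",
    "hd95",
    "paired_wilcoxon",
    "classification_report",
    "make_patient_folds",
]

log = logging.getLogger(__name__)


@dataclass
class MetricReport:
    per_case: list = field(default_factory=list)      # dicts: case_id, dsc, iou, hd95
    aggregate: Dict[str, float] = field(default_factory=dict)
    classification: Dict[str, object] = field(default_factory=dict)


def overlap_metrics(prediction: np.ndarray, truth: np.ndarray):
    """Dice and Jaccard overlap; two empty masks score 1 by convention."""
    prediction = np.asarray(prediction).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if prediction.shape != truth.shape:
        raise ValueError("prediction and truth grids differ")
    inter = np.logical_and(prediction, truth).sum()
    p, t = prediction.sum(), truth.sum()
    if p == 0 and t == 0:
        log.info("overlap_metrics: both masks empty; dsc = iou = 1 by convention")
        return 1.0, 1.0
    dsc = 2.0 * inter / (p + t)
    iou = inter / (p + t - inter)
    return float(dsc), float(iou)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary voxel coordinates: foreground voxels with a background face-neighbour."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1),
                                    border_value=0)
    return np.argwhere(mask & ~eroded)


def hd95(prediction: np.ndarray, truth: np.ndarray,
         spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile of the symmetric surface-distance distribution (mm)."""
    prediction = np.asarray(prediction).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if not prediction.any() or not truth.any():
        raise ValueError("hd95 requires two non-empty masks (no sentinel is returned)")
    sp = np.asarray(spacing, dtype=np.float64)
    a = _surface_voxels(prediction) * sp
    b = _surface_voxels(truth) * sp
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def paired_wilcoxon(scores_a: Sequence[float], scores_b: Sequence[float]):
    """Two-sided paired Wilcoxon signed-rank test on patient-level scores.

    Exact distribution for n <= 25, normal approximation above; zero
    differences are handled with the Pratt policy.  All-zero differences
    return p = 1 with a warning.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must have equal length")
    if len(a) < 6:
        raise ValueError("need at least 6 pairs")
    d = a - b
    if np.all(d == 0):
        log.warning("paired_wilcoxon: all differences zero; p = 1")
        return 0.0, 1.0
    method = "exact" if len(a) <= 25 else "approx"
    try:
        res = stats.wilcoxon(a, b, zero_method="pratt", alternative="two-sided",
                             method=method)
    except ValueError:
        res = stats.wilcoxon(a, b, zero_method="pratt", alternative="two-sided",
                             method="approx")
    return float(res.statistic), float(res.pvalue)


def classification_report(predicted: Sequence[int], truth: Sequence[int],
                          scores: np.ndarray | None = None) -> Dict[str, object]:
    """Accuracy, macro REC/PRE/F1/FPR, confusion matrix, one-vs-rest AUC."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    classes = np.unique(np.concatenate([truth, predicted]))
    present = np.unique(truth)
    if len(present) < 2:
        raise ValueError("need at least two classes present in truth")
    cm = _sk_confusion(truth, predicted, labels=classes)
    acc = float((predicted == truth).mean())

    recs, pres, f1s, fprs = [], [], [], []
    for ci, c in enumerate(classes):
        if c not in present:
            log.info("classification_report: class %s absent from truth; skipped", c)
            continue
        tp = cm[ci, ci]
        fn = cm[ci].sum() - tp
        fp = cm[:, ci].sum() - tp
        tn = cm.sum() - tp - fn - fp
        rec = tp / (tp + fn) if tp + fn else 0.0
        pre = tp / (tp + fp) if tp + fp else 0.0
        recs.append(rec)
        pres.append(pre)
        f1s.append(2 * pre * rec / (pre + rec) if pre + rec else 0.0)
        fprs.append(fp / (fp + tn) if fp + tn else 0.0)

    out = {
        "acc": acc, "rec": float(np.mean(recs)), "pre": float(np.mean(pres)),
        "f1": float(np.mean(f1s)), "fpr": float(np.mean(fprs)),
        "confusion_matrix": cm, "classes": classes,
    }
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        if len(present) == 2:
            pos = present[-1]
            out["auc"] = float(roc_auc_score(truth == pos, scores[:, list(classes).index(pos)]))
        else:
            norm = scores / np.clip(scores.sum(axis=1, keepdims=True), 1e-12, None)
            out["auc"] = float(roc_auc_score(truth, norm, multi_class="ovr",
                                             labels=classes, average="macro"))
    return out


def make_patient_folds(patient_ids: Sequence[str], n_folds: int = 5,
                       seed: int = 0) -> Dict[str, int]:
    """Random non-overlapping patient-level folds with sizes differing by <= 1."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if n_folds > len(ids):
        raise ValueError("more folds than patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return {ids[int(p)]: int(i % n_folds) for i, p in enumerate(perm)}
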