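"""Superpixel partitioning and region-graph construction.

A volume is over-segmented into SLIC superpixels; the region graph
connects face-adjacent superpixels (6-connectivity) and augments them
with kNN long-range edges in appearance/encoder feature space, so that
spatially separated but semantically similar regions can exchange
affinity information.  Node features concatenate the mean encoder
feature, intensity statistics, the normalized centroid, and a summary
of the node's initial edge affinities.  Each edge carries an initial
affinity ``a_init`` (normalized cosine of the node feature vectors) and
a soft co-membership target ``w`` derived from the CAM overlap in soft
Dice form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.segmentation import slic
from sklearn.neighbors import NearestNeighbors

from .volume import CAMVolume, VolumeImage

__all__ = [
    "SuperpixelPartition",
    "RegionGraph",
    "compute_superpixels",
    "build_region_graph",
    "soft_target_affinity",
    "export_edges_tsv",
]

KIND_ADJACENCY = 0
KIND_KNN = 1


@dataclass
class SuperpixelPartition:
    labels: np.ndarray
    n_regions: int
    region_sizes: np.ndarray
    region_centroids: np.ndarray

    def __post_init__(self):
        if self.region_sizes.sum() != self.labels.size:
            raise ValueError("region sizes must sum to voxel count")
        if (self.region_sizes <= 0).any():
            raise ValueError("every region must be non-empty")


@dataclass
class RegionGraph:
    n_nodes: int
    edges: np.ndarray          # (E, 2), u < v
    edge_kind: np.ndarray      # (E,), KIND_ADJACENCY | KIND_KNN
    node_features: np.ndarray  # (N, F)
    edge_a_init: np.ndarray    # (E,) in [0, 1]
    edge_w: np.ndarray         # (E,) in [0, 1]
    edge_a_opt: Optional[np.ndarray] = field(default=None)

    def __post_init__(self):
        if len(self.edges) and (self.edges[:, 0] >= self.edges[:, 1]).any():
            raise ValueError("edges must be stored with u < v (no self-loops)")
        for name, arr in (("a_init", self.edge_a_init), ("w", self.edge_w)):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"edge {name} values must lie in [0, 1]")

    def neighbors_directed(self):
        """Directed edge arrays (src, dst) covering both orientations."""
        src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        return src, dst


def compute_superpixels(volume: VolumeImage, n_segments: int,
                        compactness: float = 0.1) -> SuperpixelPartition:
    """SLIC over-segmentation of a [0,1]-normalized volume."""
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    labels = slic(volume.data, n_segments=n_segments, compactness=compactness,
                  channel_axis=None, start_label=0, enforce_connectivity=True)
    # make ids contiguous from 0
    uniq, labels_flat = np.unique(labels, return_inverse=True)
    labels = labels_flat.reshape(volume.data.shape).astype(np.int32)
    n_regions = len(uniq)
    sizes = np.bincount(labels.ravel(), minlength=n_regions)
    idx = np.indices(labels.shape).reshape(3, -1)
    centroids = np.stack([
        np.bincount(labels.ravel(), weights=idx[a], minlength=n_regions) / sizes
        for a in range(3)
    ], axis=1)
    return SuperpixelPartition(labels, n_regions, sizes, centroids)


def _region_cam_probabilities(cam: CAMVolume, partition: SuperpixelPartition) -> np.ndarray:
    """Mean CAM class-probability vector per region, shape (N, C)."""
    flat = partition.labels.ravel()
    out = np.stack([
        np.bincount(flat, weights=cam.values[..., c].ravel(),
                    minlength=partition.n_regions) / partition.region_sizes
        for c in range(cam.n_classes)
    ], axis=1)
    return out


def _soft_dice(p1: np.ndarray, p2: np.ndarray, epsilon: float) -> np.ndarray:
    num = 2.0 * np.sum(p1 * p2, axis=-1)
    den = np.sum(np.abs(p1), axis=-1) + np.sum(np.abs(p2), axis=-1) + epsilon
    return num / den


def soft_target_affinity(cam: CAMVolume, partition: SuperpixelPartition,
                         edge, epsilon: float = 1e-6) -> float:
    """Soft co-membership target ``w = 2<p1,p2> / (|p1|_1 + |p2|_1 + eps)``.

    ``p_i`` is region i's mean CAM class-probability vector; symmetric in
    the two nodes and bounded in [0, 1).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    u, v = int(edge[0]), int(edge[1])
    for r in (u, v):
        if not (0 <= r < partition.n_regions):
            raise KeyError(f"region {r} absent from partition")
    probs = _region_cam_probabilities(cam, partition)
    return float(_soft_dice(probs[u], probs[v], epsilon))


def _adjacency_pairs(labels: np.ndarray) -> np.ndarray:
    pairs = []
    for axis in range(3):
        a = np.moveaxis(labels, axis, 0)
        lo, hi = a[:-1].ravel(), a[1:].ravel()
        m = lo != hi
        pairs.append(np.stack([np.minimum(lo[m], hi[m]), np.maximum(lo[m], hi[m])], axis=1))
    pairs = np.concatenate(pairs, axis=0)
    return np.unique(pairs, axis=0)


def _region_intensity_stats(volume: VolumeImage, partition: SuperpixelPartition) -> np.ndarray:
    """(mean, sd, p10, p90) of intensity per region."""
    flat_lab = partition.labels.ravel()
    flat_val = volume.data.ravel()
    order = np.argsort(flat_lab, kind="stable")
    bounds = np.cumsum(partition.region_sizes)[:-1]
    groups = np.split(flat_val[order], bounds)
    stats = np.empty((partition.n_regions, 4))
    for i, g in enumerate(groups):
        stats[i] = (g.mean(), g.std(), np.percentile(g, 10), np.percentile(g, 90))
    return stats


def _cosine_affinity(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Normalized cosine mapped to [0, 1] via (cos + 1) / 2."""
    n1 = np.linalg.norm(f1, axis=-1)
    n2 = np.linalg.norm(f2, axis=-1)
    denom = np.where(n1 * n2 > 0, n1 * n2, 1.0)
    cos = np.sum(f1 * f2, axis=-1) / denom
    return np.clip((cos + 1.0) / 2.0, 0.0, 1.0)


def build_region_graph(partition: SuperpixelPartition, volume: VolumeImage,
                       encoder_features: np.ndarray, cam: CAMVolume,
                       k: int = 10, epsilon: float = 1e-6) -> RegionGraph:
    """Assemble the region graph with adjacency + kNN edges.

    ``encoder_features`` is a per-voxel vector field of shape
    ``volume.shape + (F,)``.  kNN distances use the appearance/encoder
    sub-vector only (coordinates excluded), so long-range edges reflect
    appearance rather than position.
    """
    if partition.n_regions < 2:
        raise ValueError("degenerate single-region partition")
    if k >= partition.n_regions:
        raise ValueError("k must be < number of regions")
    encoder_features = np.asarray(encoder_features, dtype=np.float64)
    if encoder_features.shape[:3] != volume.data.shape:
        raise ValueError("encoder features must share the volume grid")

    n = partition.n_regions
    flat = partition.labels.ravel()
    f_dim = encoder_features.shape[-1]
    f_enc = np.stack([
        np.bincount(flat, weights=encoder_features[..., d].ravel(), minlength=n)
        / partition.region_sizes
        for d in range(f_dim)
    ], axis=1)
    f_app = _region_intensity_stats(volume, partition)
    f_coord = partition.region_centroids / np.asarray(volume.data.shape)
    base = np.concatenate([f_enc, f_app, f_coord], axis=1)

    adj = _adjacency_pairs(partition.labels)

    knn_space = np.concatenate([f_app, f_enc], axis=1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(knn_space)
    _, nbr = nn.kneighbors(knn_space)
    knn_pairs = []
    for i in range(n):
        for j in nbr[i, 1:]:
            knn_pairs.append((min(i, j), max(i, j)))
    knn_pairs = np.unique(np.array(knn_pairs, dtype=np.int64), axis=0)

    adj_set = {tuple(p) for p in adj}
    knn_only = np.array([p for p in knn_pairs if tuple(p) not in adj_set],
                        dtype=np.int64).reshape(-1, 2)
    edges = np.concatenate([adj, knn_only], axis=0)
    kind = np.concatenate([
        np.full(len(adj), KIND_ADJACENCY, dtype=np.int8),
        np.full(len(knn_only), KIND_KNN, dtype=np.int8),
    ])

    a_init = _cosine_affinity(base[edges[:, 0]], base[edges[:, 1]])
    probs = _region_cam_probabilities(cam, partition)
    w = _soft_dice(probs[edges[:, 0]], probs[edges[:, 1]], epsilon)

    a_summary = np.zeros(n)
    deg = np.zeros(n)
    np.add.at(a_summary, edges[:, 0], a_init)
    np.add.at(a_summary, edges[:, 1], a_init)
    np.add.at(deg, edges[:, 0], 1)
    np.add.at(deg, edges[:, 1], 1)
    a_summary = a_summary / np.maximum(deg, 1)

    node_features = np.concatenate([base, a_summary[:, None]], axis=1)
    return RegionGraph(n, edges, kind, node_features, a_init, np.clip(w, 0, 1))


def export_edges_tsv(graph: RegionGraph, path) -> None:
    import pandas as pd

    kind_names = np.where(graph.edge_kind == KIND_ADJACENCY, "adjacency", "knn")
    df = pd.DataFrame({
        "node_u": graph.edges[:, 0], "node_v": graph.edges[:, 1],
        "kind": kind_names, "a_init": graph.edge_a_init, "w": graph.edge_w,
        "a_opt": graph.edge_a_opt if graph.edge_a_opt is not None
                 else np.full(len(graph.edges), np.nan),
    })
    df.to_csv(path, sep="\t", index=False)
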