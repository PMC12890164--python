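"""Random-walk refinement of CAMs.

Affinities are sharpened with an element-wise power ``eta`` and
row-normalized into a stochastic transition matrix; one application of
the matrix diffuses activation from high-confidence voxels (or regions)
to semantically affine neighbours.  The voxel-level walk runs inside
overlapping 3D blocks whose outputs are merged with a distance-weighted
taper, keeping memory bounded while matching a global walk wherever
affinities are block-local.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import sparse

from .graph import RegionGraph, SuperpixelPartition
from .pseudolabel import SparseAffinity, _overlap_slices
from .volume import CAMVolume

__all__ = [
    "PropagationConfig",
    "TransitionMatrix",
    "RegionTiling",
    "transition_matrix",
    "propagate",
    "make_tiling",
    "merge_blocks",
    "refine_cam",
    "affinity_block_matrix",
    "affinity_dense_matrix",
    "region_affinity_matrix",
]


@dataclass
class PropagationConfig:
    eta: float = 4.0
    block_size: tuple = (32, 32, 32)
    overlap_fraction: float = 0.5
    use_region_graph: bool = True
    n_iterations: int = 1


@dataclass
class TransitionMatrix:
    values: object            # dense ndarray or scipy.sparse matrix
    eta: float

    def __post_init__(self):
        rows = np.asarray(self.values.sum(axis=1)).ravel()
        if np.abs(rows - 1.0).max() > 1e-6:
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class RegionTiling:
    blocks: List[tuple]       # per block: 3-tuple of (start, stop)
    centers: np.ndarray       # (R, 3) block centers in voxel coordinates
    grid_shape: tuple
    overlap_fraction: float

    def __post_init__(self):
        covered = np.zeros(self.grid_shape, dtype=bool)
        for blk in self.blocks:
            covered[tuple(slice(a, b) for a, b in blk)] = True
        if not covered.all():
            raise ValueError("tiling does not cover the grid")

    @property
    def R(self) -> int:
        return len(self.blocks)


def transition_matrix(W, eta: float = 1.0) -> TransitionMatrix:
    """Row-normalized ``T = D^-1 W^eta`` (element-wise power)."""
    if eta <= 0:
        raise ValueError("eta must be > 0")
    if sparse.issparse(W):
        We = W.copy().tocsr()
        if (We.data < 0).any():
            raise ValueError("affinities must be non-negative")
        We.data = We.data**eta
        rows = np.asarray(We.sum(axis=1)).ravel()
        zero = np.where(rows <= 0)[0]
        if len(zero):
            raise ValueError(f"zero row(s) after exponentiation: {zero[:5]}")
        D_inv = sparse.diags(1.0 / rows)
        return TransitionMatrix(D_inv @ We, eta)
    W = np.asarray(W, dtype=np.float64)
    if (W < 0).any():
        raise ValueError("affinities must be non-negative")
    We = W**eta
    rows = We.sum(axis=1)
    zero = np.where(rows <= 0)[0]
    if len(zero):
        raise ValueError(f"zero row(s) after exponentiation: {zero[:5]}")
    return TransitionMatrix(We / rows[:, None], eta)


def propagate(T: TransitionMatrix, M: np.ndarray) -> np.ndarray:
    """Diffuse a vectorized activation block: ``M_aff = T . vec(M)``."""
    M = np.asarray(M, dtype=np.float64)
    if M.shape[0] != T.n:
        raise ValueError(f"activation length {M.shape[0]} != matrix size {T.n}")
    return T.values @ M


def make_tiling(grid_shape: Sequence[int], block_size: Sequence[int],
                overlap_fraction: float = 0.5) -> RegionTiling:
    """Regular overlapping tiling; the last block snaps to the boundary."""
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    grid_shape = tuple(int(g) for g in grid_shape)
    block_size = tuple(int(b) for b in block_size)
    if any(b > g for b, g in zip(block_size, grid_shape)):
        raise ValueError("block_size exceeds grid shape")
    axis_starts = []
    for g, b in zip(grid_shape, block_size):
        stride = max(1, int(round(b * (1 - overlap_fraction))))
        starts = list(range(0, g - b + 1, stride))
        if starts[-1] != g - b:
            starts.append(g - b)
        axis_starts.append(starts)
    blocks, centers = [], []
    for s0 in axis_starts[0]:
        for s1 in axis_starts[1]:
            for s2 in axis_starts[2]:
                blk = ((s0, s0 + block_size[0]), (s1, s1 + block_size[1]),
                       (s2, s2 + block_size[2]))
                blocks.append(blk)
                centers.append([(a + b - 1) / 2.0 for a, b in blk])
    return RegionTiling(blocks, np.asarray(centers), grid_shape, overlap_fraction)


def merge_blocks(block_outputs: List[np.ndarray], tiling: RegionTiling) -> np.ndarray:
    """Distance-weighted merge of overlapping block outputs.

    Block weight tapers linearly from 1 at the block center to 0.5 at
    the corner (``w = 1 - ||v - c|| / diag``), so every covered voxel
    keeps positive weight; weights are renormalized per voxel.
    """
    if len(block_outputs) != tiling.R:
        raise ValueError("one output required per block")
    chan = block_outputs[0].shape[3:] if block_outputs[0].ndim == 4 else ()
    acc = np.zeros(tiling.grid_shape + chan)
    wsum = np.zeros(tiling.grid_shape)
    for blk, center, out in zip(tiling.blocks, tiling.centers, block_outputs):
        sl = tuple(slice(a, b) for a, b in blk)
        shape = tuple(b - a for a, b in blk)
        diag = float(np.linalg.norm(shape))
        coords = np.indices(shape).reshape(3, -1).T + np.array([a for a, _ in blk])
        d = np.linalg.norm(coords - center, axis=1).reshape(shape)
        w = 1.0 - d / diag
        acc[sl] += out * (w[..., None] if chan else w)
        wsum[sl] += w
    if (wsum <= 0).any():
        raise ValueError("voxel with zero total merge weight")
    return acc / (wsum[..., None] if chan else wsum)


def affinity_block_matrix(affinity: SparseAffinity, block: tuple) -> sparse.csr_matrix:
    """Sparse symmetric affinity over a block's voxels (diagonal = 1)."""
    shape = tuple(b - a for a, b in block)
    origin = np.array([a for a, _ in block])
    nb = int(np.prod(shape))
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    rows, cols, vals = [np.arange(nb)], [np.arange(nb)], [np.ones(nb)]
    for off, arr in affinity.entries.items():
        src_local, dst_local = _overlap_slices(shape, off)
        # local source coordinates where v and v+off are both inside the block
        loc = np.indices(tuple(s.stop - s.start for s in src_local)).reshape(3, -1).T
        loc = loc + np.array([s.start for s in src_local])
        if len(loc) == 0:
            continue
        glob = loc + origin
        v = arr[tuple(glob.T)]
        src_idx = loc @ strides
        dst_idx = (loc + np.array(off)) @ strides
        rows.extend([src_idx, dst_idx])
        cols.extend([dst_idx, src_idx])
        vals.extend([v, v])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(nb, nb))


def affinity_dense_matrix(affinity: SparseAffinity) -> np.ndarray:
    """Dense (n_vox x n_vox) affinity matrix over the full grid."""
    full_block = tuple((0, s) for s in affinity.grid_shape)
    return affinity_block_matrix(affinity, full_block).toarray()


def region_affinity_matrix(graph: RegionGraph) -> np.ndarray:
    """Symmetric region-level affinity from trained edge posteriors."""
    if graph.edge_a_opt is None:
        raise ValueError("graph edge posteriors not trained")
    A = np.eye(graph.n_nodes)
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    A[u, v] = graph.edge_a_opt
    A[v, u] = graph.edge_a_opt
    return A


def refine_cam(cam: CAMVolume, affinity: SparseAffinity,
               config: PropagationConfig = PropagationConfig(),
               region_graph: Optional[RegionGraph] = None,
               partition: Optional[SuperpixelPartition] = None) -> CAMVolume:
    """Two-stage random-walk refinement.

    Stage A (optional): diffuse region-mean activations over the region
    graph using a transition matrix built from the trained edge
    posteriors, then broadcast back to voxels.  Stage B: region-wise
    voxel propagation — tile the grid, run one (or ``n_iterations``)
    transition steps per block on the windowed affinity, and merge with
    distance weights.
    """
    if affinity.grid_shape != cam.grid_shape:
        raise ValueError("affinity and CAM grids differ")
    values = cam.values.copy()

    if config.use_region_graph and region_graph is not None and partition is not None:
        A = region_affinity_matrix(region_graph)
        T = transition_matrix(A, config.eta)
        flat = partition.labels.ravel()
        probs = np.stack([
            np.bincount(flat, weights=values[..., c].ravel(),
                        minlength=partition.n_regions) / partition.region_sizes
            for c in range(cam.n_classes)
        ], axis=1)
        for _ in range(max(1, config.n_iterations)):
            probs = propagate(T, probs)
        values = probs[partition.labels]

    tiling = make_tiling(cam.grid_shape, config.block_size, config.overlap_fraction)
    outputs = []
    for blk in tiling.blocks:
        sl = tuple(slice(a, b) for a, b in blk)
        W = affinity_block_matrix(affinity, blk)
        T = transition_matrix(W, config.eta)
        m = values[sl].reshape(-1, cam.n_classes)
        for _ in range(max(1, config.n_iterations)):
            m = propagate(T, m)
        shape = tuple(b - a for a, b in blk)
        outputs.append(m.reshape(shape + (cam.n_classes,)))
    merged = merge_blocks(outputs, tiling)
    if merged.min() < -1e-6 or merged.max() > 1 + 1e-6:
        raise ValueError("propagated values escaped [0, 1]; transition not stochastic")
    return CAMVolume(np.clip(merged, 0.0, 1.0), class_names=list(cam.class_names),
                     spacing=cam.spacing)
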