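"""Random-walk propagation: stochasticity, tiling, merging, oracle equivalence."""

import numpy as np
import pytest

from cavseg.propagation import (PropagationConfig, affinity_block_matrix,
                                affinity_dense_matrix, make_tiling, merge_blocks,
                                propagate, refine_cam, transition_matrix)
from cavseg.pseudolabel import SparseAffinity, voxel_affinity
from cavseg.volume import CAMVolume


class TestTransitionMatrix:
    def test_uniform_affinity_gives_uniform_rows(self):
        T = transition_matrix(np.ones((2, 2)), eta=1.0)
        np.testing.assert_allclose(T.values, 0.5)

    def test_eta_two_sharpens(self):
        T = transition_matrix(np.array([[2.0, 1.0], [1.0, 2.0]]), eta=2.0)
        np.testing.assert_allclose(T.values, [[0.8, 0.2], [0.2, 0.8]])

    @pytest.mark.parametrize("eta", [0.5, 1.0, 2.0, 4.0])
    def test_rows_sum_to_one_for_all_eta(self, eta):
        rng = np.random.default_rng(0)
        W = rng.random((10, 10)) + 0.01
        T = transition_matrix(W, eta)
        np.testing.assert_allclose(T.values.sum(axis=1), 1.0, atol=1e-9)

    def test_eta_sharpening_lowers_row_entropy(self):
        rng = np.random.default_rng(1)
        W = rng.random((8, 8)) + 0.1
        entropies = []
        for eta in (0.5, 1.0, 2.0, 4.0):
            T = transition_matrix(W, eta).values
            entropies.append(-np.sum(T * np.log(T + 1e-300), axis=1).mean())
        assert all(a >= b - 1e-12 for a, b in zip(entropies, entropies[1:]))

    def test_zero_row_named_in_error(self):
        W = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="zero row"):
            transition_matrix(W, 1.0)

    def test_negative_affinity_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(np.array([[1.0, -0.1], [0.1, 1.0]]), 1.0)


class TestPropagate:
    def test_identity_transition_preserves_input(self):
        T = transition_matrix(np.eye(5), 1.0)
        M = np.random.default_rng(2).random((5, 2))
        np.testing.assert_array_equal(propagate(T, M), M)

    def test_uniform_transition_averages(self):
        T = transition_matrix(np.ones((4, 4)), 1.0)
        M = np.arange(8, dtype=float).reshape(4, 2)
        np.testing.assert_allclose(propagate(T, M), np.tile(M.mean(axis=0), (4, 1)))

    def test_matches_dense_matrix_vector_product(self):
        rng = np.random.default_rng(3)
        W = rng.random((12, 12)) + 0.01
        T = transition_matrix(W, 2.0)
        M = rng.random((12, 3))
        np.testing.assert_allclose(propagate(T, M), T.values @ M, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        T = transition_matrix(np.ones((3, 3)), 1.0)
        with pytest.raises(ValueError):
            propagate(T, np.zeros((4, 1)))


class TestTiling:
    def test_single_block_when_block_fills_grid(self):
        t = make_tiling((8, 8, 8), (8, 8, 8), 0.5)
        assert t.R == 1

    def test_half_overlap_stride_arithmetic(self):
        t = make_tiling((16, 16, 16), (8, 8, 8), 0.5)
        starts = sorted({b[0][0] for b in t.blocks})
        assert starts == [0, 4, 8]
        assert t.R == 27

    @pytest.mark.parametrize("shape,block", [((13, 9, 17), (5, 4, 6)),
                                             ((20, 20, 20), (7, 7, 7))])
    def test_every_voxel_covered(self, shape, block):
        t = make_tiling(shape, block, 0.3)
        covered = np.zeros(shape, dtype=int)
        for blk in t.blocks:
            covered[tuple(slice(a, b) for a, b in blk)] += 1
        assert covered.min() >= 1

    def test_full_overlap_rejected(self):
        with pytest.raises(ValueError):
            make_tiling((8, 8, 8), (4, 4, 4), 1.0)

    def test_oversized_block_rejected(self):
        with pytest.raises(ValueError):
            make_tiling((8, 8, 8), (9, 8, 8), 0.5)


class TestMergeBlocks:
    def test_identical_outputs_merge_to_themselves(self):
        t = make_tiling((8, 8, 8), (6, 6, 6), 0.5)
        const = np.full((6, 6, 6), 0.7)
        merged = merge_blocks([const.copy() for _ in range(t.R)], t)
        np.testing.assert_allclose(merged, 0.7, atol=1e-12)

    def test_singleton_coverage_returns_block_value(self):
        t = make_tiling((6, 6, 6), (6, 6, 6), 0.5)
        out = np.random.default_rng(4).random((6, 6, 6))
        np.testing.assert_allclose(merge_blocks([out], t), out)

    def test_two_block_merge_weighted_toward_nearer_center(self):
        t = make_tiling((12, 8, 8), (8, 8, 8), 0.5)
        assert t.R == 2
        vals = [np.zeros((8, 8, 8)), np.ones((8, 8, 8))]
        merged = merge_blocks(vals, t)
        overlap = merged[4:8, 4, 4]
        assert np.all((overlap > 0) & (overlap < 1))
        # voxel nearer the first block's center leans toward its value 0
        assert merged[4, 4, 4] < merged[7, 4, 4]


def _identity_affinity(shape, window=(3, 3, 3)):
    from cavseg.pseudolabel import _positive_offsets

    half = tuple(w // 2 for w in window)
    entries = {off: np.zeros(shape) for off in _positive_offsets(half)}
    return SparseAffinity(shape, window, entries)


class TestRefineCam:
    def test_identity_affinity_preserves_cam(self, random_cam):
        aff = _identity_affinity(random_cam.grid_shape)
        out = refine_cam(random_cam, aff,
                         PropagationConfig(block_size=(12, 12, 12),
                                           use_region_graph=False))
        np.testing.assert_allclose(out.values, random_cam.values, atol=1e-12)

    def test_single_tile_equals_global_dense_walk(self):
        rng = np.random.default_rng(5)
        shape = (16, 16, 16)
        cam = CAMVolume(rng.random(shape + (2,)))
        aff = voxel_affinity(rng.normal(size=shape + (4,)), (5, 5, 5))
        out = refine_cam(cam, aff, PropagationConfig(
            eta=1.0, block_size=shape, use_region_graph=False))
        W = affinity_dense_matrix(aff)
        T = W**1.0
        T = T / T.sum(axis=1, keepdims=True)
        expect = (T @ cam.values.reshape(-1, 2)).reshape(shape + (2,))
        np.testing.assert_allclose(out.values, expect, atol=1e-9)

    def test_blockwise_equals_global_on_block_diagonal_affinity(self):
        """Affinities restricted inside non-overlapping blocks: region-wise
        propagation must equal the global walk exactly."""
        rng = np.random.default_rng(6)
        shape = (8, 8, 8)
        cam_vals = rng.random(shape + (1,))
        aff = voxel_affinity(rng.normal(size=shape + (3,)), (3, 3, 3))
        # zero out every pair crossing the block boundary at index 4 (axis 0)
        from cavseg.pseudolabel import _overlap_slices
        for off, arr in aff.entries.items():
            src, _ = _overlap_slices(shape, off)
            idx = np.indices(shape)[0]
            crosses = (idx < 4) & (idx + off[0] >= 4) | (idx >= 4) & (idx + off[0] < 4)
            arr[crosses] = 0.0
        cam = CAMVolume(cam_vals)
        out_block = refine_cam(cam, aff, PropagationConfig(
            eta=1.0, block_size=(4, 8, 8), overlap_fraction=0.0,
            use_region_graph=False))
        W = affinity_dense_matrix(aff)
        T = W / W.sum(axis=1, keepdims=True)
        expect = (T @ cam_vals.reshape(-1, 1)).reshape(shape + (1,))
        np.testing.assert_allclose(out_block.values, expect, atol=1e-12)

    def test_max_principle_per_class(self, random_cam):
        rng = np.random.default_rng(7)
        aff = voxel_affinity(rng.normal(size=random_cam.grid_shape + (3,)), (3, 3, 3))
        out = refine_cam(random_cam, aff, PropagationConfig(
            block_size=(12, 12, 12), use_region_graph=False))
        for c in range(random_cam.n_classes):
            assert out.values[..., c].max() <= random_cam.values[..., c].max() + 1e-9
            assert out.values[..., c].min() >= random_cam.values[..., c].min() - 1e-9

    def test_refinement_recovers_undersegmented_cavity(self, small_phantom,
                                                       undersegmented_cam):
        from cavseg.evaluation import overlap_metrics
        from cavseg.pseudolabel import dual_threshold

        vol, mask, _ = small_phantom
        feats = np.stack([mask.astype(float), 0.1 * vol.data], axis=-1)
        aff = voxel_affinity(feats, (5, 5, 5))
        refined = refine_cam(undersegmented_cam, aff, PropagationConfig(
            block_size=(16, 16, 16), use_region_graph=False))
        d_raw = overlap_metrics(dual_threshold(undersegmented_cam).values > 0,
                                mask > 0)[0]
        d_ref = overlap_metrics(dual_threshold(refined).values > 0, mask > 0)[0]
        assert d_ref > d_raw

    def test_region_graph_stage_runs_and_stays_stochastic(self, small_phantom):
        from cavseg.affinity import GANetConfig, train_ganet
        from cavseg.graph import build_region_graph, compute_superpixels
        from cavseg.phantom import CamCorruption, corrupt_cam

        vol, mask, _ = small_phantom
        cam = corrupt_cam(mask, CamCorruption(0.8, 1.0, 0.02, seed=1), 2)
        part = compute_superpixels(vol, 40)
        feats = np.stack([vol.data], axis=-1)
        graph = build_region_graph(part, vol, feats, cam, k=4)
        train_ganet(graph, GANetConfig(n_layers=2, feature_dim=8, steps=20, seed=0))
        aff = _identity_affinity(vol.data.shape)
        out = refine_cam(cam, aff, PropagationConfig(
            block_size=(16, 16, 16), use_region_graph=True),
            region_graph=graph, partition=part)
        assert out.values.min() >= 0 and out.values.max() <= 1


def test_block_matrix_matches_dense_restriction():
    rng = np.random.default_rng(8)
    aff = voxel_affinity(rng.normal(size=(6, 6, 6, 2)), (3, 3, 3))
    dense = affinity_dense_matrix(aff)
    block = ((2, 6), (0, 4), (1, 5))
    sub = affinity_block_matrix(aff, block).toarray()
    # brute-force restriction of the dense matrix to the block's voxels
    idx = [i * 36 + j * 6 + k for i in range(2, 6) for j in range(0, 4)
           for k in range(1, 5)]
    np.testing.assert_allclose(sub, dense[np.ix_(idx, idx)], atol=1e-12)
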