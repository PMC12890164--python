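"""Pseudo-label generation: classifier loss, dual threshold, voxel affinity."""

import numpy as np
import pytest

from cavseg.phantom import PhantomConfig, generate_phantom
from cavseg.pseudolabel import (IGNORE, CamClassifier, ClassifierConfig,
                                PseudoLabel, affinity_to_logit, cam_from_features,
                                classification_loss, derive_affinity_targets,
                                dual_threshold, focal_affinity_loss,
                                train_classifier_and_cam, voxel_affinity)
from cavseg.volume import CAMVolume


class TestClassificationLoss:
    def test_smoothed_target_value(self):
        # epsilon=0.15, K=5: true-class target 0.85 + 0.03 = 0.88
        eps, K = 0.15, 5
        t = (1 - eps) + eps / K
        assert t == pytest.approx(0.88)

    def test_perfect_onehot_without_smoothing_is_zero(self):
        p = np.array([[1 - 1e-9, 1e-9, 1e-9]])
        loss = classification_loss(p, [0], epsilon=0.0)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_matches_scalar_arithmetic(self):
        p = np.array([[0.7, 0.2]])
        eps, K = 0.15, 2
        t = np.array([(1 - eps) + eps / K, eps / K])
        hand = -(t[0] * np.log(0.7) + (1 - t[0]) * np.log(0.3)
                 + t[1] * np.log(0.2) + (1 - t[1]) * np.log(0.8))
        assert classification_loss(p, [0], eps) == pytest.approx(hand, rel=1e-12)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(np.array([[0.5, 0.5]]), [0], epsilon=1.0)


class TestCam:
    def test_cam_equals_weighted_feature_sum(self):
        feats = np.zeros((2, 2, 2, 2))
        feats[..., 0] = 1.0
        feats[..., 1] = 2.0
        weights = np.array([[0.5, -1.0], [0.25, 0.5]])  # (C_feat, K)
        raw = cam_from_features(feats, weights)
        np.testing.assert_allclose(raw[..., 0], 1 * 0.5 + 2 * 0.25)
        np.testing.assert_allclose(raw[..., 1], 1 * -1.0 + 2 * 0.5)

    def test_normalized_cam_spans_unit_interval(self, small_phantom):
        vol, _, _ = small_phantom
        model = CamClassifier(ClassifierConfig(n_classes=3, seed=0))
        cam = model.cam(vol)
        for c in range(cam.n_classes):
            chan = cam.values[..., c]
            if chan.max() > chan.min():
                assert chan.min() == pytest.approx(0.0, abs=1e-12)
                assert chan.max() == pytest.approx(1.0, abs=1e-12)

    def test_training_loss_decreases(self):
        rng = np.random.default_rng(0)
        vols, labels = [], []
        for i in range(20):
            cfg = PhantomConfig(shape=(32, 32, 32), n_cavities=int(rng.integers(0, 3)),
                                cavity_radius_range=(4, 6), seed=100 + i)
            v, _, c = generate_phantom(cfg)
            vols.append(v)
            labels.append(c)
        _, _, hist = train_classifier_and_cam(
            vols, labels, ClassifierConfig(steps=200, seed=0))
        losses = [h["loss_cls"] for h in hist]
        assert np.mean(losses[-20:]) <= 0.5 * losses[0]

    def test_single_class_manifest_rejected(self, small_phantom):
        vol, _, _ = small_phantom
        with pytest.raises(ValueError):
            train_classifier_and_cam([vol, vol], [2, 2], ClassifierConfig(steps=1))


class TestDualThreshold:
    def test_rule_on_representative_activations(self):
        cam = np.zeros((1, 1, 3, 2))
        cam[..., 1] = [0.50, 0.20, 0.40]
        out = dual_threshold(CAMVolume(cam), 0.32, 0.46)
        assert list(out.values[0, 0]) == [1, 0, IGNORE]

    def test_partition_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        cam = CAMVolume(rng.random((16, 16, 16, 3)))
        out = dual_threshold(cam, 0.32, 0.46)
        for idx in np.ndindex(4, 4, 4):  # spot-check a sub-grid voxel by voxel
            fg = cam.values[idx][1:]
            if fg.max() >= 0.46:
                assert out.values[idx] == fg.argmax() + 1
            elif fg.max() <= 0.32:
                assert out.values[idx] == 0
            else:
                assert out.values[idx] == IGNORE

    def test_statuses_exhaustive_on_random_cams(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            cam = CAMVolume(rng.random((6, 6, 6, 2)))
            out = dual_threshold(cam)
            fg, bg, ign = out.status_counts()
            assert fg + bg + ign == out.values.size

    def test_inverted_thresholds_rejected(self, random_cam):
        with pytest.raises(ValueError):
            dual_threshold(random_cam, 0.5, 0.3)


class TestVoxelAffinity:
    def test_identical_orthogonal_antiparallel(self):
        f = np.zeros((3, 1, 1, 2))
        f[0, 0, 0] = [1, 0]
        f[1, 0, 0] = [0, 1]
        f[2, 0, 0] = [-1, 0]
        aff = voxel_affinity(f, (5, 1, 1))
        assert aff.get((0, 0, 0), (1, 0, 0)) == pytest.approx(0.5)   # orthogonal
        assert aff.get((1, 0, 0), (2, 0, 0)) == pytest.approx(0.5)
        assert aff.get((0, 0, 0), (2, 0, 0)) == pytest.approx(0.0)   # antiparallel
        assert aff.get((1, 0, 0), (1, 0, 0)) == 1.0                  # self

    def test_symmetry_and_unit_diagonal_on_random_fields(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=(6, 6, 6, 4))
        aff = voxel_affinity(f, (3, 3, 3))
        for u, v in [((0, 0, 0), (1, 1, 1)), ((2, 3, 1), (3, 2, 2)),
                     ((5, 5, 5), (4, 4, 4))]:
            assert aff.get(u, v) == pytest.approx(aff.get(v, u), abs=1e-12)
        assert aff.get((2, 2, 2), (2, 2, 2)) == 1.0

    def test_zero_norm_vectors_get_uninformative_half(self):
        f = np.zeros((3, 1, 1, 2))
        f[0, 0, 0] = [1, 0]
        aff = voxel_affinity(f, (3, 1, 1))
        assert aff.get((0, 0, 0), (1, 0, 0)) == pytest.approx(0.5)


class TestAffinityTargets:
    def test_half_half_cube_matches_exhaustive_enumeration(self):
        lab = np.zeros((6, 6, 6), dtype=np.int16)
        lab[3:] = 1
        pseudo = PseudoLabel(lab)
        window = (3, 3, 3)
        tgt = derive_affinity_targets(pseudo, window)

        n_pos = n_neg = 0
        offs = [(di, dj, dk) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                for dk in (-1, 0, 1) if (di, dj, dk) > (0, 0, 0)]
        for i, j, k in np.ndindex(6, 6, 6):
            for di, dj, dk in offs:
                u, v, w = i + di, j + dj, k + dk
                if 0 <= u < 6 and 0 <= v < 6 and 0 <= w < 6:
                    if lab[i, j, k] == lab[u, v, w]:
                        n_pos += 1
                    else:
                        n_neg += 1
        assert (tgt.n_positive, tgt.n_negative) == (n_pos, n_neg)

    def test_all_background_has_no_negatives(self):
        pseudo = PseudoLabel(np.zeros((4, 4, 4), dtype=np.int16))
        tgt = derive_affinity_targets(pseudo, (3, 3, 3))
        assert tgt.n_negative == 0 and tgt.n_positive > 0

    def test_all_ignore_rejected(self):
        pseudo = PseudoLabel(np.full((4, 4, 4), IGNORE, dtype=np.int16))
        with pytest.raises(ValueError):
            derive_affinity_targets(pseudo, (3, 3, 3))


class TestFocalAffinityLoss:
    def _logit_container(self, value, shape=(4, 4, 4), window=(3, 3, 3)):
        from cavseg.pseudolabel import SparseAffinity, _positive_offsets

        half = tuple(w // 2 for w in window)
        entries = {off: np.full(shape, float(value))
                   for off in _positive_offsets(half)}
        return SparseAffinity(shape, window, entries, is_logit=True)

    def test_zero_logits_give_two_ln_two(self):
        lab = np.zeros((4, 4, 4), dtype=np.int16)
        lab[2:] = 1
        tgt = derive_affinity_targets(PseudoLabel(lab), (3, 3, 3))
        loss = focal_affinity_loss(self._logit_container(0.0), tgt)
        assert loss == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_saturated_logits_give_near_zero(self):
        lab = np.zeros((4, 4, 4), dtype=np.int16)
        lab[2:] = 1
        tgt = derive_affinity_targets(PseudoLabel(lab), (3, 3, 3))
        from cavseg.pseudolabel import SparseAffinity

        entries = {}
        for off, pm in tgt.positive_masks.items():
            e = np.where(pm, 20.0, -20.0)
            entries[off] = e
        aff = SparseAffinity((4, 4, 4), (3, 3, 3), entries, is_logit=True)
        assert focal_affinity_loss(aff, tgt) == pytest.approx(0.0, abs=1e-6)

    def test_gradient_sign_by_finite_difference(self):
        lab = np.zeros((4, 4, 4), dtype=np.int16)
        lab[2:] = 1
        tgt = derive_affinity_targets(PseudoLabel(lab), (3, 3, 3))
        base = self._logit_container(0.3)
        l0 = focal_affinity_loss(base, tgt)
        # raise one positive-pair logit -> loss must drop
        off = next(o for o, m in tgt.positive_masks.items() if m.any())
        idx = tuple(np.argwhere(tgt.positive_masks[off])[0])
        base.entries[off][idx] += 1e-4
        assert focal_affinity_loss(base, tgt) < l0
        base.entries[off][idx] -= 1e-4
        # raise one negative-pair logit -> loss must grow
        off_n = next(o for o, m in tgt.negative_masks.items() if m.any())
        idx_n = tuple(np.argwhere(tgt.negative_masks[off_n])[0])
        base.entries[off_n][idx_n] += 1e-4
        assert focal_affinity_loss(base, tgt) > l0

    def test_affinity_logit_roundtrip(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=(4, 4, 4, 3))
        aff = voxel_affinity(f, (3, 3, 3))
        logit = affinity_to_logit(aff)
        assert logit.is_logit
        # sigmoid(logit) recovers the (clamped) affinity
        off = next(iter(aff.entries))
        back = 1 / (1 + np.exp(-logit.entries[off]))
        np.testing.assert_allclose(back[:3, :3, :3], np.clip(aff.entries[off], 1e-4, 1 - 1e-4)[:3, :3, :3], atol=1e-9)

    def test_requires_logit_container(self):
        rng = np.random.default_rng(5)
        aff = voxel_affinity(rng.normal(size=(4, 4, 4, 2)), (3, 3, 3))
        lab = np.zeros((4, 4, 4), dtype=np.int16)
        tgt = derive_affinity_targets(PseudoLabel(lab), (3, 3, 3))
        with pytest.raises(ValueError):
            focal_affinity_loss(aff, tgt)
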