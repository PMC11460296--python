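"""Fold construction, augmentation, fusion, voting, and member training."""

import numpy as np
import pytest

from pzseg.ensemble import (EnsembleSegmenter, fuse_pair, majority_vote,
                            make_folds, train_member)
from pzseg.metrics import dice_score
from pzseg.network import HyperparamVector
from pzseg.training import TrainSchedule, augment_batch
from pzseg.preprocess import PreprocessConfig, VolumePreprocessor


class TestMakeFolds:
    def test_150_cases_five_folds_thirty_validation_each(self):
        split = make_folds(list(range(150)), k=5, seed=0)
        for train, valid in split.folds:
            assert len(valid) == 30 and len(train) == 120
            assert not set(train) & set(valid)

    def test_validation_sets_disjoint_and_cover_cohort(self):
        ids = [f"case{i}" for i in range(23)]
        split = make_folds(ids, k=5, seed=3)
        valid_union = [v for _, vs in split.folds for v in vs]
        assert len(valid_union) == len(set(valid_union)) == 23
        sizes = [len(vs) for _, vs in split.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_same_split(self):
        a = make_folds(list(range(40)), k=5, seed=9)
        b = make_folds(list(range(40)), k=5, seed=9)
        assert a.folds == b.folds

    def test_k_larger_than_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_folds([1, 2, 3], k=5)

    def test_random_mode_gives_20_percent_validation(self):
        split = make_folds(list(range(50)), k=5, seed=0, mode="random")
        for train, valid in split.folds:
            assert len(valid) == 10 and len(train) == 40


class TestAugmentBatch:
    def _data(self, rng, n=3):
        imgs = rng.random((n, 16, 16))
        gl = (rng.random((n, 16, 16)) > 0.6).astype(np.uint8)
        pz = (rng.random((n, 16, 16)) > 0.8).astype(np.uint8)
        return imgs, gl, pz

    def test_zero_magnitudes_identity(self, rng):
        imgs, gl, pz = self._data(rng)
        hp = HyperparamVector(aug_rotation_deg=0, aug_width_shift=0,
                              aug_height_shift=0, aug_zoom=0, aug_hflip=False)
        ai, ag, ap = augment_batch(imgs, gl, pz, hp, rng)
        np.testing.assert_array_equal(ai, imgs)
        np.testing.assert_array_equal(ag, gl)

    def test_flip_is_involution(self, rng):
        imgs, gl, pz = self._data(rng)
        hp = HyperparamVector(aug_rotation_deg=0, aug_width_shift=0,
                              aug_height_shift=0, aug_zoom=0, aug_hflip=True)
        # force the flip branch by drawing until a flip occurs, then reflip
        ai, ag, _ = augment_batch(imgs, gl, pz, hp, np.random.default_rng(1))
        flipped = ai[:, :, ::-1]
        for i in range(imgs.shape[0]):
            same = np.array_equal(ai[i], imgs[i])
            unflipped = np.array_equal(flipped[i], imgs[i])
            assert same or unflipped  # flip twice = identity

    def test_small_rotation_moves_masks_but_not_far(self):
        rng = np.random.default_rng(0)
        gl = np.zeros((1, 32, 32), np.uint8)
        gl[0, 4:14, 6:20] = 1  # off-centre asymmetric blob
        imgs = gl.astype(float)
        hp = HyperparamVector(aug_rotation_deg=10, aug_width_shift=0,
                              aug_height_shift=0, aug_zoom=0, aug_hflip=False)
        _, ag, _ = augment_batch(imgs, gl, None, hp, rng)
        d = dice_score(gl[0], ag[0])
        assert 0.5 < d < 1.0

    def test_masks_stay_binary(self, rng):
        imgs, gl, pz = self._data(rng)
        hp = HyperparamVector(aug_rotation_deg=15, aug_width_shift=0.1,
                              aug_height_shift=0.1, aug_zoom=0.2, aug_hflip=True)
        _, ag, ap = augment_batch(imgs, gl, pz, hp, rng)
        assert set(np.unique(ag)) <= {0, 1}
        assert set(np.unique(ap)) <= {0, 1}


class TestFuseAndVote:
    def test_fuse_identical_maps_idempotent(self, rng):
        p = rng.random((16, 16, 8))
        crop = p[4:12, 4:12, :]
        fused = fuse_pair(p, crop, (4, 4, 0))
        np.testing.assert_allclose(fused, p)

    def test_fuse_arithmetic_mean_inside_crop_only(self):
        p2d = np.full((16, 16, 8), 0.2)
        p3d = np.full((8, 8, 8), 0.6)
        fused = fuse_pair(p2d, p3d, (4, 4, 0))
        assert fused[8, 8, 0] == pytest.approx(0.4)
        assert fused[0, 0, 0] == pytest.approx(0.2)  # outside: 2D stands alone

    def test_fuse_out_of_bounds_offsets_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            fuse_pair(np.zeros((16, 16, 8)), np.zeros((8, 8, 8)), (12, 4, 0))

    def test_vote_definition_and_symmetry(self, rng):
        masks = [(rng.random((6, 6)) > 0.5).astype(np.uint8) for _ in range(5)]
        vote = majority_vote(masks)
        counts = np.sum(masks, axis=0)
        np.testing.assert_array_equal(vote, counts > 2.5)
        perm = [masks[i] for i in rng.permutation(5)]
        np.testing.assert_array_equal(majority_vote(perm), vote)

    def test_all_identical_members_return_that_mask(self, rng):
        m = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(majority_vote([m] * 5), m)

    def test_even_member_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            majority_vote([np.zeros((2, 2))] * 4)

    def test_vote_threshold_equivalence(self, rng):
        # majority of thresholded maps == thresholding the vote fraction at 0.5
        probs = [rng.random((8, 8)) for _ in range(5)]
        thresholded = [(p >= 0.5).astype(np.uint8) for p in probs]
        vote = majority_vote(thresholded)
        frac = np.mean(thresholded, axis=0)
        np.testing.assert_array_equal(vote, (frac > 0.5).astype(np.uint8))


class TestTrainMember:
    @pytest.fixture(scope="class")
    def fold_data(self, small_cohort):
        pre = VolumePreprocessor(PreprocessConfig(
            target_spacing_mm=(5.0, 5.0, 6.0), target_shape=(16, 16, 8),
            crop3d_shape=(8, 8, 8)))
        std = [pre.transform(s, m)[:2] for s, m in small_cohort]
        train = EnsembleSegmenter._dataset_2d(std[:6])
        valid = EnsembleSegmenter._dataset_2d(std[6:])
        return train, valid

    def test_learning_smoke_and_checkpoint_rule(self, fold_data):
        train, valid = fold_data
        hp = HyperparamVector(n_blocks=1, base_filters=4, dropout_p=0.0,
                              aug_rotation_deg=0, aug_width_shift=0,
                              aug_height_shift=0, aug_zoom=0, aug_hflip=False)
        sch = TrainSchedule(learning_rate=3e-3, batch_size=16)
        net, history = train_member(hp, "2d", train, valid, sch, seed=0,
                                    epochs=30)
        assert len(history["train_loss"]) == 30
        assert history["train_loss"][-1] < history["train_loss"][0]
        assert min(history["valid_loss"]) <= history["valid_loss"][-1]

    def test_single_epoch_logged(self, fold_data):
        train, valid = fold_data
        hp = HyperparamVector(n_blocks=1, base_filters=2, dropout_p=0.0)
        sch = TrainSchedule(learning_rate=1e-3, batch_size=16)
        _, history = train_member(hp, "2d", train, valid, sch, seed=0, epochs=1)
        assert len(history["train_loss"]) == 1
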