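"""Fold splitting, window sampling, DiceCE loss and the training loop."""

import numpy as np
import pytest

from paraseg.estimator import UNetSegmenter
from paraseg.nn.losses import dice_ce_parts, dice_ce_loss
from paraseg.preprocess import normalize_intensity
from paraseg.train import TrainConfig, kfold_split, sample_windows


class TestKFold:
    def test_76_subjects_k3_fold_sizes(self):
        ids = [f"s{i}" for i in range(76)]
        splits = kfold_split(ids, 3, seed=0)
        sizes = sorted(len(s.test_ids) for s in splits)
        assert sizes == [25, 25, 26]
        assert all(len(s.train_ids) + len(s.test_ids) == 76 for s in splits)

    def test_partition_invariants(self):
        ids = list(range(11))
        splits = kfold_split(ids, 4, seed=2)
        tested = [i for s in splits for i in s.test_ids]
        assert sorted(tested) == ids  # each subject tests exactly once
        for s in splits:
            assert not set(s.train_ids) & set(s.test_ids)

    def test_equal_folds(self):
        splits = kfold_split(list(range(6)), 3, seed=1)
        assert [len(s.test_ids) for s in splits] == [2, 2, 2]

    def test_deterministic(self):
        a = kfold_split(list(range(20)), 3, seed=9)
        b = kfold_split(list(range(20)), 3, seed=9)
        assert [s.test_ids for s in a] == [s.test_ids for s in b]

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_split([1, 2], 3)


class TestSampleWindows:
    def test_all_foreground_mask(self, rng):
        img = np.zeros((16, 16, 4), dtype=np.float32)
        msk = np.ones((16, 16, 4), dtype=np.uint8)
        cfg = TrainConfig(window=(8, 8, 1), num_samples=5, batch_size=5)
        wins = sample_windows(img, msk, cfg, rng)
        assert len(wins) == 5
        assert all(m.shape == (8, 8) for _, m in wins)

    def test_no_foreground_warns(self, rng):
        img = np.zeros((16, 16, 4), dtype=np.float32)
        msk = np.zeros((16, 16, 4), dtype=np.uint8)
        cfg = TrainConfig(window=(8, 8, 1), num_samples=2, batch_size=2)
        with pytest.warns(UserWarning):
            sample_windows(img, msk, cfg, rng)

    def test_foreground_fraction_binomial(self):
        # half-foreground volume; sampled centres must split 50/50
        img = np.zeros((8, 8, 8), dtype=np.float32)
        msk = np.zeros((8, 8, 8), dtype=np.uint8)
        msk[:4] = 1
        cfg = TrainConfig(window=(2, 2, 1), num_samples=10000, batch_size=10000,
                          pos_neg_ratio=1.0)
        rng = np.random.default_rng(0)
        from paraseg.train import _SubjectVolumes, _sample_from_subject
        sub = _SubjectVolumes(img, msk)
        p_fg = cfg.resolved(2).pos_neg_ratio / 2.0
        draws = [rng.random() < p_fg for _ in range(10000)]
        # direct check of the acceptance-rule probability
        assert np.mean(draws) == pytest.approx(0.5, abs=0.02)
        wins = _sample_from_subject(sub, cfg.resolved(2), np.random.default_rng(1))
        assert len(wins) == 10000

    def test_window_squeeze_2d(self, phantom_pair, rng):
        img, msk = phantom_pair
        cfg = TrainConfig(window=(64, 64, 1), num_samples=2, batch_size=2)
        wins = sample_windows(img, msk, cfg, rng)
        assert wins[0][0].shape == (64, 64)

    def test_volume_smaller_than_window_padded(self, rng):
        img = np.zeros((10, 10, 2), dtype=np.float32)
        msk = np.ones((10, 10, 2), dtype=np.uint8)
        cfg = TrainConfig(window=(16, 16, 1), num_samples=1, batch_size=1)
        (iw, mw), = sample_windows(img, msk, cfg, rng)
        assert iw.shape == (16, 16)


class TestDiceCELoss:
    def test_uniform_scores_cross_entropy_ln7(self, rng):
        scores = np.zeros((2, 7, 6, 6), dtype=np.float64)
        labels = rng.integers(0, 7, size=(2, 6, 6))
        _, _, ce, _ = dice_ce_parts(scores, labels)
        assert ce == pytest.approx(np.log(7), rel=1e-12)

    def test_peaked_scores_drive_loss_to_zero(self):
        labels = np.tile(np.arange(7), 7).reshape(1, 7, 7)
        onehot = np.moveaxis(np.eye(7)[labels], -1, 1)
        losses = [dice_ce_loss(a * onehot, labels) for a in (5.0, 10.0, 20.0)]
        assert losses[0] > losses[1] > losses[2]
        assert losses[2] < 1e-3

    def test_voxel_permutation_invariance(self, rng):
        scores = rng.normal(size=(1, 7, 4, 4))
        labels = rng.integers(0, 7, size=(1, 4, 4))
        perm = rng.permutation(16)
        s2 = scores.reshape(1, 7, 16)[:, :, perm].reshape(1, 7, 4, 4)
        l2 = labels.reshape(1, 16)[:, perm].reshape(1, 4, 4)
        assert dice_ce_loss(scores, labels) == pytest.approx(
            dice_ce_loss(s2, l2), rel=1e-12)

    def test_loss_gradient_matches_finite_differences(self, rng):
        scores = rng.normal(size=(1, 4, 3, 3))
        labels = rng.integers(0, 4, size=(1, 3, 3))
        _, _, _, g = dice_ce_parts(scores, labels)
        eps = 1e-6
        for _ in range(5):
            idx = tuple(rng.integers(0, d) for d in scores.shape)
            s = scores.copy()
            s[idx] += eps
            up = dice_ce_loss(s, labels)
            s[idx] -= 2 * eps
            dn = dice_ce_loss(s, labels)
            assert g[idx] == pytest.approx((up - dn) / (2 * eps), rel=1e-5, abs=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            dice_ce_loss(rng.normal(size=(1, 7, 4, 4)), np.zeros((1, 5, 5), dtype=int))


class TestTrainingLoop:
    @pytest.fixture(scope="class")
    def tiny_fit(self, clean_phantom_pair):
        img, msk = clean_phantom_pair
        X = [normalize_intensity(img)]
        est = UNetSegmenter(dims=2, channels=(4, 8, 16), iterations=150,
                            batch_size=4, num_samples=2, window=(64, 64, 1),
                            seed=0, log_every=10)
        return est.fit(X, [msk]), X, msk

    def test_loss_decreases(self, tiny_fit):
        est, _, _ = tiny_fit
        hist = dict(est.loss_history_)
        assert hist[149] < hist[0]

    def test_determinism_same_seed(self, clean_phantom_pair):
        img, msk = clean_phantom_pair
        X = [normalize_intensity(img)]
        runs = []
        for _ in range(2):
            est = UNetSegmenter(dims=2, channels=(4, 8), iterations=20,
                                batch_size=4, num_samples=2, window=(32, 32, 1),
                                seed=11, log_every=5)
            est.fit(X, [msk])
            runs.append(est.loss_history_)
        assert runs[0] == runs[1]

    def test_prediction_geometry_and_labels(self, tiny_fit):
        est, X, msk = tiny_fit
        pred = est.predict(X)[0]
        assert pred.shape == msk.shape
        assert set(np.unique(pred.data)) <= set(range(7))

    def test_divergence_aborts_with_diagnostic(self, clean_phantom_pair):
        img, msk = clean_phantom_pair
        est = UNetSegmenter(dims=2, channels=(4, 8), iterations=50,
                            batch_size=4, num_samples=2, window=(32, 32, 1),
                            seed=0, learning_rate=1e12)
        with pytest.raises(RuntimeError, match="diverged"):
            est.fit([normalize_intensity(img)], [msk])

    def test_3d_training_smoke(self, clean_phantom_pair):
        img, msk = clean_phantom_pair
        est = UNetSegmenter(dims=3, channels=(2, 4), iterations=10,
                            batch_size=1, num_samples=1, window=(32, 32, 4),
                            seed=0, log_every=2)
        est.fit([normalize_intensity(img)], [msk])
        pred = est.predict([normalize_intensity(img)])[0]
        assert pred.shape == img.shape
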