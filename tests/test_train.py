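"""Split, augmentation, loss and training-loop behavior."""

import numpy as np
import pytest

from hepaseg import (
    AugmentConfig,
    NetworkSpec,
    TrainConfig,
    augment_pair,
    bce_loss,
    build_unet,
    default_train_config,
    split_dataset,
    train_network,
)


class TestSplit:
    @pytest.mark.parametrize("n,fraction,expected", [
        (740, 0.8, (592, 148)),
        (700, 0.7, (490, 210)),
    ])
    def test_published_counts(self, n, fraction, expected):
        tr, va = split_dataset(n, fraction, seed=0)
        assert (len(tr), len(va)) == expected

    @pytest.mark.parametrize("n", [4, 10, 37, 101])
    @pytest.mark.parametrize("fraction", [0.5, 0.7, 0.8])
    def test_partition_property(self, n, fraction):
        tr, va = split_dataset(n, fraction, seed=3)
        union = np.sort(np.concatenate([tr, va]))
        np.testing.assert_array_equal(union, np.arange(n))
        assert len(np.intersect1d(tr, va)) == 0

    def test_reproducible_given_seed(self):
        a = split_dataset(50, 0.8, seed=11)
        b = split_dataset(50, 0.8, seed=11)
        np.testing.assert_array_equal(a[0], b[0])

    def test_degenerate_cases_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(1, 0.8)
        with pytest.raises(ValueError):
            split_dataset(100, 0.0)
        with pytest.raises(ValueError):
            split_dataset(3, 0.99)  # empty validation


class TestAugment:
    def test_disabled_is_identity(self, rng):
        img = np.random.default_rng(0).random((16, 16))
        mask = (img > 0.5).astype(np.uint8)
        out_img, out_mask = augment_pair(img, mask, AugmentConfig.disabled(), rng)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_flip_alignment_index_reversal_oracle(self):
        """With only flips enabled the transform is an exact index reversal,
        so mask(flipped image) == flip(mask)."""
        base = np.zeros((8, 8))
        base[1:3, 2:7] = 1.0  # asymmetric
        mask = base.astype(np.uint8)
        cfg = AugmentConfig(shift_fraction=0.0, zoom_range=(1.0, 1.0))
        seen = set()
        for seed in range(20):
            r = np.random.default_rng(seed)
            img_t, mask_t = augment_pair(base, mask, cfg, r)
            np.testing.assert_array_equal((img_t > 0.5).astype(np.uint8), mask_t)
            seen.add(mask_t.tobytes())
        assert len(seen) > 1  # several distinct flip combinations occurred

    @pytest.mark.parametrize("seed", range(100))
    def test_image_mask_alignment_under_full_transform(self, seed):
        """The mask transformed alongside a binary image stays identical to
        the transformed image re-thresholded: IoU exactly 1."""
        base = np.zeros((24, 24), dtype=np.float32)
        base[6:14, 9:20] = 1.0
        mask = base.astype(np.uint8)
        img_t, mask_t = augment_pair(base, mask, AugmentConfig(), np.random.default_rng(seed))
        np.testing.assert_array_equal((img_t >= 0.5).astype(np.uint8), mask_t)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            augment_pair(np.zeros((4, 4)), np.zeros((5, 4)), AugmentConfig(), rng)


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        p = np.array([1.0, 0.0, 1.0])
        assert bce_loss(p, y) < 1e-6

    def test_uninformative_prediction_is_ln2(self):
        y = np.array([1.0, 0.0])
        assert abs(bce_loss(np.full(2, 0.5), y) - np.log(2)) < 1e-12

    def test_hand_computed_two_by_two(self):
        p = np.array([[0.9, 0.1], [0.8, 0.2]])
        y = np.array([[1.0, 0.0], [1.0, 0.0]])
        # mean of (-ln .9, -ln .9, -ln .8, -ln .8) = 0.1642520
        assert abs(bce_loss(p, y) - 0.1642520) < 1e-6

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros(3), np.zeros(4))


def _toy_disk_data(n, size, rng):
    """Bright disk on dark background: a linearly separable toy task."""
    images = np.zeros((n, size, size), dtype=np.float32)
    masks = np.zeros((n, size, size), dtype=np.uint8)
    yy, xx = np.mgrid[:size, :size]
    for i in range(n):
        cy, cx = rng.integers(size // 4, 3 * size // 4, size=2)
        r = rng.integers(size // 8, size // 4)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        masks[i][disk] = 1
        images[i] = 0.1 + 0.7 * disk + 0.03 * rng.standard_normal((size, size))
    return np.clip(images, 0, 1), masks


class TestTrainLoop:
    def test_zero_epochs_is_a_no_op(self, rng):
        net = build_unet(NetworkSpec(variant=1, base_filters=2, depth=1, input_size=16))
        before = [p.value.copy() for p in net.params()]
        imgs, masks = _toy_disk_data(4, 16, rng)
        tc = TrainConfig(epochs=0, batch_size=2, steps_per_epoch=1, seed=0)
        _, history = train_network(net, (imgs, masks), None, tc)
        assert history.empty
        for p, b in zip(net.params(), before):
            np.testing.assert_array_equal(p.value, b)

    @pytest.mark.parametrize("variant", [1, 2, 3])
    def test_loss_decreases_on_separable_toy(self, variant, rng):
        imgs, masks = _toy_disk_data(8, 32, rng)
        net = build_unet(NetworkSpec(variant=variant, base_filters=4, depth=2,
                                     input_size=32), seed=1)
        tc = TrainConfig(epochs=3, batch_size=4, steps_per_epoch=5,
                         learning_rate=1e-3, seed=1)
        _, history = train_network(net, (imgs, masks), None, tc)
        assert history.train_loss.iloc[-1] < history.train_loss.iloc[0]

    def test_training_is_reproducible(self, rng):
        imgs, masks = _toy_disk_data(6, 16, rng)
        histories = []
        for _ in range(2):
            net = build_unet(NetworkSpec(variant=1, base_filters=2, depth=1,
                                         input_size=16), seed=4)
            tc = TrainConfig(epochs=2, batch_size=2, steps_per_epoch=3, seed=4)
            _, h = train_network(net, (imgs, masks), (imgs[:2], masks[:2]), tc)
            histories.append(h)
        np.testing.assert_array_equal(histories[0].train_loss, histories[1].train_loss)
        np.testing.assert_array_equal(histories[0].val_loss, histories[1].val_loss)

    def test_empty_training_set_rejected(self):
        net = build_unet(NetworkSpec(variant=1, base_filters=2, depth=1, input_size=16))
        with pytest.raises(ValueError, match="empty"):
            train_network(net, (np.zeros((0, 16, 16)), np.zeros((0, 16, 16))),
                          None, TrainConfig())


def test_task_hyperparameter_table():
    hl = default_train_config("HL", 1)
    assert (hl.epochs, hl.batch_size, hl.steps_per_epoch,
            hl.base_filters, hl.learning_rate) == (20, 8, 35, 8, 1e-3)
    mla = default_train_config("MLA", 2)
    assert (mla.batch_size, mla.steps_per_epoch, mla.learning_rate) == (10, 55, 1e-1)
    lm1 = default_train_config("LM", 1)
    assert (lm1.batch_size, lm1.steps_per_epoch, lm1.base_filters) == (8, 65, 8)
    lm2 = default_train_config("LM", 2)
    assert (lm2.batch_size, lm2.steps_per_epoch, lm2.base_filters) == (10, 35, 8)
    lm3 = default_train_config("LM", 3)
    assert (lm3.batch_size, lm3.steps_per_epoch, lm3.base_filters) == (10, 65, 5)
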