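"""Loss function, cube-level splitting, and the optimization schedule."""

import numpy as np
import pytest

from octfluid.model import build_unet
from octfluid.train import (SegmentationDataset, TrainConfig,
                            dataset_from_cubes, smooth_dice_loss,
                            _smooth_dice_loss_grad, split_by_cube, train_model)


def brute_smooth_dice(pred: np.ndarray, target: np.ndarray) -> float:
    """Literal set-arithmetic evaluation for binary grids."""
    inter = sum(1 for p, t in zip(pred.ravel(), target.ravel()) if p and t)
    sx = int(pred.sum())
    sy = int(target.sum())
    return 1.0 - 2.0 * (inter + 1.0) / (sx + sy + 1.0)


class TestSmoothDiceLoss:
    def test_empty_vs_empty_is_minus_one(self):
        z = np.zeros((10, 10))
        assert smooth_dice_loss(z, z) == pytest.approx(-1.0)

    def test_identical_100_pixel_masks(self):
        m = np.zeros(200); m[:100] = 1
        assert smooth_dice_loss(m, m) == pytest.approx(-1.0 / 201.0)

    def test_disjoint_100_pixel_masks(self):
        a = np.zeros(200); a[:100] = 1
        b = np.zeros(200); b[100:] = 1
        assert smooth_dice_loss(a, b) == pytest.approx(199.0 / 201.0)

    def test_conventional_variant(self):
        z = np.zeros((4, 4))
        assert smooth_dice_loss(z, z, conventional=True) == pytest.approx(0.0)

    def test_matches_brute_force_on_binary_pairs(self, rng):
        for _ in range(300):
            a = (rng.random((8, 8)) < rng.uniform(0, 1)).astype(float)
            b = (rng.random((8, 8)) < rng.uniform(0, 1)).astype(float)
            assert smooth_dice_loss(a, b) == pytest.approx(
                brute_smooth_dice(a, b), abs=1e-12)

    def test_decreasing_in_soft_intersection(self, rng):
        # holding sums fixed, more overlap means lower loss
        t = np.zeros(16); t[:8] = 1
        low = np.concatenate([np.full(8, 0.2), np.full(8, 0.8)])
        high = np.concatenate([np.full(8, 0.8), np.full(8, 0.2)])
        assert smooth_dice_loss(high, t) < smooth_dice_loss(low, t)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            smooth_dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_gradient_matches_finite_difference(self, rng):
        pred = rng.uniform(0.1, 0.9, (2, 6, 6))
        target = (rng.random((2, 6, 6)) < 0.4).astype(float)
        loss, grad = _smooth_dice_loss_grad(pred, target)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 3, 3), (0, 5, 2)]:
            p2 = pred.copy(); p2[idx] += eps
            lp, _ = _smooth_dice_loss_grad(p2, target)
            p2[idx] -= 2 * eps
            lm, _ = _smooth_dice_loss_grad(p2, target)
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


class TestSplitByCube:
    def test_48_cubes_20_15_leaves_13_test(self):
        plan = split_by_cube([f"c{i}" for i in range(48)], 20, 15, seed=0)
        assert len(plan.train) == 20
        assert len(plan.val) == 15
        assert len(plan.test) == 13

    def test_determinism_and_disjointness(self):
        ids = list(range(30))
        p1 = split_by_cube(ids, 10, 5, seed=7)
        p2 = split_by_cube(ids, 10, 5, seed=7)
        assert p1 == p2
        assert not (set(p1.train) & set(p1.val))
        assert not (set(p1.train) & set(p1.test))
        assert not (set(p1.val) & set(p1.test))
        assert set(p1.train) | set(p1.val) | set(p1.test) == set(ids)

    def test_insufficient_cubes_raises(self):
        with pytest.raises(ValueError):
            split_by_cube([1, 2, 3], 2, 2)


def _scripted_training(val_sequence, cfg):
    """Run the real loop on a tiny problem with a scripted validation signal."""
    model = build_unet(base_width=4, input_size=None, seed=0)
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
    msk = np.zeros((16, 16), dtype=bool)
    data = SegmentationDataset(((img, msk),), ((img, msk),))
    return train_model(model, data, aug=None, cfg=cfg,
                       validation_fn=lambda m, e: val_sequence(e))


class TestSchedule:
    def test_single_epoch_run(self):
        model, hist = _scripted_training(lambda e: 0.5,
                                         TrainConfig(max_epochs=1, seed=0))
        assert len(hist.train_loss) == 1
        assert hist.best_epoch == 1
        assert hist.stop_reason == "max_epochs"

    def test_lr_drop_after_exact_plateau(self):
        # validation improves for 3 epochs then plateaus forever
        cfg = TrainConfig(plateau_patience=4, early_stop_patience=8,
                          max_epochs=12, seed=0)
        _, hist = _scripted_training(lambda e: max(1.0 - 0.1 * e, 0.7), cfg)
        # best at epoch 3; stall counts epochs 4.. ; drop after 4 stalled
        assert hist.best_epoch == 3
        lrs = hist.lr
        assert lrs[:7] == [cfg.lr0] * 7          # epochs 1-7 at lr0
        assert lrs[7] == pytest.approx(cfg.lr0 * 0.3)  # drop applied for epoch 8

    def test_early_stop_returns_best_snapshot(self):
        cfg = TrainConfig(plateau_patience=3, early_stop_patience=6,
                          max_epochs=50, seed=0)
        model, hist = _scripted_training(lambda e: float(e), cfg)
        assert hist.best_epoch == 1
        assert hist.stop_reason == "early_stopping"
        assert len(hist.val_loss) == 7           # stop at patience+1 epochs

    def test_lr_sequence_non_increasing_with_factor_drops(self):
        cfg = TrainConfig(plateau_patience=2, early_stop_patience=6,
                          max_epochs=10, seed=0)
        _, hist = _scripted_training(lambda e: 1.0, cfg)
        lrs = np.array(hist.lr)
        assert np.all(np.diff(lrs) <= 1e-15)
        drops = lrs[1:][np.diff(lrs) < 0] / lrs[:-1][np.diff(lrs) < 0]
        assert np.allclose(drops, cfg.plateau_factor)

    def test_empty_split_raises(self):
        with pytest.raises(ValueError):
            train_model(build_unet(base_width=4, input_size=None),
                        SegmentationDataset((), ()), cfg=TrainConfig(max_epochs=1))

    def test_warmup_ramps_lr(self):
        cfg = TrainConfig(warmup_epochs=2, max_epochs=4, seed=0)
        _, hist = _scripted_training(lambda e: 1.0, cfg)
        assert hist.lr[0] == pytest.approx(cfg.lr0 * (0.1 + 0.9 / 3))
        assert hist.lr[1] == pytest.approx(cfg.lr0 * (0.1 + 0.9 * 2 / 3))
        assert hist.lr[2] == pytest.approx(cfg.lr0)

    def test_gradient_clipping_bounds_update(self):
        def run(clip):
            model = build_unet(base_width=4, input_size=None, seed=0)
            rng = np.random.default_rng(0)
            img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            msk = np.zeros((16, 16), dtype=bool); msk[4:9, 4:9] = True
            data = SegmentationDataset(((img, msk),), ((img, msk),))
            init = {k: v.copy() for k, v in model.parameters().items()}
            model, _ = train_model(model, data, cfg=TrainConfig(
                max_epochs=1, seed=0, grad_clip=clip))
            return np.sqrt(sum(float(((v - init[k]) ** 2).sum())
                               for k, v in model.parameters().items()))
        assert run(1e-8) < 1e-6 < run(None)


def test_real_training_reduces_loss_and_restores_best():
    """A few epochs on a trivially separable slice task must reduce the loss,
    and the returned snapshot must reproduce its recorded validation loss."""
    from octfluid.train import evaluate_loss
    rng = np.random.default_rng(0)
    pairs = []
    for _ in range(6):
        msk = np.zeros((32, 32), dtype=bool)
        y, x = rng.integers(8, 24, 2)
        msk[y - 4:y + 4, x - 4:x + 4] = True
        img = np.where(msk, 40, 200).astype(np.uint8)
        pairs.append((img, msk))
    data = SegmentationDataset(tuple(pairs[:4]), tuple(pairs[4:]))
    model = build_unet(base_width=4, input_size=None, seed=1)
    cfg = TrainConfig(batch_size=4, lr0=0.05, max_epochs=6, seed=0)
    model, hist = train_model(model, data, aug=None, cfg=cfg)
    assert hist.val_loss[-1] < hist.val_loss[0] or min(hist.val_loss) < hist.val_loss[0]
    re_eval = evaluate_loss(model, data.val_pairs, cfg.batch_size)
    assert re_eval == pytest.approx(hist.val_loss[hist.best_epoch - 1], abs=1e-6)


def test_dataset_from_cubes_flattens_all_slices(small_cube):
    volume, mask = small_cube
    ds = dataset_from_cubes([(volume, mask)], [(volume, mask)])
    assert len(ds.train_pairs) == volume.shape[0]
    img, msk = ds.train_pairs[3]
    assert np.array_equal(img, volume[3])
    assert np.array_equal(msk, mask[3])
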