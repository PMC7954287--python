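import dataclasses

import numpy as np
import pytest

from dlseg.architectures import build_network
from dlseg.config import (ArchitectureSpec, AugmentationParams,
                          TrainingConfig)
from dlseg.dataset_prep import SplitResult
from dlseg.image_io import ImageVolume, LabelMask
from dlseg.training import (TrainingError, compute_loss,
                            inverse_frequency_weights, load_checkpoint,
                            resume_training, save_checkpoint, train_model,
                            validate_model)

SPEC = ArchitectureSpec("unet2d", (16, 16, 1, 1), 2, depth_levels=1,
                        n_first_filters=8, padding="same")


def threshold_pairs(n=4, seed=1, size=32):
    """Tiny separable task: class = (intensity > 0.5)."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        im = rng.random((1, size, size, 1)).astype(np.float32)
        pairs.append((ImageVolume(im),
                      LabelMask((im[..., 0] > 0.5).astype(np.int64), 2)))
    return pairs


def make_split(n=4, n_val=1, seed=1):
    pairs = threshold_pairs(n, seed)
    return SplitResult(pairs[:n - n_val], pairs[n - n_val:], seed,
                       n_val / n)


def base_cfg(**over):
    kw = dict(max_epochs=4, batch_size=2, patches_per_image=4, seed=5,
              augmentation=AugmentationParams(rotation_range=30,
                                              shear_range=5))
    kw.update(over)
    return TrainingConfig(**kw)


class TestComputeLoss:
    def test_one_hot_correct_is_zero(self):
        target = np.array([[[0, 1], [1, 0]]])
        scores = np.eye(2)[target]
        assert compute_loss(scores, target) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("k", [2, 4])
    def test_uniform_scores_give_log_k(self, k):
        scores = np.full((1, 3, 3, k), 1.0 / k)
        target = np.zeros((1, 3, 3), np.int64)
        assert compute_loss(scores, target) == pytest.approx(np.log(k))

    def test_shape_mismatch_and_bad_weights(self):
        scores = np.full((1, 2, 2, 2), 0.5)
        with pytest.raises(TrainingError, match="mismatch"):
            compute_loss(scores, np.zeros((1, 3, 3), np.int64))
        with pytest.raises(TrainingError, match="class_weights"):
            compute_loss(scores, np.zeros((1, 2, 2), np.int64), [1.0, 1.0, 1.0])

    def test_class_weights_reweight(self):
        # all-background target, weight on class 0 only: same as unweighted
        scores = np.full((1, 2, 2, 2), 0.5)
        target = np.zeros((1, 2, 2), np.int64)
        assert compute_loss(scores, target, [2.0, 0.5]) == pytest.approx(np.log(2))


def test_fixed_seed_runs_are_bit_identical():
    split = make_split()
    cfg = base_cfg()
    _, h1, _ = train_model(build_network(SPEC, seed=5), split, cfg)
    _, h2, _ = train_model(build_network(SPEC, seed=5), split, cfg)
    assert h1.train_loss == h2.train_loss
    assert h1.val_loss == h2.val_loss


def test_zero_learning_rate_leaves_weights_unchanged():
    split = make_split()
    model = build_network(SPEC, seed=5)
    before = {p.name: p.value.copy() for p in model.parameters()}
    model, hist, _ = train_model(model, split, base_cfg(learning_rate=0.0))
    for p in model.parameters():
        assert np.array_equal(p.value, before[p.name])


def test_resume_equals_uninterrupted_run():
    split = make_split()
    _, h10, _ = train_model(build_network(SPEC, seed=5), split,
                            base_cfg(max_epochs=8))
    m10w = None
    m10, h10b, _ = train_model(build_network(SPEC, seed=5), split,
                               base_cfg(max_epochs=8))
    m4, h4, c4 = train_model(build_network(SPEC, seed=5), split,
                             base_cfg(max_epochs=4))
    mr, hr, _ = resume_training(c4[-1], split, 4)
    assert hr.train_loss == h10b.train_loss
    w10 = {p.name: p.value for p in m10.parameters()}
    for p in mr.parameters():
        assert np.array_equal(p.value, w10[p.name]), p.name


def test_resume_zero_epochs_is_identity():
    split = make_split()
    _, _, ckpts = train_model(build_network(SPEC, seed=5), split, base_cfg())
    model, hist, new = resume_training(ckpts[-1], split, 0)
    assert new == []
    for p in model.parameters():
        assert np.array_equal(p.value, ckpts[-1].state[p.name])


def test_mid_epoch_checkpoint_resumes_exactly():
    split = make_split()
    cfg = base_cfg(max_epochs=4, checkpoint_every_n_iterations=3)
    m_full, h_full, ckpts = train_model(build_network(SPEC, seed=5), split, cfg)
    mid = next(c for c in ckpts if c.batches_into_epoch)
    epochs_left = cfg.max_epochs - mid.epoch
    mr, hr, _ = resume_training(mid, split, epochs_left)
    assert hr.train_loss == h_full.train_loss
    wf = {p.name: p.value for p in m_full.parameters()}
    for p in mr.parameters():
        assert np.array_equal(p.value, wf[p.name])


def test_resume_twice_is_deterministic():
    split = make_split()
    _, _, c = train_model(build_network(SPEC, seed=5), split,
                          base_cfg(max_epochs=3))
    _, ha, _ = resume_training(c[-1], split, 2)
    _, hb, _ = resume_training(c[-1], split, 2)
    assert ha.train_loss == hb.train_loss


def test_checkpoint_disk_round_trip(tmp_path):
    split = make_split()
    _, h8, _ = train_model(build_network(SPEC, seed=5), split,
                           base_cfg(max_epochs=6))
    _, _, c3 = train_model(build_network(SPEC, seed=5), split,
                           base_cfg(max_epochs=3))
    save_checkpoint(c3[-1], tmp_path / "ck")
    rec = load_checkpoint(tmp_path / "ck")
    _, hr, _ = resume_training(rec, split, 3)
    assert hr.train_loss == h8.train_loss


def test_loss_decreases_on_separable_task():
    split = make_split(n=4, n_val=0)
    cfg = base_cfg(max_epochs=5, patches_per_image=16,
                   validation_fraction=0.0,
                   augmentation=AugmentationParams(enabled_2d=False))
    _, hist, _ = train_model(build_network(SPEC, seed=5), split, cfg)
    per_epoch = len(hist.train_loss) // 5
    first = np.mean(hist.train_loss[:per_epoch])
    last = np.mean(hist.train_loss[-per_epoch:])
    assert last < 0.5 * first


def test_empty_training_or_validation_sets():
    pairs = threshold_pairs(2)
    with pytest.raises(TrainingError, match="empty"):
        train_model(build_network(SPEC, seed=0),
                    SplitResult([], pairs, 0, 0.5), base_cfg())
    model = build_network(SPEC, seed=0)
    from conftest import identity_stats
    with pytest.raises(TrainingError, match="empty"):
        validate_model(model, [], base_cfg(), identity_stats(1))


def test_overfit_single_image_validates_near_one():
    pairs = threshold_pairs(1, size=32)
    split = SplitResult(pairs, pairs, 0, 0.0)
    cfg = base_cfg(max_epochs=25, patches_per_image=16, learning_rate=3e-3,
                   augmentation=AugmentationParams(enabled_2d=False))
    model, hist, _ = train_model(build_network(SPEC, seed=2), split, cfg)
    assert hist.val_jaccard[-1].min() > 0.9


def test_inverse_frequency_weights():
    mask = LabelMask(np.array([[[0, 0, 0, 1]]]), 2)
    w = inverse_frequency_weights([(None, mask)], 2)
    # rarer class gets the larger weight; weighted mean frequency balances
    assert w[1] > w[0] > 0
    assert w[0] * 3 == pytest.approx(w[1] * 1)
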