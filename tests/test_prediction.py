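import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlseg.architectures import build_network, output_shape
from dlseg.config import ArchitectureSpec, PredictionConfig
from dlseg.image_io import ImageVolume, LabelMask
from dlseg.prediction import (PredictionError, plan_tiles, predict_tiled,
                              scores_to_labels)

from conftest import identity_stats

SAME = ArchitectureSpec("unet2d", (128, 128, 1, 1), 2, depth_levels=2)
VALID = ArchitectureSpec("unet2d", (100, 100, 1, 1), 2, depth_levels=2,
                         n_first_filters=4, padding="valid")


def emit_coverage(plan):
    cover = np.zeros(plan.image_shape, np.int32)
    for t in plan.tiles:
        cover[t.out_placement] += 1
    return cover


class TestPlan:
    def test_single_tile_full_emit(self):
        plan = plan_tiles((1, 128, 128), SAME,
                          PredictionConfig(overlap_voxels=(0, 0, 0)))
        assert len(plan.tiles) == 1
        t = plan.tiles[0]
        assert t.out_placement[1] == slice(0, 128)

    def test_four_abutting_tiles(self):
        plan = plan_tiles((1, 256, 256), SAME,
                          PredictionConfig(overlap_voxels=(0, 0, 0)))
        assert len(plan.tiles) == 4
        assert emit_coverage(plan).min() == 1

    def test_valid_mode_stride_is_output_size(self):
        plan = plan_tiles((1, 256, 256), VALID, PredictionConfig())
        # output 60 per axis -> ceil(256/60) = 5 tiles per axis
        assert len(plan.tiles) == 25
        cov = emit_coverage(plan)
        assert cov.min() == 1 and cov.max() == 1
        # input windows are patch sized
        for t in plan.tiles:
            assert t.in_window[1].stop - t.in_window[1].start == 100

    def test_overlap_margin_discarded(self):
        plan = plan_tiles((1, 224, 224), SAME,
                          PredictionConfig(overlap_voxels=(0, 32, 32)))
        cov = emit_coverage(plan)
        assert cov.min() == 1 and cov.max() == 1
        # an interior tile discards floor(32/2) = 16 on its low side
        t = plan.tiles[-1]
        assert t.emit_crop[1].start == t.out_placement[1].start - 96

    def test_overlap_too_large(self):
        with pytest.raises(PredictionError, match="overlap"):
            plan_tiles((1, 256, 256), SAME,
                       PredictionConfig(overlap_voxels=(0, 128, 0)))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(size=st.integers(20, 400), overlap=st.integers(0, 100))
    def test_emit_partition_property_same_mode(self, size, overlap):
        overlap = min(overlap, 127)
        plan = plan_tiles((1, size, 200), SAME,
                          PredictionConfig(overlap_voxels=(0, overlap, 64)))
        cov = emit_coverage(plan)
        assert cov.min() == 1 and cov.max() == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(size=st.integers(10, 300))
    def test_emit_partition_property_valid_mode(self, size):
        plan = plan_tiles((1, size, 60), VALID, PredictionConfig())
        cov = emit_coverage(plan)
        assert cov.min() == 1 and cov.max() == 1


class TestPredict:
    def test_constant_input_constant_scores(self):
        model = build_network(VALID, seed=0)
        img = ImageVolume(np.full((1, 150, 130, 1), 0.3, np.float32))
        scores = predict_tiled(model, img, identity_stats(1))
        spread = (scores.max(axis=(0, 1, 2)) - scores.min(axis=(0, 1, 2)))
        assert spread.max() == 0.0
        assert np.allclose(scores.sum(axis=-1), 1.0, atol=1e-5)

    def test_valid_tiling_equals_whole_image_pass(self):
        model = build_network(VALID, seed=0)
        rng = np.random.default_rng(4)
        img = ImageVolume(rng.random((1, 60, 60, 1), dtype=np.float32))
        tiled = predict_tiled(model, img, identity_stats(1))
        padded = np.pad(np.moveaxis(img.data, 3, 0),
                        ((0, 0), (0, 0), (20, 20), (20, 20)), mode="reflect")
        direct = model.forward(padded[None])[0]
        assert np.array_equal(np.moveaxis(tiled, 3, 0), direct)

    def test_same_mode_single_tile_equals_direct(self):
        model = build_network(SAME, seed=1)
        rng = np.random.default_rng(5)
        img = ImageVolume(rng.random((1, 128, 128, 1), dtype=np.float32))
        tiled = predict_tiled(model, img, identity_stats(1),
                              PredictionConfig(overlap_voxels=(0, 0, 0)))
        direct = model.forward(np.moveaxis(img.data, 3, 0)[None])[0]
        assert np.array_equal(np.moveaxis(tiled, 3, 0), direct)

    def test_interior_scores_independent_of_overlap(self):
        # voxels farther from every seam than the receptive field must not
        # depend on the chosen overlap
        model = build_network(SAME, seed=2)
        rng = np.random.default_rng(6)
        img = ImageVolume(rng.random((1, 192, 192, 1), dtype=np.float32))
        a = predict_tiled(model, img, identity_stats(1),
                          PredictionConfig(overlap_voxels=(0, 64, 64)))
        b = predict_tiled(model, img, identity_stats(1),
                          PredictionConfig(overlap_voxels=(0, 96, 96)))
        # patch interior far from any border: compare a central block
        assert np.allclose(a[:, 16:48, 16:48], b[:, 16:48, 16:48], atol=1e-5)

    def test_channel_mismatch_rejected(self):
        model = build_network(SAME, seed=0)
        img = ImageVolume(np.zeros((1, 128, 128, 3), np.float32))
        with pytest.raises(PredictionError, match="channel"):
            predict_tiled(model, img, identity_stats(3))

    def test_smaller_than_patch_image_is_padded(self):
        model = build_network(SAME, seed=0)
        img = ImageVolume(np.random.default_rng(1)
                          .random((1, 100, 90, 1), dtype=np.float32))
        scores = predict_tiled(model, img, identity_stats(1))
        assert scores.shape == (1, 100, 90, 2)


class TestScoresToLabels:
    def test_argmax_and_tie_break(self):
        scores = np.array([[[[0.1, 0.9], [0.5, 0.5]]]])
        labels = scores_to_labels(scores)
        assert labels.data[0, 0, 0] == 1    # clear winner
        assert labels.data[0, 0, 1] == 0    # tie -> lowest class index

    def test_one_hot_round_trip(self, rng):
        masks = rng.integers(0, 4, (3, 8, 8))
        onehot = np.eye(4)[masks]
        back = scores_to_labels(onehot)
        assert np.array_equal(back.data, masks)
        assert back.n_classes == 4
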