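import numpy as np
import pytest

from dlseg.config import ArchitectureSpec, validate_architecture_spec, ConfigError
from dlseg.dataset_prep import NormalizationStats, SplitResult
from dlseg.image_io import ImageVolume, LabelMask


def identity_stats(n_channels: int) -> NormalizationStats:
    return NormalizationStats(np.zeros(n_channels), np.ones(n_channels),
                              np.zeros(n_channels), np.ones(n_channels),
                              "none")


def random_pair(rng, spatial=(1, 32, 32), channels=1, n_classes=2):
    img = rng.random(spatial + (channels,)).astype(np.float32)
    mask = (img[..., 0] > 0.5).astype(np.int64) % n_classes
    return ImageVolume(img), LabelMask(mask, n_classes)


def random_valid_spec(rng, max_depth=2):
    """Draw one validated ArchitectureSpec (small enough to run quickly)."""
    while True:
        family = rng.choice(["unet2d", "unet3d", "unet3d_aniso", "segnet2d"])
        padding = rng.choice(["same", "valid"])
        if family == "segnet2d":
            padding = "same"
        depth = int(rng.integers(1, max_depth + 1))
        if family == "unet3d_aniso":
            depth = max(depth, 2)
        n_classes = int(rng.integers(2, 4))
        filters = int(rng.choice([2, 4]))
        if family in ("unet2d", "segnet2d"):
            if padding == "valid":
                yx = int(rng.choice([20, 24, 28] if depth == 1 else [44, 52]))
            else:
                yx = int(rng.choice([8, 16, 24])) * 2 ** (depth - 1)
            patch = (yx, yx, 1, int(rng.integers(1, 3)))
        else:
            if padding == "valid":
                depth = 1
                yx = int(rng.choice([20, 24]))
                z = yx
                if family == "unet3d_aniso":
                    # aniso needs depth >= 2: too slow in valid 3D, use same
                    padding = "same"
                    depth = 2
                    yx, z = 16, 8
            else:
                yx = int(rng.choice([8, 16])) * 2 ** max(0, depth - 1)
                z = int(rng.choice([4, 8])) * 2 ** max(0, depth - 1)
                if family == "unet3d_aniso":
                    z = int(rng.choice([4, 8])) * 2 ** max(0, depth - 2)
            patch = (yx, yx, z, int(rng.integers(1, 3)))
        spec = ArchitectureSpec(family, patch, n_classes, depth_levels=depth,
                                n_first_filters=filters, padding=padding)
        try:
            return validate_architecture_spec(spec)
        except ConfigError:
            continue


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
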