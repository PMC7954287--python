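"""Preprocessing: train/validation split, chopping, patches, normalization.

Splitting operates on whole items (files or chopped subvolumes), never on
patches, so no voxel can leak between the training and validation sets.
All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import ArchitectureSpec
from .image_io import ImageVolume, LabelMask


class PrepError(ValueError):
    pass


@dataclass
class SplitResult:
    train_pairs: list
    validation_pairs: list
    seed: int
    fraction: float


@dataclass
class NormalizationStats:
    """Per-channel statistics pooled over all training voxels."""

    mean: np.ndarray
    std: np.ndarray
    min: np.ndarray
    max: np.ndarray
    mode: str


def split_train_validation(pairs: Sequence, fraction: float,
                           seed: int) -> SplitResult:
    """Randomly partition items into train / validation sets.

    The validation count is round-half-up(fraction * N); fraction 0 disables
    validation entirely.  Reproducible for a fixed seed.
    """
    if not 0.0 <= fraction <= 0.5:
        raise PrepError(f"fraction must be in [0, 0.5], got {fraction}")
    pairs = list(pairs)
    n = len(pairs)
    n_val = int(math.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [pairs[i] for i in range(n) if i not in val_idx]
    val = [pairs[i] for i in range(n) if i in val_idx]
    return SplitResult(train, val, seed, fraction)


def chop_volume(vol: ImageVolume, mask: Optional[LabelMask],
                grid: Tuple[int, int, int]
                ) -> List[Tuple[ImageVolume, Optional[LabelMask]]]:
    """Split one volume into an (nz, ny, nx) grid of subvolumes.

    Subvolumes tile the volume exactly; when an axis is not divisible the
    trailing subvolume absorbs the remainder, so concatenating the pieces
    back reproduces the original array.
    """
    nz, ny, nx = grid
    if min(grid) < 1:
        raise PrepError(f"grid components must be >= 1, got {grid}")
    Z, Y, X = vol.spatial_shape
    if nz > Z or ny > Y or nx > X:
        raise PrepError(
            f"grid {grid} larger than volume {vol.spatial_shape} in some axis")
    if mask is not None and mask.spatial_shape != vol.spatial_shape:
        raise PrepError("mask shape does not match volume")

    def edges(size, parts):
        base = size // parts
        # trailing piece absorbs the remainder
        bounds = [i * base for i in range(parts)] + [size]
        return bounds

    ez, ey, ex = edges(Z, nz), edges(Y, ny), edges(X, nx)
    out = []
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                sl = (slice(ez[iz], ez[iz + 1]),
                      slice(ey[iy], ey[iy + 1]),
                      slice(ex[ix], ex[ix + 1]))
                sub = ImageVolume(vol.data[sl], vol.voxel_size)
                smask = (LabelMask(mask.data[sl], mask.n_classes)
                         if mask is not None else None)
                out.append((sub, smask))
    return out


def sample_patches(pair: Tuple[ImageVolume, LabelMask],
                   spec: ArchitectureSpec, n: int, seed=0
                   ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Draw n uniform-random aligned (patch, patch_mask) crops.

    Patches are exactly ``spec.patch_size``; image and mask crops share the
    same offset.  ``seed`` may be an int or an existing Generator (the
    training loop passes its own stream for checkpointable determinism).
    Returns (c, z, y, x) image patches and (z, y, x) mask patches.
    """
    vol, mask = pair
    pz, py, px = spec.spatial_shape
    Z, Y, X = vol.spatial_shape
    if Z < pz or Y < py or X < px:
        raise PrepError(
            f"image spatial shape {(Z, Y, X)} smaller than patch {(pz, py, px)}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = []
    for _ in range(n):
        oz = int(rng.integers(0, Z - pz + 1))
        oy = int(rng.integers(0, Y - py + 1))
        ox = int(rng.integers(0, X - px + 1))
        sl = (slice(oz, oz + pz), slice(oy, oy + py), slice(ox, ox + px))
        patch = np.moveaxis(vol.data[sl], 3, 0).copy()   # (c, z, y, x)
        mpatch = mask.data[sl].copy() if mask is not None else None
        out.append((patch, mpatch))
    return out


def compute_normalization(pairs: Sequence[Tuple[ImageVolume, object]],
                          mode: str) -> NormalizationStats:
    """Pool per-channel mean/std/min/max over all training voxels."""
    if not pairs:
        raise PrepError("cannot compute normalization on an empty training set")
    first = pairs[0][0]
    c = first.n_channels
    if mode == "none":
        return NormalizationStats(np.zeros(c), np.ones(c),
                                  np.zeros(c), np.ones(c), mode)
    tot = np.zeros(c)
    tot2 = np.zeros(c)
    count = 0
    mn = np.full(c, np.inf)
    mx = np.full(c, -np.inf)
    for vol, _ in pairs:
        d = vol.data.reshape(-1, vol.n_channels).astype(np.float64)
        tot += d.sum(axis=0)
        tot2 += (d * d).sum(axis=0)
        count += d.shape[0]
        mn = np.minimum(mn, d.min(axis=0))
        mx = np.maximum(mx, d.max(axis=0))
    mean = tot / count
    var = np.maximum(tot2 / count - mean ** 2, 0.0)
    std = np.sqrt(var)
    if mode == "zscore" and np.any(std <= 0):
        bad = np.nonzero(std <= 0)[0].tolist()
        raise PrepError(
            f"zscore normalization undefined: constant channel(s) {bad}")
    if mode == "rescale01" and np.any(mx <= mn):
        bad = np.nonzero(mx <= mn)[0].tolist()
        raise PrepError(
            f"rescale01 normalization undefined: constant channel(s) {bad}")
    return NormalizationStats(mean, std, mn, mx, mode)


def apply_normalization(vol: ImageVolume,
                        stats: NormalizationStats) -> ImageVolume:
    """Apply training-time statistics to one volume (identity for 'none')."""
    data = vol.data.astype(np.float32)
    if stats.mode == "none":
        out = data
    elif stats.mode == "zero_center":
        out = data - stats.mean.astype(np.float32)
    elif stats.mode == "zscore":
        out = (data - stats.mean.astype(np.float32)) / stats.std.astype(np.float32)
    elif stats.mode == "rescale01":
        rng_ = (stats.max - stats.min).astype(np.float32)
        out = (data - stats.min.astype(np.float32)) / rng_
    else:
        raise PrepError(f"unknown normalization mode {stats.mode!r}")
    return ImageVolume(out, vol.voxel_size)


def stats_to_dict(stats: NormalizationStats) -> dict:
    return {"mean": stats.mean.tolist(), "std": stats.std.tolist(),
            "min": stats.min.tolist(), "max": stats.max.tolist(),
            "mode": stats.mode}


def stats_from_dict(d: dict) -> NormalizationStats:
    return NormalizationStats(np.asarray(d["mean"], float),
                              np.asarray(d["std"], float),
                              np.asarray(d["min"], float),
                              np.asarray(d["max"], float),
                              d["mode"])
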