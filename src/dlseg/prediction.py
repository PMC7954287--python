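"""Whole-image inference by overlap-tiling with padding-aware stitching.

Tiles are stitched by *central-crop emission*: each tile writes only an
interior region and the emitted regions partition the image domain exactly
(no averaging, no double-writes), so stitching is deterministic and
order-independent.

Valid-padding mode: input tiles are one patch large, strides equal the
network's output size (inputs overlap by the total shrink) and the input is
reflect-padded by half the shrink per side so the output covers the full
domain — the classic overlap-tile strategy.

Same-padding mode with per-axis overlap ``o``: stride = patch - o, each tile
emits its core up to the midpoint of the overlap with its neighbours
(discarding a margin of floor(o/2), except at image borders).  With o = 0
tiles abut, which is fast but prone to seam artefacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .architectures import NetworkModel, output_shape
from .config import ArchitectureSpec, PredictionConfig
from .dataset_prep import NormalizationStats, apply_normalization
from .image_io import ImageVolume, LabelMask


class PredictionError(ValueError):
    pass


@dataclass
class Tile:
    in_window: Tuple[slice, slice, slice]    # in padded-input coordinates
    out_placement: Tuple[slice, slice, slice]  # in image coordinates
    emit_crop: Tuple[slice, slice, slice]    # within the tile's network output


@dataclass
class TilePlan:
    tiles: List[Tile]
    pad: Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]  # per-axis (lo, hi)
    image_shape: Tuple[int, int, int]
    padded_shape: Tuple[int, int, int]


def _axis_plan_valid(S: int, P: int, Q: int) -> Tuple[List[Tuple[int, int, int, int]], int, int]:
    """Valid mode, one axis: tiles of input size P emitting Q, stride Q."""
    shrink = P - Q
    half = shrink // 2
    m = max(1, math.ceil(S / Q))
    pad_lo = half
    pad_hi = m * Q - S + half
    segs = []
    for i in range(m):
        out_lo = i * Q
        out_hi = min(out_lo + Q, S)
        segs.append((i * Q, i * Q + P, out_lo, out_hi))
    return segs, pad_lo, pad_hi


def _axis_plan_same(S: int, P: int, o: int) -> Tuple[List[Tuple[int, int, int, int]], int, int]:
    """Same mode, one axis: stride P - o, emit up to overlap midpoints."""
    if o >= P:
        raise PredictionError(f"overlap {o} must be smaller than patch {P}")
    pad_lo = 0
    pad_hi = max(0, P - S)
    Sp = S + pad_hi
    stride = P - o
    if Sp == P:
        positions = [0]
    else:
        m = math.ceil((Sp - P) / stride) + 1
        positions = sorted({min(i * stride, Sp - P) for i in range(m)})
    segs = []
    prev_cut = 0
    for j, p in enumerate(positions):
        if j + 1 < len(positions):
            cut = (positions[j + 1] + p + P) // 2
        else:
            cut = S
        cut = min(cut, S)
        segs.append((p, p + P, prev_cut, cut))
        prev_cut = cut
    return segs, pad_lo, pad_hi


def plan_tiles(image_shape: Tuple[int, int, int], spec: ArchitectureSpec,
               pcfg: PredictionConfig) -> TilePlan:
    """Compute the tiling of one (z, y, x) image for the given network."""
    patch = spec.spatial_shape
    out = output_shape(spec)
    if spec.padding == "valid":
        per_axis = [_axis_plan_valid(S, P, Q)
                    for S, P, Q in zip(image_shape, patch, out)]
    else:
        if pcfg.overlap_voxels is None:
            overlap = tuple(P // 4 for P in patch)
        else:
            overlap = tuple(pcfg.overlap_voxels)
        per_axis = [_axis_plan_same(S, P, o)
                    for S, P, o in zip(image_shape, patch, overlap)]
    pad = tuple((pl, ph) for _, pl, ph in per_axis)
    padded_shape = tuple(S + pl + ph for S, (pl, ph)
                         in zip(image_shape, pad))
    tiles = []
    for sz in per_axis[0][0]:
        for sy in per_axis[1][0]:
            for sx in per_axis[2][0]:
                in_win = tuple(slice(s[0], s[1]) for s in (sz, sy, sx))
                placement = tuple(slice(s[2], s[3]) for s in (sz, sy, sx))
                if spec.padding == "valid":
                    # tile output covers image coords [i*Q, i*Q + Q)
                    emit = tuple(slice(0, s[3] - s[2]) for s in (sz, sy, sx))
                else:
                    # tile output covers image coords [p, p + P)
                    emit = tuple(slice(s[2] - s[0], s[3] - s[0])
                                 for s in (sz, sy, sx))
                tiles.append(Tile(in_win, placement, emit))
    return TilePlan(tiles, pad, tuple(image_shape), padded_shape)


def _reflect_pad(data: np.ndarray, pad) -> np.ndarray:
    """Reflect-pad spatial axes; axes of extent 1 fall back to edge padding."""
    widths = [(0, 0)] + list(pad)
    out = data
    for ax, (lo, hi) in enumerate(widths):
        if lo == 0 and hi == 0:
            continue
        w = [(0, 0)] * out.ndim
        w[ax] = (lo, hi)
        mode = "reflect" if out.shape[ax] > 1 else "edge"
        out = np.pad(out, w, mode=mode)
    return out


def predict_tiled(model: NetworkModel, image: ImageVolume,
                  stats: NormalizationStats,
                  pcfg: Optional[PredictionConfig] = None) -> np.ndarray:
    """Normalize, tile, run the network and stitch a full score map.

    Returns a (z, y, x, class) softmax-normalized score map spatially
    congruent with the input image.
    """
    pcfg = pcfg or PredictionConfig()
    spec = model.spec
    if image.n_channels != spec.n_channels:
        raise PredictionError(
            f"image has {image.n_channels} channel(s) but the network expects "
            f"{spec.n_channels}")
    plan = plan_tiles(image.spatial_shape, spec, pcfg)
    norm = apply_normalization(image, stats)
    data = np.moveaxis(norm.data, 3, 0).astype(model.dtype)  # (c, z, y, x)
    padded = _reflect_pad(data, plan.pad)
    scores = np.zeros((spec.n_classes,) + plan.image_shape, dtype=model.dtype)
    for tile in plan.tiles:
        x = padded[(slice(None),) + tile.in_window]
        probs = model.forward(x[None], training=False)[0]
        scores[(slice(None),) + tile.out_placement] = \
            probs[(slice(None),) + tile.emit_crop]
    return np.moveaxis(scores, 0, 3)


def scores_to_labels(scores: np.ndarray) -> LabelMask:
    """Per-voxel argmax over the class axis; ties break to the lowest index."""
    scores = np.asarray(scores)
    n_classes = scores.shape[-1]
    return LabelMask(np.argmax(scores, axis=-1).astype(np.int64), n_classes)
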