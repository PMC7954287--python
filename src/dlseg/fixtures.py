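"""Deterministic synthetic image+mask generators for every pipeline stage.

Four geometry families mimic the *structure* (not the appearance) of common
microscopy segmentation tasks:

``membranes2d``
    Voronoi-like polygonal cells separated by dark ~2-voxel membranes
    (classes: background, membrane) — EM-style thin-structure segmentation.
``nuclei2d``
    Round-to-elliptical nuclei, a 2-voxel outer rim per nucleus and
    *interface* voxels where the rims of two adjacent nuclei meet (classes:
    background, nucleus, boundary, interface) — touching-object separation.
``blobs3d_iso``
    Random ellipsoids in an isotropic volume (classes: background, blob).
``blobs3d_aniso_2ch``
    Two-channel volume with ellipsoidal cells squashed in z according to a
    1:1:``z_aspect`` voxel aspect; channel 1 marks the cytoplasm, channel 2
    the nucleus subregion (classes: background, cytoplasm, nucleus).

Images are two- (or few-) level intensity functions of the noiseless
geometry plus Gaussian noise, so each fixture is separable by a small
network; instance maps are kept so derived classes (boundary, interface)
are computed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.segmentation import find_boundaries

from .dataset_prep import split_train_validation
from .image_io import ImageVolume, LabelMask, write_image_volume
import tifffile

KINDS = ("membranes2d", "nuclei2d", "blobs3d_iso", "blobs3d_aniso_2ch")
_KIND_CLASSES = {"membranes2d": 2, "nuclei2d": 4,
                 "blobs3d_iso": 2, "blobs3d_aniso_2ch": 3}
_KIND_DEFAULT_SIZE = {"membranes2d": (1, 128, 128),
                      "nuclei2d": (1, 128, 128),
                      "blobs3d_iso": (24, 64, 64),
                      "blobs3d_aniso_2ch": (24, 64, 64)}
_KIND_MIN_SIZE = {"membranes2d": (1, 32, 32),
                  "nuclei2d": (1, 64, 64),
                  "blobs3d_iso": (12, 32, 32),
                  "blobs3d_aniso_2ch": (12, 32, 32)}


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    kind: str
    n_items: int = 10
    size: Optional[Tuple[int, int, int]] = None   # (z, y, x)
    noise_sigma: float = 0.05
    seed: int = 0
    z_aspect: float = 2.0

    @property
    def n_classes(self) -> int:
        return _KIND_CLASSES[self.kind]

    def resolved_size(self) -> Tuple[int, int, int]:
        return tuple(self.size) if self.size else _KIND_DEFAULT_SIZE[self.kind]


def _check_spec(fs: FixtureSpec) -> Tuple[int, int, int]:
    if fs.kind not in KINDS:
        raise FixtureError(f"unknown fixture kind {fs.kind!r}; choose {KINDS}")
    if fs.n_items < 1:
        raise FixtureError("n_items must be >= 1")
    size = fs.resolved_size()
    mins = _KIND_MIN_SIZE[fs.kind]
    if any(s < m for s, m in zip(size, mins)):
        raise FixtureError(
            f"size {size} smaller than the minimal object footprint {mins} "
            f"for kind {fs.kind!r}")
    return size


def _noisy(levels: np.ndarray, sigma: float,
           rng: np.random.Generator) -> np.ndarray:
    img = levels.astype(np.float32)
    if sigma > 0:
        img = img + rng.normal(0.0, sigma, size=img.shape).astype(np.float32)
    return img


def membranes_image(size_yx: Tuple[int, int], noise_sigma: float,
                    rng: np.random.Generator
                    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One membranes2d item: (image (y,x), mask (y,x), cell instance map)."""
    Y, X = size_yx
    n_seeds = int(rng.integers(6, 13))
    seeds = np.stack([rng.uniform(0, Y, n_seeds), rng.uniform(0, X, n_seeds)],
                     axis=1)
    yy, xx = np.meshgrid(np.arange(Y), np.arange(X), indexing="ij")
    d2 = ((yy[..., None] - seeds[:, 0]) ** 2
          + (xx[..., None] - seeds[:, 1]) ** 2)
    cells = np.argmin(d2, axis=-1).astype(np.int32) + 1
    membrane = find_boundaries(cells, mode="thick")
    mask = membrane.astype(np.int64)
    levels = np.where(membrane, 0.25, 0.75)
    return _noisy(levels, noise_sigma, rng), mask, cells


def _ellipse(shape_yx, cy, cx, ry, rx, theta) -> np.ndarray:
    Y, X = shape_yx
    yy, xx = np.meshgrid(np.arange(Y) - cy, np.arange(X) - cx, indexing="ij")
    ct, st = np.cos(theta), np.sin(theta)
    u = yy * ct + xx * st
    v = -yy * st + xx * ct
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def nuclei_image(size_yx: Tuple[int, int], noise_sigma: float,
                 rng: np.random.Generator
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One nuclei2d item: (image, mask, instance map).

    Classes: 0 background, 1 nucleus interior, 2 boundary (2-voxel rim of a
    single nucleus), 3 interface (rim voxels claimed by >= 2 nuclei).  One
    touching doublet is always planted so the interface class is non-empty.
    """
    Y, X = size_yx
    instances: List[np.ndarray] = []
    occupied = np.zeros(size_yx, dtype=bool)

    def try_place(cy, cx, ry, rx, theta) -> bool:
        e = _ellipse(size_yx, cy, cx, ry, rx, theta)
        if not e.any() or (e & occupied).any():
            return False
        instances.append(e)
        occupied[e] = True
        return True

    # planted doublet: two circles with a 2-voxel gap -> rims must overlap
    r = int(rng.integers(7, 10))
    cy = float(rng.uniform(2.5 * r, Y - 2.5 * r))
    cx = float(rng.uniform(2.5 * r, X - 3.5 * r))
    try_place(cy, cx, r, r, 0.0)
    try_place(cy, cx + 2 * r + 2, r, r, 0.0)
    n_extra = int(rng.integers(2, 5))
    attempts = 0
    while n_extra > 0 and attempts < 50:
        attempts += 1
        ry = float(rng.uniform(6, 11))
        rx = float(rng.uniform(6, 11))
        if try_place(float(rng.uniform(ry, Y - ry)),
                     float(rng.uniform(rx, X - rx)),
                     ry, rx, float(rng.uniform(0, np.pi))):
            n_extra -= 1
    inst_map = np.zeros(size_yx, dtype=np.int32)
    rim_count = np.zeros(size_yx, dtype=np.int32)
    selem = ndimage.generate_binary_structure(2, 1)
    for i, e in enumerate(instances, start=1):
        inst_map[e] = i
        dil = ndimage.binary_dilation(e, selem, iterations=2)
        rim_count += (dil & ~e).astype(np.int32)
    interior = inst_map > 0
    mask = np.zeros(size_yx, dtype=np.int64)
    mask[interior] = 1
    mask[(rim_count == 1) & ~interior] = 2
    mask[(rim_count >= 2) & ~interior] = 3
    levels = np.choose(mask, [0.10, 0.85, 0.45, 0.65])
    return _noisy(levels, noise_sigma, rng), mask, inst_map


def _ellipsoid(shape_zyx, center, radii) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s) for s in shape_zyx), indexing="ij")
    acc = np.zeros(shape_zyx)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def blobs_volume(size_zyx: Tuple[int, int, int], noise_sigma: float,
                 rng: np.random.Generator, z_aspect: float = 1.0,
                 two_channel: bool = False
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """One 3D blob item: (image (z,y,x,c), mask (z,y,x)).

    With ``two_channel`` the blobs carry a nucleus-like inner ellipsoid:
    channel 1 = cytoplasm signal, channel 2 = nucleus signal, and the mask
    distinguishes cytoplasm (1) from nucleus (2).  ``z_aspect`` > 1 shrinks
    the z radius, emulating coarser physical z sampling.
    """
    Z, Y, X = size_zyx
    n_blobs = int(rng.integers(3, 7))
    blob = np.zeros(size_zyx, dtype=bool)
    inner = np.zeros(size_zyx, dtype=bool)
    placed = 0
    attempts = 0
    while placed < n_blobs and attempts < 60:
        attempts += 1
        ry = float(rng.uniform(7, 12))
        rx = float(rng.uniform(7, 12))
        rz = max(2.5, ry / z_aspect)
        if 2 * rz >= Z or 2 * ry >= Y or 2 * rx >= X:
            continue
        c = (float(rng.uniform(rz, Z - rz)), float(rng.uniform(ry, Y - ry)),
             float(rng.uniform(rx, X - rx)))
        e = _ellipsoid(size_zyx, c, (rz, ry, rx))
        blob |= e
        if two_channel:
            inner |= _ellipsoid(size_zyx, c,
                                (max(1.5, rz * 0.5), ry * 0.5, rx * 0.5))
        placed += 1
    if two_channel:
        mask = np.zeros(size_zyx, dtype=np.int64)
        mask[blob] = 1
        mask[inner] = 2
        ch1 = np.where(blob, 0.65, 0.10)
        ch2 = np.where(inner, 0.80, 0.05)
        img = np.stack([_noisy(ch1, noise_sigma, rng),
                        _noisy(ch2, noise_sigma, rng)], axis=-1)
    else:
        mask = blob.astype(np.int64)
        img = _noisy(np.where(blob, 0.75, 0.20), noise_sigma, rng)[..., None]
    return img.astype(np.float32), mask


def generate_fixture(fs: FixtureSpec) -> List[Tuple[ImageVolume, LabelMask]]:
    """Generate ``n_items`` deterministic (image, mask) pairs."""
    size = _check_spec(fs)
    rng = np.random.default_rng(np.random.SeedSequence([fs.seed, 7]))
    out = []
    for _ in range(fs.n_items):
        if fs.kind == "membranes2d":
            img, mask, _ = membranes_image(size[1:], fs.noise_sigma, rng)
            vol = ImageVolume(img[None, :, :, None])
            lm = LabelMask(mask[None], fs.n_classes)
        elif fs.kind == "nuclei2d":
            img, mask, _ = nuclei_image(size[1:], fs.noise_sigma, rng)
            vol = ImageVolume(img[None, :, :, None])
            lm = LabelMask(mask[None], fs.n_classes)
        elif fs.kind == "blobs3d_iso":
            img, mask = blobs_volume(size, fs.noise_sigma, rng)
            vol = ImageVolume(img)
            lm = LabelMask(mask, fs.n_classes)
        else:  # blobs3d_aniso_2ch
            img, mask = blobs_volume(size, fs.noise_sigma, rng,
                                     z_aspect=fs.z_aspect, two_channel=True)
            vol = ImageVolume(img, voxel_size=(fs.z_aspect, 1.0, 1.0))
            lm = LabelMask(mask, fs.n_classes)
        out.append((vol, lm))
    return out


def write_fixture_tree(dataset: List[Tuple[ImageVolume, LabelMask]],
                       root, fraction: float, seed: int) -> Path:
    """Write a dataset as the train/validation/predict directory layout."""
    root = Path(root)
    indexed = list(enumerate(dataset))
    split = split_train_validation(indexed, fraction, seed)
    for role, items in (("train", split.train_pairs),
                        ("validation", split.validation_pairs)):
        if not items and role == "validation":
            continue
        (root / role / "Images").mkdir(parents=True, exist_ok=True)
        (root / role / "Labels").mkdir(parents=True, exist_ok=True)
        for i, (vol, mask) in items:
            write_image_volume(vol, root / role / "Images" / f"img_{i:03d}.tif")
            m = mask.data.astype(np.uint8)
            tifffile.imwrite(root / role / "Labels" / f"img_{i:03d}.tif",
                             m[0] if m.shape[0] == 1 else m)
    (root / "predict" / "Images").mkdir(parents=True, exist_ok=True)
    for i, (vol, _mask) in indexed:
        write_image_volume(vol, root / "predict" / "Images" / f"img_{i:03d}.tif")
    return root
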