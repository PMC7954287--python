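"""Reading/writing images, stacks, masks and score maps; dataset indexing.

Axis convention: every volume is ``(z, y, x, c)`` with ``z == 1`` for 2D
images; label masks are ``(z, y, x)`` integer arrays with 0 = background.
All tile/crop coordinates in the package are 0-based half-open intervals.

Directory convention::

    <root>/<role>/Images/*.{png,tif,tiff}
    <root>/<role>/Labels/*        # same base filenames; absent for predict

Supported file formats are PNG and (multipage) TIFF; proprietary microscopy
containers are out of scope.  When a 3D TIFF array is read, a trailing axis
of length <= 4 is interpreted as channels, otherwise as z-pages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import tifffile

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


class ImageIOError(ValueError):
    pass


@dataclass
class ImageVolume:
    """n-dimensional intensity volume, axes (z, y, x, c), with voxel size."""

    data: np.ndarray
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ImageIOError(
                f"ImageVolume data must have axes (z, y, x, c), got shape "
                f"{self.data.shape}")
        if self.data.shape[3] < 1:
            raise ImageIOError("ImageVolume needs at least one channel")

    @property
    def spatial_shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]


@dataclass
class LabelMask:
    """Integer class-index mask, axes (z, y, x); values in [0, n_classes)."""

    data: np.ndarray
    n_classes: int

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ImageIOError(
                f"LabelMask data must have axes (z, y, x), got shape "
                f"{self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ImageIOError(
                f"LabelMask requires an integer dtype, got {self.data.dtype}")

    @property
    def spatial_shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class DatasetLayout:
    """Image/mask path pairs found under one dataset role directory."""

    pairs: List[Tuple[Path, Optional[Path]]]
    role: str


def _normalize_axes(arr: np.ndarray, path) -> np.ndarray:
    """Bring a raw decoded array to (z, y, x, c)."""
    if arr.ndim == 2:
        return arr[None, :, :, None]
    if arr.ndim == 3:
        if arr.shape[-1] <= 4:     # (y, x, c)
            return arr[None]
        return arr[:, :, :, None]  # (z, y, x)
    if arr.ndim == 4:
        return arr
    raise ImageIOError(f"{path}: cannot interpret array of shape {arr.shape}")


def read_image_volume(path) -> ImageVolume:
    """Read a PNG or single/multipage TIFF into (z, y, x, c) layout.

    PNGs become single z-slices; TIFF pages become z-slices in file order.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        arr = iio.imread(path)
    elif suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            if len(tf.pages) == 0:
                raise ImageIOError(f"{path}: TIFF has zero pages")
            if len(tf.series) > 1:
                shapes = sorted({p.shape for p in tf.pages})
                raise ImageIOError(
                    f"{path}: inconsistent page shapes {shapes}")
            arr = tf.series[0].asarray()
    else:
        raise ImageIOError(
            f"{path}: unsupported format {suffix!r} (use PNG or TIFF)")
    return ImageVolume(_normalize_axes(arr, path))


def read_label_mask(path, n_classes: int) -> LabelMask:
    """Read an integer-valued PNG/TIFF mask and verify its class range."""
    vol = read_image_volume(path)
    data = vol.data
    if data.shape[3] != 1:
        raise ImageIOError(
            f"{path}: label mask must be single-channel, got {data.shape[3]}")
    data = data[..., 0]
    if not np.issubdtype(data.dtype, np.integer):
        raise ImageIOError(
            f"{path}: label mask must have integer dtype, got {data.dtype}")
    hi = int(data.max()) if data.size else 0
    if hi >= n_classes:
        raise ImageIOError(
            f"{path}: max label {hi} >= n_classes {n_classes}")
    if data.size and int(data.min()) < 0:
        raise ImageIOError(f"{path}: negative label {int(data.min())}")
    return LabelMask(data.astype(np.int64), n_classes)


def write_image_volume(vol: ImageVolume, path) -> Path:
    """Write a volume as TIFF; squeeze trivial z/c axes for compactness."""
    path = Path(path)
    arr = vol.data
    if arr.shape[3] == 1:
        arr = arr[..., 0]
    if arr.shape[0] == 1:
        arr = arr[0]
    tifffile.imwrite(path, arr)
    return path


def write_outputs(scores: Optional["np.ndarray"], labels: LabelMask,
                  out_dir, basename: str) -> List[Path]:
    """Write predicted labels (uint8 TIFF) and score maps (float32 TIFF).

    ``scores`` is a (z, y, x, class) softmax map or ``None``.  Re-reading
    either file reproduces the arrays bit-exactly.
    """
    out_dir = Path(out_dir)
    if labels.n_classes > 255:
        raise ImageIOError(
            f"cannot write {labels.n_classes} classes to an 8-bit label file "
            "(> 255 classes)")
    if scores is not None and scores.shape[:3] != labels.spatial_shape:
        raise ImageIOError(
            f"scores shape {scores.shape[:3]} does not match labels "
            f"{labels.spatial_shape}")
    written = []
    labels_dir = out_dir / "Labels"
    labels_dir.mkdir(parents=True, exist_ok=True)
    lp = labels_dir / f"{basename}.tif"
    tifffile.imwrite(lp, labels.data.astype(np.uint8))
    written.append(lp)
    if scores is not None:
        scores_dir = out_dir / "Scores"
        scores_dir.mkdir(parents=True, exist_ok=True)
        sp = scores_dir / f"{basename}.tif"
        tifffile.imwrite(sp, np.asarray(scores, dtype=np.float32))
        written.append(sp)
    return written


def index_dataset(root, role: str) -> DatasetLayout:
    """Enumerate Images/ (and Labels/) under ``root`` in sorted order.

    Pairing is by identical base filename (stem); train/validation roles
    require a mask for every image, predict tolerates absent masks.
    """
    if role not in ("train", "validation", "predict"):
        raise ImageIOError(f"unknown dataset role {role!r}")
    root = Path(root)
    images_dir = root / "Images"
    if not images_dir.is_dir():
        raise ImageIOError(f"missing directory {images_dir}")
    images = sorted(p for p in images_dir.iterdir()
                    if p.suffix.lower() in IMAGE_SUFFIXES)
    if not images:
        raise ImageIOError(f"no images found in {images_dir}")
    labels_dir = root / "Labels"
    masks_by_stem = {}
    if labels_dir.is_dir():
        for p in sorted(labels_dir.iterdir()):
            if p.suffix.lower() in IMAGE_SUFFIXES:
                masks_by_stem[p.stem] = p
    pairs: List[Tuple[Path, Optional[Path]]] = []
    unpaired = []
    for img in images:
        mask = masks_by_stem.get(img.stem)
        if mask is None and role != "predict":
            unpaired.append(img.stem)
        pairs.append((img, mask))
    if unpaired:
        raise ImageIOError(
            f"{role} role requires a mask for every image; unpaired: "
            + ", ".join(unpaired))
    return DatasetLayout(pairs, role)


def load_pairs(layout: DatasetLayout, n_classes: int
               ) -> List[Tuple[ImageVolume, Optional[LabelMask]]]:
    """Load every (image, mask) pair of a layout into memory."""
    out = []
    for img_path, mask_path in layout.pairs:
        vol = read_image_volume(img_path)
        mask = read_label_mask(mask_path, n_classes) if mask_path else None
        if mask is not None and mask.spatial_shape != vol.spatial_shape:
            raise ImageIOError(
                f"{img_path}: mask shape {mask.spatial_shape} does not match "
                f"image {vol.spatial_shape}")
        out.append((vol, mask))
    return out
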