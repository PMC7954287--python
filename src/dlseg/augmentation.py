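"""Stochastic geometric augmentation of image/mask patch pairs.

The augmenter draws reflections (per axis), one in-plane rotation angle, an
isotropic scale and a shear angle; 3D rotations are restricted to the z axis
(in-plane), which respects anisotropic z spacing, while reflections may flip
z.  Images are resampled with linear interpolation, masks with
nearest-neighbour, so class indices always remain valid; out-of-bounds
samples are filled by reflection so no artificial background rim appears.

Elastic distortion follows the classic construction: per-axis uniform random
displacement fields in [-1, 1], smoothed by a Gaussian of scale ``sigma``
and scaled by ``alpha`` (voxels), applied identically to image and mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .config import AugmentationParams
from .image_io import ImageVolume, LabelMask


@dataclass
class GeometricTransform:
    """One sampled augmentation: flips + in-plane affine about the center."""

    flip_z: bool
    flip_y: bool
    flip_x: bool
    angle_deg: float
    scale: float
    shear_deg: float
    dims: int

    @property
    def is_identity(self) -> bool:
        return (not (self.flip_z or self.flip_y or self.flip_x)
                and self.angle_deg == 0.0 and self.scale == 1.0
                and self.shear_deg == 0.0)

    @property
    def affine_is_identity(self) -> bool:
        return (self.angle_deg == 0.0 and self.scale == 1.0
                and self.shear_deg == 0.0)


def sample_transform(params: AugmentationParams, dims: int,
                     rng: np.random.Generator) -> GeometricTransform:
    """Draw one transform; draw order is fixed (flips, angle, scale, shear)."""
    if dims not in (2, 3):
        raise ValueError(f"dims must be 2 or 3, got {dims}")
    flip_z = bool(rng.random() < params.p_reflect) if dims == 3 else False
    flip_y = bool(rng.random() < params.p_reflect)
    flip_x = bool(rng.random() < params.p_reflect)
    angle = float(rng.uniform(-params.rotation_range, params.rotation_range))
    scale = float(rng.uniform(params.scale_range[0], params.scale_range[1]))
    shear = float(rng.uniform(-params.shear_range, params.shear_range))
    return GeometricTransform(flip_z, flip_y, flip_x, angle, scale, shear, dims)


def _inplane_matrix(t: GeometricTransform) -> np.ndarray:
    """Forward (y, x) affine: rotation . shear . isotropic scale."""
    th = np.deg2rad(t.angle_deg)
    sh = np.deg2rad(t.shear_deg)
    rot = np.array([[np.cos(th), -np.sin(th)],
                    [np.sin(th), np.cos(th)]])
    shear = np.array([[1.0, np.tan(sh)],
                      [0.0, 1.0]])
    return rot @ shear @ (t.scale * np.eye(2))


def _apply_inplane(arr: np.ndarray, t: GeometricTransform, order: int
                   ) -> np.ndarray:
    """Apply the continuous part slice-wise on (z, y, x[, ...])-shaped data."""
    A = _inplane_matrix(t)
    Ainv = np.linalg.inv(A)
    center = (np.array(arr.shape[1:3]) - 1) / 2.0
    offset = center - Ainv @ center
    out = np.empty_like(arr)
    for z in range(arr.shape[0]):
        out[z] = ndimage.affine_transform(
            arr[z], Ainv, offset=offset, order=order, mode="reflect",
            output=arr.dtype)
    return out


def apply_transform(patch: ImageVolume, mask: LabelMask,
                    t: GeometricTransform) -> Tuple[ImageVolume, LabelMask]:
    """Apply the identical spatial map to an image and its mask.

    Output shape equals input shape; the affine acts about the patch center.
    """
    img = patch.data
    msk = mask.data
    if msk.shape != img.shape[:3]:
        raise ValueError(
            f"patch {img.shape[:3]} and mask {msk.shape} are not congruent")
    flips = tuple(ax for ax, f in enumerate((t.flip_z, t.flip_y, t.flip_x)) if f)
    if flips:
        img = np.flip(img, axis=flips)
        msk = np.flip(msk, axis=flips)
    if t.affine_is_identity:
        return (ImageVolume(img.copy(), patch.voxel_size),
                LabelMask(msk.copy(), mask.n_classes))
    out_img = np.empty_like(img)
    for c in range(img.shape[3]):
        out_img[..., c] = _apply_inplane(np.ascontiguousarray(img[..., c]), t, order=1)
    out_msk = _apply_inplane(np.ascontiguousarray(msk), t, order=0)
    return (ImageVolume(out_img, patch.voxel_size),
            LabelMask(out_msk, mask.n_classes))


def augment_pair(params: AugmentationParams, patch: ImageVolume,
                 mask: LabelMask, dims: int, rng: np.random.Generator
                 ) -> Tuple[ImageVolume, LabelMask]:
    """Training-loop entry point: draw and apply one transform if enabled."""
    enabled = params.enabled_2d if dims == 2 else params.enabled_3d
    if not enabled:
        return patch, mask
    t = sample_transform(params, dims, rng)
    return apply_transform(patch, mask, t)


def elastic_distortion(patch: ImageVolume, mask: LabelMask, alpha: float,
                       sigma: float, rng: np.random.Generator
                       ) -> Tuple[ImageVolume, LabelMask]:
    """Smoothed random displacement field applied to image and mask.

    ``alpha`` scales the displacement in voxels (0 = identity); ``sigma`` is
    the Gaussian smoothing scale of the field.  2D patches (z = 1) are
    displaced in-plane only; 3D patches along all three axes.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    img = patch.data
    msk = mask.data
    if alpha == 0:
        return (ImageVolume(img.copy(), patch.voxel_size),
                LabelMask(msk.copy(), mask.n_classes))
    spatial = img.shape[:3]
    axes = (1, 2) if spatial[0] == 1 else (0, 1, 2)
    coords = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in spatial),
                         indexing="ij")
    coords = [c.copy() for c in coords]
    for ax in axes:
        field = rng.uniform(-1.0, 1.0, size=spatial)
        if spatial[0] == 1:
            field[0] = ndimage.gaussian_filter(field[0], sigma)
        else:
            field = ndimage.gaussian_filter(field, sigma)
        coords[ax] += alpha * field
    out_img = np.empty_like(img)
    for c in range(img.shape[3]):
        out_img[..., c] = ndimage.map_coordinates(
            img[..., c], coords, order=1, mode="reflect")
    out_msk = ndimage.map_coordinates(msk, coords, order=0, mode="reflect")
    return (ImageVolume(out_img, patch.voxel_size),
            LabelMask(out_msk, mask.n_classes))
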