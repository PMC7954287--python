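"""Typed configuration for the segmentation pipeline.

Three dataclasses describe a run: :class:`ArchitectureSpec` (which network to
build), :class:`TrainingConfig` (how to train it, including
:class:`AugmentationParams`) and :class:`PredictionConfig` (how to tile
whole images at inference time).  Configs are read from a flat YAML mapping
with an explicitly enumerated key set; unknown keys are hard errors so that a
typo can never silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml

FAMILIES = ("unet2d", "unet3d", "unet3d_aniso", "segnet2d")
FAMILIES_2D = ("unet2d", "segnet2d")
PADDINGS = ("same", "valid")
NORMALIZATION_MODES = ("none", "zero_center", "zscore", "rescale01")
CLASS_WEIGHTINGS = ("none", "inverse_frequency")


class ConfigError(ValueError):
    """Raised for any invalid, unknown or inconsistent configuration value."""


@dataclass
class ArchitectureSpec:
    """Complete description of one encoder-decoder segmentation network.

    ``patch_size`` follows the (height, width, depth, channels) convention;
    2D families use depth 1.  ``depth_levels`` counts pooling/downsampling
    steps, so depth 2 means two encoder levels plus a bridge.
    """

    family: str
    patch_size: Tuple[int, int, int, int]
    n_classes: int
    depth_levels: int = 2
    n_first_filters: int = 16
    padding: str = "same"
    batch_norm: bool = True

    @property
    def is_2d(self) -> bool:
        return self.family in FAMILIES_2D

    @property
    def spatial_shape(self) -> Tuple[int, int, int]:
        """Patch spatial extent in (z, y, x) axis order."""
        h, w, d, _c = self.patch_size
        return (d, h, w)

    @property
    def n_channels(self) -> int:
        return self.patch_size[3]


@dataclass
class AugmentationParams:
    """Geometric augmentation ranges for image/mask patch pairs.

    ``elastic_alpha``/``elastic_sigma`` parameterize the elastic-distortion
    filter (displacement magnitude in voxels, Gaussian smoothing scale);
    elastic distortion is a dataset-expansion step, not part of the
    per-iteration augmenter.
    """

    p_reflect: float = 0.5
    rotation_range: float = 90.0
    scale_range: Tuple[float, float] = (0.8, 1.2)
    shear_range: float = 10.0
    enabled_2d: bool = True
    enabled_3d: bool = True
    elastic_alpha: float = 0.0
    elastic_sigma: float = 4.0


@dataclass
class TrainingConfig:
    validation_fraction: float = 0.1
    max_epochs: int = 50
    batch_size: int = 4
    learning_rate: float = 1e-3
    augmentation: AugmentationParams = field(default_factory=AugmentationParams)
    normalization_mode: str = "zscore"
    checkpoint_every_n_iterations: int = 0
    seed: int = 0
    class_weighting: str = "none"
    patches_per_image: int = 16


@dataclass
class PredictionConfig:
    """Tiled-inference settings.

    ``overlap_voxels`` is the per-axis (z, y, x) overlap between adjacent
    input tiles in same-padding mode; ``None`` selects the default of 25% of
    the patch per axis.  In valid-padding mode the overlap is not a free
    parameter: it always equals the network's total per-axis shrink.
    """

    overlap_voxels: Optional[Tuple[int, int, int]] = None
    output_scoremaps: bool = True


def _check(cond: bool, errors: list, msg: str) -> None:
    if not cond:
        errors.append(msg)


def validate_architecture_spec(spec: ArchitectureSpec) -> ArchitectureSpec:
    """Validate every architecture invariant; raise naming all violations.

    Checks family/padding enums, patch-dimensionality rules (2D families
    need depth 1, 3D families depth >= 2, the anisotropic variant needs at
    least one 3D level) and finally runs the full layer-by-layer shape
    propagation so that no spec with an ill-posed geometry ever reaches the
    network builder.
    """
    errors: list[str] = []
    _check(spec.family in FAMILIES, errors,
           f"invalid family {spec.family!r}; choose one of {FAMILIES}")
    _check(spec.padding in PADDINGS, errors,
           f"invalid padding {spec.padding!r}; choose one of {PADDINGS}")
    ps = tuple(spec.patch_size)
    _check(len(ps) == 4 and all(isinstance(v, int) and v >= 1 for v in ps),
           errors, f"patch_size must be 4 positive integers (h, w, d, c), got {ps!r}")
    _check(spec.n_classes >= 2, errors,
           f"n_classes must be >= 2 (including background), got {spec.n_classes}")
    _check(spec.depth_levels >= 1, errors,
           f"depth_levels must be >= 1, got {spec.depth_levels}")
    _check(spec.n_first_filters >= 1, errors,
           f"n_first_filters must be >= 1, got {spec.n_first_filters}")
    if not errors:
        h, w, d, _c = ps
        if spec.family in FAMILIES_2D:
            _check(d == 1, errors,
                   f"2D family {spec.family!r} requires patch depth 1, got {d}")
        else:
            _check(d >= 2, errors,
                   f"3D family {spec.family!r} requires patch depth >= 2, got {d}")
        if spec.family == "unet3d_aniso":
            _check(spec.depth_levels >= 2, errors,
                   "unet3d_aniso requires depth_levels >= 2 "
                   "(level 1 is 2D; at least one 3D level must exist)")
        if spec.family == "segnet2d":
            _check(spec.padding == "same", errors,
                   "segnet2d supports 'same' padding only")
    if not errors:
        # Full geometric feasibility: propagate shapes through the layer plan.
        from . import architectures  # deferred: architectures imports this module

        try:
            architectures.output_shape(spec, _validated=True)
        except architectures.ShapeError as exc:
            errors.append(str(exc))
    if errors:
        raise ConfigError("invalid ArchitectureSpec: " + "; ".join(errors))
    return spec


def _validate_training(cfg: TrainingConfig) -> TrainingConfig:
    errors: list[str] = []
    _check(0.0 <= cfg.validation_fraction <= 0.5, errors,
           f"validation_fraction must be in [0, 0.5], got {cfg.validation_fraction}")
    _check(cfg.max_epochs >= 0, errors, "max_epochs must be >= 0")
    _check(cfg.batch_size >= 1, errors, "batch_size must be >= 1")
    _check(cfg.learning_rate > 0 or cfg.learning_rate == 0, errors,
           "learning_rate must be >= 0")
    _check(cfg.learning_rate >= 0, errors, "learning_rate must be >= 0")
    _check(cfg.normalization_mode in NORMALIZATION_MODES, errors,
           f"invalid normalization_mode {cfg.normalization_mode!r}")
    _check(cfg.checkpoint_every_n_iterations >= 0, errors,
           "checkpoint_every_n_iterations must be >= 0 (0 = only at end)")
    _check(cfg.class_weighting in CLASS_WEIGHTINGS, errors,
           f"invalid class_weighting {cfg.class_weighting!r}")
    _check(cfg.patches_per_image >= 1, errors, "patches_per_image must be >= 1")
    a = cfg.augmentation
    _check(0.0 <= a.p_reflect <= 1.0, errors, "p_reflect must be in [0, 1]")
    _check(a.rotation_range >= 0, errors, "rotation_range must be >= 0")
    _check(len(a.scale_range) == 2 and a.scale_range[0] > 0
           and a.scale_range[1] >= a.scale_range[0], errors,
           f"scale_range must be (min, max) with min > 0, got {a.scale_range!r}")
    _check(a.shear_range >= 0, errors, "shear_range must be >= 0")
    _check(a.elastic_alpha >= 0, errors, "elastic_alpha must be >= 0")
    _check(a.elastic_sigma > 0, errors, "elastic_sigma must be > 0")
    if errors:
        raise ConfigError("invalid TrainingConfig: " + "; ".join(errors))
    return cfg


def _validate_prediction(cfg: PredictionConfig) -> PredictionConfig:
    if cfg.overlap_voxels is not None:
        ov = tuple(cfg.overlap_voxels)
        if len(ov) != 3 or any((not isinstance(v, int)) or v < 0 for v in ov):
            raise ConfigError(
                f"overlap_voxels must be 3 non-negative integers (z, y, x), got {ov!r}")
    return cfg


# ---------------------------------------------------------------------------
# Flat YAML key set
# ---------------------------------------------------------------------------

_ARCH_KEYS = ("family", "patch_size", "n_classes", "depth_levels",
              "n_first_filters", "padding", "batch_norm")
_TRAIN_KEYS = ("validation_fraction", "max_epochs", "batch_size",
               "learning_rate", "normalization_mode",
               "checkpoint_every_n_iterations", "seed", "class_weighting",
               "patches_per_image")
_AUG_KEYS = ("p_reflect", "rotation_range", "scale_range", "shear_range",
             "enabled_2d", "enabled_3d", "elastic_alpha", "elastic_sigma")
_PRED_KEYS = ("overlap_voxels", "output_scoremaps")
_REQUIRED_KEYS = ("family", "patch_size", "n_classes")
ALL_KEYS = _ARCH_KEYS + _TRAIN_KEYS + _AUG_KEYS + _PRED_KEYS


def _as_int_tuple(value, n, key) -> tuple:
    if not isinstance(value, (list, tuple)) or len(value) != n:
        raise ConfigError(f"key {key!r} must be a list of {n} values, got {value!r}")
    return tuple(int(v) for v in value)


def load_config(path) -> Tuple[ArchitectureSpec, TrainingConfig, PredictionConfig]:
    """Load and validate the three pipeline configs from a flat YAML file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse YAML config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> Tuple[ArchitectureSpec, TrainingConfig, PredictionConfig]:
    unknown = sorted(set(raw) - set(ALL_KEYS))
    if unknown:
        raise ConfigError("unknown config key(s): " + ", ".join(repr(k) for k in unknown))
    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise ConfigError("missing required config key(s): " + ", ".join(missing))

    arch_kwargs = {k: raw[k] for k in _ARCH_KEYS if k in raw}
    arch_kwargs["patch_size"] = _as_int_tuple(arch_kwargs["patch_size"], 4, "patch_size")
    spec = ArchitectureSpec(**arch_kwargs)

    aug_kwargs = {k: raw[k] for k in _AUG_KEYS if k in raw}
    if "scale_range" in aug_kwargs:
        sr = aug_kwargs["scale_range"]
        if not isinstance(sr, (list, tuple)) or len(sr) != 2:
            raise ConfigError(f"scale_range must be [min, max], got {sr!r}")
        aug_kwargs["scale_range"] = (float(sr[0]), float(sr[1]))
    train_kwargs = {k: raw[k] for k in _TRAIN_KEYS if k in raw}
    tcfg = TrainingConfig(augmentation=AugmentationParams(**aug_kwargs), **train_kwargs)

    pred_kwargs = {k: raw[k] for k in _PRED_KEYS if k in raw}
    if pred_kwargs.get("overlap_voxels") is not None:
        pred_kwargs["overlap_voxels"] = _as_int_tuple(
            pred_kwargs["overlap_voxels"], 3, "overlap_voxels")
    pcfg = PredictionConfig(**pred_kwargs)

    validate_architecture_spec(spec)
    _validate_training(tcfg)
    _validate_prediction(pcfg)
    return spec, tcfg, pcfg


def config_to_dict(spec: ArchitectureSpec, tcfg: TrainingConfig,
                   pcfg: PredictionConfig) -> dict:
    """Normalized flat dict such that load(dump(x)) is a fixed point."""
    out: dict = {}
    for k in _ARCH_KEYS:
        out[k] = getattr(spec, k)
    out["patch_size"] = [int(v) for v in spec.patch_size]
    for k in _TRAIN_KEYS:
        out[k] = getattr(tcfg, k)
    for k in _AUG_KEYS:
        out[k] = getattr(tcfg.augmentation, k)
    out["scale_range"] = [float(v) for v in tcfg.augmentation.scale_range]
    for k in _PRED_KEYS:
        out[k] = getattr(pcfg, k)
    if pcfg.overlap_voxels is not None:
        out["overlap_voxels"] = [int(v) for v in pcfg.overlap_voxels]
    return out


def dump_config(spec: ArchitectureSpec, tcfg: TrainingConfig,
                pcfg: PredictionConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(spec, tcfg, pcfg), sort_keys=True))
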