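"""Patch-based training with validation monitoring and exact resumption.

Loss is voxelwise softmax cross-entropy (optionally class-weighted);
optimizer is Adam.  One epoch samples ``patches_per_image`` random patches
from every training item, augments them, shuffles and iterates minibatches.

Determinism contract: all randomness (weight init, patch sampling,
augmentation, shuffling) flows through generators seeded from the training
config, and the sampler/augmenter share a single stream whose bit-generator
state is serialized into every checkpoint.  Resuming a checkpoint therefore
reproduces the uninterrupted run bit-for-bit: a mid-epoch checkpoint stores
the stream state at the start of its epoch plus the number of minibatches
already consumed, and the resumed run regenerates the epoch's patch stream
and skips the consumed prefix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .architectures import NetworkModel, build_network
from .augmentation import augment_pair
from .config import ArchitectureSpec, PredictionConfig, TrainingConfig, config_from_dict, config_to_dict
from .dataset_prep import (NormalizationStats, SplitResult, apply_normalization,
                           compute_normalization, sample_patches,
                           stats_from_dict, stats_to_dict)
from .evaluation import confusion_matrix, segmentation_metrics
from .image_io import ImageVolume, LabelMask


class TrainingError(ValueError):
    pass


@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)   # per iteration
    val_loss: List[float] = field(default_factory=list)     # per epoch
    val_jaccard: List[np.ndarray] = field(default_factory=list)  # per epoch, per class
    epochs_completed: int = 0
    iterations_completed: int = 0


@dataclass
class CheckpointRecord:
    """Everything needed to continue training exactly where it stopped."""

    state: Dict[str, np.ndarray]          # model weights + buffers
    optimizer_state: dict
    rng_state: dict                        # sampling/augmentation stream, current
    epoch_start_rng_state: dict            # stream state at start of this epoch
    epoch: int                             # epochs fully completed
    iteration: int                         # global iterations completed
    batches_into_epoch: int                # 0 if at an epoch boundary
    history: TrainingHistory
    spec: ArchitectureSpec
    cfg: TrainingConfig
    stats: NormalizationStats
    init_seed: int


def compute_loss(scores: np.ndarray, target, class_weights=None) -> float:
    """Mean (optionally class-weighted) cross-entropy from softmax scores.

    ``scores`` is (z, y, x, class) or any (..., class) array; ``target`` the
    matching integer mask.  Zero iff the prediction is the one-hot truth.
    """
    scores = np.asarray(scores, dtype=np.float64)
    t = np.asarray(target.data if isinstance(target, LabelMask) else target)
    if scores.shape[:-1] != t.shape:
        raise TrainingError(
            f"shape mismatch: scores {scores.shape[:-1]} vs target {t.shape}")
    n_cls = scores.shape[-1]
    p_true = np.take_along_axis(scores, t[..., None], axis=-1)[..., 0]
    logp = np.log(np.clip(p_true, 1e-12, None))
    if class_weights is None:
        return float(-logp.mean())
    w = np.asarray(class_weights, dtype=np.float64)
    if w.shape != (n_cls,):
        raise TrainingError(
            f"class_weights length {w.size} != n_classes {n_cls}")
    w_vox = w[t]
    denom = w_vox.sum()
    if denom == 0:
        return 0.0
    return float(-(w_vox * logp).sum() / denom)


def inverse_frequency_weights(pairs: Sequence[Tuple[ImageVolume, LabelMask]],
                              n_classes: int) -> np.ndarray:
    """w_c proportional to 1/frequency over the training masks (absent -> 0)."""
    counts = np.zeros(n_classes, dtype=np.float64)
    for _, mask in pairs:
        counts += np.bincount(mask.data.ravel(), minlength=n_classes)[:n_classes]
    present = counts > 0
    w = np.zeros(n_classes)
    w[present] = counts[present].sum() / (present.sum() * counts[present])
    return w


def _rng_state(rng: np.random.Generator) -> dict:
    return rng.bit_generator.state


def _make_rng(state: Optional[dict], seed_seq) -> np.random.Generator:
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    if state is not None:
        rng.bit_generator.state = state
    return rng


def validate_model(model: NetworkModel,
                   validation_pairs: Sequence[Tuple[ImageVolume, LabelMask]],
                   cfg: TrainingConfig, stats: NormalizationStats,
                   class_weights=None) -> dict:
    """Whole-image tiled prediction on the validation set, scored per class."""
    from .prediction import predict_tiled, scores_to_labels

    if not validation_pairs:
        raise TrainingError("validation set is empty")
    n_classes = model.spec.n_classes
    cm_total = np.zeros((n_classes, n_classes), dtype=np.int64)
    losses = []
    for vol, mask in validation_pairs:
        scores = predict_tiled(model, vol, stats, PredictionConfig())
        pred = scores_to_labels(scores)
        cm_total += confusion_matrix(pred, mask, n_classes).counts
        losses.append(compute_loss(scores, mask, class_weights))
    from .evaluation import ConfusionMatrix
    metrics = segmentation_metrics(ConfusionMatrix(cm_total))
    metrics["loss"] = float(np.mean(losses))
    return metrics


def _epoch_batches(train_pairs, spec: ArchitectureSpec, cfg: TrainingConfig,
                   rng: np.random.Generator):
    """Deterministically regenerate one epoch's shuffled minibatch list."""
    dims = 2 if spec.is_2d else 3
    patches = []
    for vol, mask in train_pairs:
        for patch, mpatch in sample_patches((vol, mask), spec,
                                            cfg.patches_per_image, rng):
            pv = ImageVolume(np.moveaxis(patch, 0, 3))
            pm = LabelMask(mpatch, spec.n_classes)
            pv, pm = augment_pair(cfg.augmentation, pv, pm, dims, rng)
            patches.append((np.moveaxis(pv.data, 3, 0), pm.data))
        # sample_patches consumed `patches_per_image` draws from rng
    order = rng.permutation(len(patches))
    batches = []
    for start in range(0, len(order), cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        xb = np.stack([patches[i][0] for i in idx]).astype(np.float32)
        tb = np.stack([patches[i][1] for i in idx]).astype(np.int64)
        batches.append((xb, tb))
    return batches


def _crop_target(target: np.ndarray, out_spatial) -> np.ndarray:
    """Center-crop targets to the network output (valid-padding training)."""
    slices = [slice(None)]
    for dim, out in zip(target.shape[1:], out_spatial):
        off = (dim - out) // 2
        slices.append(slice(off, off + out))
    return target[tuple(slices)]


def _run_epochs(model: NetworkModel, split: SplitResult, cfg: TrainingConfig,
                stats: NormalizationStats, class_weights,
                rng: np.random.Generator, opt: nn.Adam,
                history: TrainingHistory, start_epoch: int, end_epoch: int,
                skip_batches: int, init_seed: int,
                checkpoint_dir: Optional[Path] = None
                ) -> List[CheckpointRecord]:
    from .architectures import output_shape

    spec = model.spec
    out_spatial = output_shape(spec)
    train_pairs = [(apply_normalization(v, stats), m)
                   for v, m in split.train_pairs]
    val_pairs = [(v, m) for v, m in split.validation_pairs]
    checkpoints: List[CheckpointRecord] = []

    def snapshot(epoch_start_state, epoch, batches_into_epoch):
        rec = CheckpointRecord(
            state=model.state_dict(),
            optimizer_state=opt.state_dict(),
            rng_state=_rng_state(rng),
            epoch_start_rng_state=epoch_start_state,
            epoch=epoch,
            iteration=history.iterations_completed,
            batches_into_epoch=batches_into_epoch,
            history=TrainingHistory(list(history.train_loss),
                                    list(history.val_loss),
                                    [j.copy() for j in history.val_jaccard],
                                    history.epochs_completed,
                                    history.iterations_completed),
            spec=spec, cfg=cfg, stats=stats, init_seed=init_seed)
        checkpoints.append(rec)
        if checkpoint_dir is not None:
            save_checkpoint(rec, Path(checkpoint_dir) /
                            f"checkpoint_iter{rec.iteration:06d}")
        return rec

    for epoch in range(start_epoch, end_epoch):
        epoch_start_state = _rng_state(rng)
        batches = _epoch_batches(train_pairs, spec, cfg, rng)
        for bi, (xb, tb) in enumerate(batches):
            if epoch == start_epoch and bi < skip_batches:
                continue
            model.forward(xb, training=True)
            tb_c = _crop_target(tb, out_spatial)
            loss, dlogits = nn.softmax_cross_entropy(
                model.last_logits, tb_c, class_weights)
            model.backward(dlogits)
            opt.step(model.parameters())
            history.train_loss.append(loss)
            history.iterations_completed += 1
            if (cfg.checkpoint_every_n_iterations
                    and history.iterations_completed
                    % cfg.checkpoint_every_n_iterations == 0):
                snapshot(epoch_start_state, epoch, bi + 1)
        history.epochs_completed = epoch + 1
        if val_pairs:
            vm = validate_model(model, val_pairs, cfg, stats, class_weights)
            history.val_loss.append(vm["loss"])
            history.val_jaccard.append(np.asarray(vm["jaccard"]))
    # final checkpoint at the end of training, always
    snapshot(_rng_state(rng), end_epoch, 0)
    return checkpoints


def train_model(model: NetworkModel, split: SplitResult, cfg: TrainingConfig,
                checkpoint_dir=None
                ) -> Tuple[NetworkModel, TrainingHistory, List[CheckpointRecord]]:
    """Train a freshly built network on the split's training pairs."""
    if not split.train_pairs:
        raise TrainingError("training set is empty")
    spec = model.spec
    stats = compute_normalization(split.train_pairs, cfg.normalization_mode)
    class_weights = None
    if cfg.class_weighting == "inverse_frequency":
        class_weights = inverse_frequency_weights(split.train_pairs,
                                                  spec.n_classes)
    rng = _make_rng(None, np.random.SeedSequence([cfg.seed, 1]))
    opt = nn.Adam(cfg.learning_rate)
    history = TrainingHistory()
    checkpoints = _run_epochs(model, split, cfg, stats, class_weights, rng,
                              opt, history, 0, cfg.max_epochs, 0, cfg.seed,
                              checkpoint_dir)
    model.norm_stats = stats
    return model, history, checkpoints


def resume_training(checkpoint: CheckpointRecord, split: SplitResult,
                    additional_epochs: int, checkpoint_dir=None
                    ) -> Tuple[NetworkModel, TrainingHistory, List[CheckpointRecord]]:
    """Continue training from a checkpoint, bit-for-bit equal to an
    uninterrupted run with the same seed."""
    spec = checkpoint.spec
    cfg = checkpoint.cfg
    model = build_network(spec, seed=checkpoint.init_seed)
    model.load_state_dict(checkpoint.state)
    opt = nn.Adam(cfg.learning_rate)
    opt.load_state_dict(checkpoint.optimizer_state)
    history = TrainingHistory(list(checkpoint.history.train_loss),
                              list(checkpoint.history.val_loss),
                              [j.copy() for j in checkpoint.history.val_jaccard],
                              checkpoint.history.epochs_completed,
                              checkpoint.history.iterations_completed)
    class_weights = None
    if cfg.class_weighting == "inverse_frequency":
        class_weights = inverse_frequency_weights(split.train_pairs,
                                                  spec.n_classes)
    stats = checkpoint.stats
    model.norm_stats = stats
    if additional_epochs == 0:
        return model, history, []
    start_epoch = checkpoint.epoch
    end_epoch = checkpoint.epoch + additional_epochs
    skip = checkpoint.batches_into_epoch
    if skip:
        # mid-epoch: replay the epoch's patch stream, skip consumed batches
        # (the partially-done epoch counts as the first additional epoch)
        rng = _make_rng(checkpoint.epoch_start_rng_state,
                        np.random.SeedSequence([cfg.seed, 1]))
    else:
        rng = _make_rng(checkpoint.rng_state,
                        np.random.SeedSequence([cfg.seed, 1]))
    checkpoints = _run_epochs(model, split, cfg, stats, class_weights, rng,
                              opt, history, start_epoch, end_epoch, skip,
                              checkpoint.init_seed, checkpoint_dir)
    model.norm_stats = stats
    return model, history, checkpoints


# ---------------------------------------------------------------------------
# Checkpoint serialization: one .npz (arrays) + one .json sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(rec: CheckpointRecord, prefix) -> Tuple[Path, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"state/{k}": v for k, v in rec.state.items()}
    arrays.update({f"adam_m/{k}": v for k, v in rec.optimizer_state["m"].items()})
    arrays.update({f"adam_v/{k}": v for k, v in rec.optimizer_state["v"].items()})
    arrays["val_jaccard"] = (np.stack(rec.history.val_jaccard)
                             if rec.history.val_jaccard
                             else np.zeros((0, rec.spec.n_classes)))
    arrays["train_loss"] = np.asarray(rec.history.train_loss)
    arrays["val_loss"] = np.asarray(rec.history.val_loss)
    np.savez(str(prefix) + ".npz", **arrays)
    meta = {
        "config": config_to_dict(rec.spec, rec.cfg, PredictionConfig()),
        "stats": stats_to_dict(rec.stats),
        "rng_state": _jsonable(rec.rng_state),
        "epoch_start_rng_state": _jsonable(rec.epoch_start_rng_state),
        "adam_t": rec.optimizer_state["t"],
        "epoch": rec.epoch,
        "iteration": rec.iteration,
        "batches_into_epoch": rec.batches_into_epoch,
        "epochs_completed": rec.history.epochs_completed,
        "init_seed": rec.init_seed,
    }
    Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=1))
    return Path(str(prefix) + ".npz"), Path(str(prefix) + ".json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_checkpoint(prefix) -> CheckpointRecord:
    prefix = Path(prefix)
    with np.load(str(prefix) + ".npz") as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(Path(str(prefix) + ".json").read_text())
    spec, cfg, _ = config_from_dict(meta["config"])
    state = {k[len("state/"):]: v for k, v in arrays.items()
             if k.startswith("state/")}
    opt_state = {
        "t": meta["adam_t"],
        "m": {k[len("adam_m/"):]: v for k, v in arrays.items()
              if k.startswith("adam_m/")},
        "v": {k[len("adam_v/"):]: v for k, v in arrays.items()
              if k.startswith("adam_v/")},
    }
    history = TrainingHistory(
        arrays["train_loss"].tolist(), arrays["val_loss"].tolist(),
        [row for row in arrays["val_jaccard"]],
        meta["epochs_completed"], meta["iteration"])
    return CheckpointRecord(
        state=state, optimizer_state=opt_state,
        rng_state=meta["rng_state"],
        epoch_start_rng_state=meta["epoch_start_rng_state"],
        epoch=meta["epoch"], iteration=meta["iteration"],
        batches_into_epoch=meta["batches_into_epoch"],
        history=history, spec=spec, cfg=cfg,
        stats=stats_from_dict(meta["stats"]), init_seed=meta["init_seed"])
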