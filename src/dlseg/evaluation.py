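"""Quantitative comparison against ground truth and network inspection.

Per-class overlap metrics from an exact confusion matrix:

    J  = TP / (TP + FP + FN)          (Jaccard similarity coefficient)
    F1 = 2 TP / (2 TP + FP + FN)      (= Dice; F1 = 2J / (1 + J))

A class absent from both prediction and truth reports every metric as 1 by
convention, so unweighted per-class means remain defined on sparse data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .architectures import NetworkModel, shape_trace
from .image_io import ImageVolume, LabelMask


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """counts[i, j] = number of voxels of true class i predicted as j."""

    counts: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]


def confusion_matrix(pred: LabelMask, truth: LabelMask,
                     n_classes: int) -> ConfusionMatrix:
    p = np.asarray(pred.data if isinstance(pred, LabelMask) else pred)
    t = np.asarray(truth.data if isinstance(truth, LabelMask) else truth)
    if p.shape != t.shape:
        raise EvaluationError(
            f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    for name, arr in (("pred", p), ("truth", t)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise EvaluationError(
                f"{name} labels out of range [0, {n_classes}): "
                f"found [{arr.min()}, {arr.max()}]")
    flat = t.ravel().astype(np.int64) * n_classes + p.ravel().astype(np.int64)
    counts = np.bincount(flat, minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes))


def segmentation_metrics(cm: ConfusionMatrix) -> Dict[str, object]:
    """Per-class jaccard/f1/precision/recall plus unweighted means."""
    c = cm.counts.astype(np.float64)
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    absent = (tp + fp + fn) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        jaccard = np.where(absent, 1.0, tp / np.maximum(tp + fp + fn, 1e-300))
        f1 = np.where(absent, 1.0, 2 * tp / np.maximum(2 * tp + fp + fn, 1e-300))
        precision = np.where(absent, 1.0,
                             np.where(tp + fp == 0, 0.0,
                                      tp / np.maximum(tp + fp, 1e-300)))
        recall = np.where(absent, 1.0,
                          np.where(tp + fn == 0, 0.0,
                                   tp / np.maximum(tp + fn, 1e-300)))
    return {
        "jaccard": jaccard, "f1": f1,
        "precision": precision, "recall": recall,
        "mean_jaccard": float(jaccard.mean()),
        "mean_f1": float(f1.mean()),
        "mean_precision": float(precision.mean()),
        "mean_recall": float(recall.mean()),
    }


def extract_activations(model: NetworkModel, input_vol: ImageVolume,
                        layer_name: str) -> Tuple[np.ndarray, tuple]:
    """Feature stack (z, y, x, features) of one named layer for one input.

    Also returns that layer's (name, spatial shape, channels) entry of the
    symbolic shape trace, against which the measured shape is checked.
    """
    names = model.layer_names()
    if layer_name not in names:
        raise EvaluationError(
            f"unknown layer {layer_name!r}; available layers: "
            + ", ".join(names))
    x = np.moveaxis(input_vol.data, 3, 0).astype(model.dtype)[None]
    model.forward(x, training=False, capture=[layer_name])
    feats = model.captured[layer_name][0]          # (C, z, y, x)
    trace = shape_trace(model.spec)
    entry = next(e for e in trace if e[0] == layer_name)
    if feats.shape != (entry[2],) + tuple(entry[1]):
        raise EvaluationError(
            f"measured activation shape {feats.shape} disagrees with symbolic "
            f"trace {entry}")
    return np.moveaxis(feats, 0, 3), entry
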