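"""Network construction and exact shape/parameter arithmetic.

Every family is described first as a symbolic *layer plan* (an ordered list
of :class:`PlanEntry`), which is the single source of truth shared by

* :func:`output_shape` / :func:`shape_trace` — pure shape propagation,
  including the valid-padding feasibility rules,
* :func:`count_parameters` — closed-form trainable-element count,
* :func:`build_network` — instantiation of actual numpy layers.

Families
--------
``unet2d`` / ``unet3d``
    Standard U-Net: per level two 3x3(x3) convolutions (+ optional batch
    norm) + ReLU, 2x max-pool down, 2x nearest-neighbour upsampling with a
    1x1 projection convolution up (checkerboard-free), center-crop skip
    concatenation, final 1x1(x1) convolution to ``n_classes`` with softmax.
    Filters double per level.
``unet3d_aniso``
    As ``unet3d`` but the first encoder level uses 2D convolutions and a 2D
    max-pool (acting on y, x only; z untouched), and the last decoder level
    mirrors the swap (2D up-convolution and 2D convolutions).  Intended for
    volumes with anisotropic voxels (~1:1:2 x:y:z), where pooling z at full
    resolution would mix information across a coarser physical distance.
``segnet2d``
    Symmetric encoder-decoder with max-pooling-index unpooling and no skip
    concatenation; 'same' padding only.

In valid-padding mode the spatial size entering every 2x pooling and every
2x transposed convolution must be even; violations raise :class:`ShapeError`
naming the first failing junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .config import ArchitectureSpec, validate_architecture_spec


class ShapeError(ValueError):
    """A spec's geometry is infeasible (shrink below 1 or odd junction)."""


@dataclass
class PlanEntry:
    kind: str                      # conv | bn | relu | pool | upconv | concat | unpool | softmax
    name: str
    inputs: Tuple[str, ...]
    in_ch: int = 0
    out_ch: int = 0
    kernel: Optional[Tuple[int, int, int]] = None
    factors: Optional[Tuple[int, int, int]] = None
    source: Optional[str] = None   # concat: skip tensor name; unpool: pool name


@dataclass
class ShapeTrace:
    """Per-layer (name, spatial shape (z, y, x), channel count) record."""
    entries: List[Tuple[str, Tuple[int, int, int], int]]

    def __iter__(self):
        return iter(self.entries)

    def as_text(self) -> str:
        lines = [f"{'layer':<20} {'z':>5} {'y':>5} {'x':>5} {'ch':>5}"]
        for name, (z, y, x), c in self.entries:
            lines.append(f"{name:<20} {z:>5} {y:>5} {x:>5} {c:>5}")
        return "\n".join(lines)


def _level_kernel(spec: ArchitectureSpec, level: int) -> Tuple[int, int, int]:
    if spec.is_2d:
        return (1, 3, 3)
    if spec.family == "unet3d_aniso" and level == 1:
        return (1, 3, 3)
    return (3, 3, 3)


def _level_factors(spec: ArchitectureSpec, level: int) -> Tuple[int, int, int]:
    if spec.is_2d:
        return (1, 2, 2)
    if spec.family == "unet3d_aniso" and level == 1:
        return (1, 2, 2)
    return (2, 2, 2)


def build_layer_plan(spec: ArchitectureSpec) -> List[PlanEntry]:
    """Symbolic layer sequence for a validated spec (no weights involved)."""
    D = spec.depth_levels
    f = [spec.n_first_filters * 2 ** i for i in range(D + 1)]
    entries: List[PlanEntry] = []
    prev = "input"

    def add(kind, name, in_ch=0, out_ch=0, **kw):
        nonlocal prev
        entries.append(PlanEntry(kind, name, (prev,), in_ch, out_ch, **kw))
        prev = name

    def conv_block(tag, in_ch, out_ch, kernel):
        add("conv", f"{tag}", in_ch, out_ch, kernel=kernel)
        if spec.batch_norm:
            add("bn", f"{tag}_bn", out_ch, out_ch)
        add("relu", f"{tag}_relu", out_ch, out_ch)

    if spec.family == "segnet2d":
        in_ch = spec.n_channels
        for i in range(1, D + 1):
            k = _level_kernel(spec, i)
            conv_block(f"enc{i}_conv1", in_ch, f[i - 1], k)
            conv_block(f"enc{i}_conv2", f[i - 1], f[i - 1], k)
            add("pool", f"enc{i}_pool", f[i - 1], f[i - 1],
                factors=_level_factors(spec, i))
            in_ch = f[i - 1]
        for i in range(D, 0, -1):
            k = _level_kernel(spec, i)
            out = f[i - 2] if i > 1 else f[0]
            entries.append(PlanEntry("unpool", f"dec{i}_unpool", (prev,),
                                     f[i - 1], f[i - 1], source=f"enc{i}_pool"))
            prev = f"dec{i}_unpool"
            conv_block(f"dec{i}_conv1", f[i - 1], out, k)
            conv_block(f"dec{i}_conv2", out, out, k)
    else:
        skips: Dict[int, str] = {}
        in_ch = spec.n_channels
        for i in range(1, D + 1):
            k = _level_kernel(spec, i)
            conv_block(f"enc{i}_conv1", in_ch, f[i - 1], k)
            conv_block(f"enc{i}_conv2", f[i - 1], f[i - 1], k)
            skips[i] = prev
            add("pool", f"enc{i}_pool", f[i - 1], f[i - 1],
                factors=_level_factors(spec, i))
            in_ch = f[i - 1]
        kb = _level_kernel(spec, D + 1)
        conv_block("bridge_conv1", f[D - 1], f[D], kb)
        conv_block("bridge_conv2", f[D], f[D], kb)
        for i in range(D, 0, -1):
            k = _level_kernel(spec, i)
            add("upconv", f"up{i}", f[i], f[i - 1],
                factors=_level_factors(spec, i))
            entries.append(PlanEntry("concat", f"dec{i}_concat",
                                     (skips[i], prev),
                                     f[i - 1], 2 * f[i - 1], source=skips[i]))
            prev = f"dec{i}_concat"
            conv_block(f"dec{i}_conv1", 2 * f[i - 1], f[i - 1], k)
            conv_block(f"dec{i}_conv2", f[i - 1], f[i - 1], k)

    add("conv", "final_conv", f[0], spec.n_classes, kernel=(1, 1, 1))
    add("softmax", "softmax", spec.n_classes, spec.n_classes)
    return entries


def _propagate(spec: ArchitectureSpec,
               plan: Optional[List[PlanEntry]] = None) -> ShapeTrace:
    """Walk the plan symbolically, enforcing all geometric feasibility rules."""
    if plan is None:
        plan = build_layer_plan(spec)
    shapes: Dict[str, Tuple[Tuple[int, int, int], int]] = {
        "input": (spec.spatial_shape, spec.n_channels)}
    trace: List[Tuple[str, Tuple[int, int, int], int]] = []
    valid = spec.padding == "valid"
    for e in plan:
        s, _c = shapes[e.inputs[-1]]
        if e.kind == "conv":
            if valid and e.kernel != (1, 1, 1):
                s = tuple(d - (k - 1) for d, k in zip(s, e.kernel))
                if min(s) < 1:
                    raise ShapeError(
                        f"{e.name}: patch too small for depth — valid convolution "
                        f"shrinks spatial shape to {s}")
            out = (s, e.out_ch)
        elif e.kind == "pool":
            new = []
            for d, fct in zip(s, e.factors):
                if fct > 1:
                    if d < fct:
                        raise ShapeError(f"{e.name}: size {d} too small to pool")
                    if d % fct:
                        raise ShapeError(
                            f"{e.name}: size {d} not divisible by {fct} at "
                            f"pooling junction")
                new.append(d // fct)
            out = (tuple(new), e.out_ch)
        elif e.kind == "upconv":
            if valid:
                for d, fct in zip(s, e.factors):
                    if fct > 1 and d % 2:
                        raise ShapeError(
                            f"{e.name}: size {d} odd entering upsampling "
                            f"junction")
            out = (tuple(d * fct for d, fct in zip(s, e.factors)), e.out_ch)
        elif e.kind == "unpool":
            out = (tuple(d * fct for d, fct in
                         zip(s, next(p.factors for p in plan
                                     if p.name == e.source))), e.out_ch)
        elif e.kind == "concat":
            skip_s, skip_c = shapes[e.inputs[0]]
            cur_s, cur_c = shapes[e.inputs[1]]
            for a, b in zip(skip_s, cur_s):
                if a < b:
                    raise ShapeError(
                        f"{e.name}: skip tensor {skip_s} smaller than decoder "
                        f"tensor {cur_s}")
            out = (cur_s, skip_c + cur_c)
        else:  # bn, relu, softmax
            out = (s, e.out_ch)
        shapes[e.name] = out
        trace.append((e.name, out[0], out[1]))
    return ShapeTrace(trace)


def output_shape(spec: ArchitectureSpec,
                 _validated: bool = False) -> Tuple[int, int, int]:
    """Spatial output shape (z, y, x) for one input patch.

    'same' padding returns the input spatial shape; 'valid' padding shrinks
    it (for isotropic U-Nets by 12 * 2**D - 8 per axis at depth D) and
    raises :class:`ShapeError` when the patch does not satisfy the
    evenness/positivity constraints at some junction.
    """
    if not _validated:
        validate_architecture_spec(spec)
    return _propagate(spec).entries[-1][1]


def shape_trace(spec: ArchitectureSpec) -> ShapeTrace:
    """Symbolic per-layer shapes; verified against real forward passes in tests."""
    validate_architecture_spec(spec)
    return _propagate(spec)


def count_parameters(spec: ArchitectureSpec) -> int:
    """Exact trainable-element count of the network the spec generates."""
    validate_architecture_spec(spec)
    total = 0
    for e in build_layer_plan(spec):
        if e.kind == "conv":
            total += int(np.prod(e.kernel)) * e.in_ch * e.out_ch + e.out_ch
        elif e.kind == "upconv":
            # nearest-neighbour resize + 1x1 projection: kernel volume 1
            total += e.in_ch * e.out_ch + e.out_ch
        elif e.kind == "bn":
            total += 2 * e.out_ch
    return total


class NetworkModel:
    """A built network: layer objects + the generating spec.

    Data layout is ``(N, C, Z, Y, X)``.  ``forward`` returns softmax class
    probabilities; during training :meth:`backward` starts from the gradient
    with respect to the final-convolution logits (cached on forward), which
    keeps the cross-entropy gradient numerically stable.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0,
                 dtype=np.float32):
        validate_architecture_spec(spec)
        self.spec = spec
        self.dtype = dtype
        self.plan = build_layer_plan(spec)
        rng = np.random.default_rng(seed)
        self.layers: Dict[str, nn.Layer] = {}
        pools: Dict[str, nn.MaxPool] = {}
        for e in self.plan:
            if e.kind == "conv":
                layer = nn.Conv(e.name, e.in_ch, e.out_ch, e.kernel,
                                spec.padding if e.kernel != (1, 1, 1) else "same",
                                rng, dtype)
            elif e.kind == "bn":
                layer = nn.BatchNorm(e.name, e.out_ch, dtype)
            elif e.kind == "relu":
                layer = nn.ReLU(e.name)
            elif e.kind == "pool":
                layer = nn.MaxPool(e.name, e.factors)
                pools[e.name] = layer
            elif e.kind == "upconv":
                layer = nn.UpConv(e.name, e.in_ch, e.out_ch, e.factors, rng, dtype)
            elif e.kind == "unpool":
                layer = nn.MaxUnpool(e.name, pools[e.source])
            elif e.kind == "concat":
                layer = nn.CropConcat(e.name)
            elif e.kind == "softmax":
                layer = nn.Softmax(e.name)
            else:  # pragma: no cover
                raise ValueError(e.kind)
            self.layers[e.name] = layer

    # -- execution ---------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                capture: Optional[Sequence[str]] = None) -> np.ndarray:
        """Run the network on a batch; optionally capture named outputs."""
        if x.ndim != 5:
            raise ValueError(f"expected (N, C, Z, Y, X) input, got shape {x.shape}")
        if x.shape[1] != self.spec.n_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels but the architecture expects "
                f"{self.spec.n_channels}")
        outs: Dict[str, np.ndarray] = {"input": x.astype(self.dtype, copy=False)}
        self.captured: Dict[str, np.ndarray] = {}
        for e in self.plan:
            args = [outs[i] for i in e.inputs]
            y = self.layers[e.name].forward(*args, training=training)
            outs[e.name] = y
            if capture and e.name in capture:
                self.captured[e.name] = y
        self.last_logits = outs["final_conv"]
        return outs["softmax"]

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate from the final-convolution logits (training mode)."""
        grads: Dict[str, np.ndarray] = {"final_conv": dlogits}
        for e in reversed(self.plan):
            if e.kind == "softmax" or e.name not in grads:
                continue
            dy = grads.pop(e.name)
            dxs = self.layers[e.name].backward(dy)
            if not isinstance(dxs, list):
                dxs = [dxs]
            for inp, dx in zip(e.inputs, dxs):
                if inp in grads:
                    grads[inp] = grads[inp] + dx
                else:
                    grads[inp] = dx

    def predict_patch(self, patch_czyx: np.ndarray) -> np.ndarray:
        """Class probabilities (C_classes, z, y, x) for one (c, z, y, x) patch."""
        return self.forward(patch_czyx[None], training=False)[0]

    # -- bookkeeping -------------------------------------------------------

    def parameters(self) -> List[nn.Param]:
        out = []
        for e in self.plan:
            out.extend(self.layers[e.name].params())
        return out

    def layer_names(self) -> List[str]:
        return [e.name for e in self.plan]

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.parameters()}
        for e in self.plan:
            state.update({k: v.copy() for k, v in
                          self.layers[e.name].buffers().items()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value = np.asarray(state[p.name], dtype=self.dtype).copy()
        for e in self.plan:
            layer = self.layers[e.name]
            if layer.buffers():
                layer.load_buffers({k: np.asarray(v, dtype=self.dtype)
                                    for k, v in state.items()
                                    if k in layer.buffers()})

    def summary(self) -> str:
        trace = _propagate(self.spec, self.plan)
        counts = {e.name: sum(p.value.size for p in self.layers[e.name].params())
                  for e in self.plan}
        lines = [f"{'layer':<20} {'z':>5} {'y':>5} {'x':>5} {'ch':>5} {'params':>9}"]
        for name, (z, y, x), c in trace:
            lines.append(f"{name:<20} {z:>5} {y:>5} {x:>5} {c:>5} {counts[name]:>9}")
        lines.append(f"total trainable parameters: {sum(counts.values())}")
        return "\n".join(lines)


def build_network(spec: ArchitectureSpec, seed: int = 0,
                  dtype=np.float32) -> NetworkModel:
    """Construct a network with He-uniform initialized weights."""
    return NetworkModel(spec, seed=seed, dtype=dtype)
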