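"""Minimal deterministic CNN substrate (numpy).

All tensors are dense numpy arrays in ``(N, C, Z, Y, X)`` layout; 2D networks
simply keep ``Z == 1`` and use kernels/pool factors of 1 along z, so a single
set of volumetric layer implementations serves every architecture family.

Each layer implements ``forward`` (caching what its ``backward`` needs) and
``backward`` returning the gradient with respect to its input(s).  The design
goal is exact reproducibility: given identical inputs and parameter values
the same sequence of numpy operations runs, so training trajectories are
bit-identical across runs and across checkpoint resumption.

Convolutions are computed with ``sliding_window_view`` + ``tensordot``
(im2col without the copy); the input gradient is the full correlation of the
output gradient with the spatially flipped kernel.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """One trainable tensor with its current gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad: Optional[np.ndarray] = None


class Layer:
    def __init__(self, name: str):
        self.name = name

    def params(self) -> List[Param]:
        return []

    def buffers(self) -> Dict[str, np.ndarray]:
        return {}

    def load_buffers(self, bufs: Dict[str, np.ndarray]) -> None:
        pass


class Conv(Layer):
    """ND cross-correlation, kernel (kz, ky, kx), 'same' (zero pad) or 'valid'."""

    def __init__(self, name: str, in_ch: int, out_ch: int,
                 kernel: Tuple[int, int, int], padding: str,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__(name)
        self.kernel = tuple(kernel)
        self.padding = padding
        fan_in = in_ch * int(np.prod(self.kernel))
        limit = math.sqrt(6.0 / fan_in)  # He-uniform
        self.W = Param(name + ".W",
                       rng.uniform(-limit, limit,
                                   (out_ch, in_ch) + self.kernel).astype(dtype))
        self.b = Param(name + ".b", np.zeros(out_ch, dtype))
        self._xp: Optional[np.ndarray] = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def _pad_widths(self):
        kz, ky, kx = self.kernel
        return ((0, 0), (0, 0), ((kz - 1) // 2,) * 2,
                ((ky - 1) // 2,) * 2, ((kx - 1) // 2,) * 2)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        xp = np.pad(x, self._pad_widths()) if self.padding == "same" else x
        self._xp = xp if training else None
        win = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        y = np.tensordot(win, self.W.value, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        y = np.moveaxis(y, 4, 1)
        y = y + self.b.value[None, :, None, None, None]
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        win = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        self.W.grad = np.tensordot(dy, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        self.b.grad = dy.sum(axis=(0, 2, 3, 4))
        kz, ky, kx = self.kernel
        dyp = np.pad(dy, ((0, 0), (0, 0), (kz - 1,) * 2, (ky - 1,) * 2, (kx - 1,) * 2))
        winy = sliding_window_view(dyp, self.kernel, axis=(2, 3, 4))
        Wf = np.flip(self.W.value, axis=(2, 3, 4))
        dxp = np.tensordot(winy, Wf, axes=([1, 5, 6, 7], [0, 2, 3, 4]))
        dxp = np.moveaxis(dxp, 4, 1)
        if self.padding == "same":
            pz, py, px = (kz - 1) // 2, (ky - 1) // 2, (kx - 1) // 2
            sl = (slice(None), slice(None),
                  slice(pz, dxp.shape[2] - pz or None),
                  slice(py, dxp.shape[3] - py or None),
                  slice(px, dxp.shape[4] - px or None))
            dxp = dxp[sl]
        self._xp = None
        return np.ascontiguousarray(dxp)


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, name: str, ch: int, dtype=np.float32,
                 momentum: float = 0.1, eps: float = 1e-5):
        super().__init__(name)
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(name + ".gamma", np.ones(ch, dtype))
        self.beta = Param(name + ".beta", np.zeros(ch, dtype))
        self.running_mean = np.zeros(ch, dtype)
        self.running_var = np.ones(ch, dtype)
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> Dict[str, np.ndarray]:
        return {self.name + ".running_mean": self.running_mean,
                self.name + ".running_var": self.running_var}

    def load_buffers(self, bufs: Dict[str, np.ndarray]) -> None:
        self.running_mean = bufs[self.name + ".running_mean"].copy()
        self.running_var = bufs[self.name + ".running_var"].copy()

    @staticmethod
    def _bc(v: np.ndarray) -> np.ndarray:
        return v[None, :, None, None, None]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mu)) * self._bc(inv)
        if training:
            n = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
            self._cache = (xhat, inv, n)
        return self._bc(self.gamma.value) * xhat + self._bc(self.beta.value)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, n = self._cache
        axes = (0, 2, 3, 4)
        self.gamma.grad = (dy * xhat).sum(axis=axes)
        self.beta.grad = dy.sum(axis=axes)
        dxhat = dy * self._bc(self.gamma.value)
        dx = (self._bc(inv) / n) * (
            n * dxhat
            - self._bc(dxhat.sum(axis=axes))
            - xhat * self._bc((dxhat * xhat).sum(axis=axes)))
        self._cache = None
        return dx.astype(dy.dtype, copy=False)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool(Layer):
    """Max pooling with kernel == stride (factor 1 or 2 per axis).

    Argmax indices within each pooling window are retained so that SegNet's
    unpooling and the pooling backward pass can scatter to the exact winning
    positions.  Input spatial sizes must be divisible by the factors.
    """

    def __init__(self, name: str, factors: Tuple[int, int, int]):
        super().__init__(name)
        self.factors = tuple(factors)

    def _windows(self, x: np.ndarray) -> np.ndarray:
        fz, fy, fx = self.factors
        N, C, Z, Y, X = x.shape
        r = x.reshape(N, C, Z // fz, fz, Y // fy, fy, X // fx, fx)
        r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7)
        return r.reshape(N, C, Z // fz, Y // fy, X // fx, fz * fy * fx)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        r = self._windows(x)
        self.idx = r.argmax(axis=-1)
        self.in_shape = x.shape
        y = np.take_along_axis(r, self.idx[..., None], axis=-1)[..., 0]
        return np.ascontiguousarray(y)

    def scatter(self, vals: np.ndarray) -> np.ndarray:
        """Place pooled-resolution values at the recorded argmax positions."""
        fz, fy, fx = self.factors
        N, C, Z, Y, X = self.in_shape
        r = np.zeros((N, C, Z // fz, Y // fy, X // fx, fz * fy * fx), vals.dtype)
        np.put_along_axis(r, self.idx[..., None], vals[..., None], axis=-1)
        r = r.reshape(N, C, Z // fz, Y // fy, X // fx, fz, fy, fx)
        r = r.transpose(0, 1, 2, 5, 3, 6, 4, 7)
        return np.ascontiguousarray(r.reshape(N, C, Z, Y, X))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.scatter(dy)


class MaxUnpool(Layer):
    """SegNet-style unpooling using the paired MaxPool's recorded indices."""

    def __init__(self, name: str, source: MaxPool):
        super().__init__(name)
        self.source = source

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.source.scatter(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        r = self.source._windows(dy)
        y = np.take_along_axis(r, self.source.idx[..., None], axis=-1)[..., 0]
        return np.ascontiguousarray(y)


class UpConv(Layer):
    """Upsampling: nearest-neighbour resize (factor 1 or 2 per axis) + 1x1
    projection convolution.

    Constant-preserving by construction (a stride-2 transposed convolution
    is not: its independent taps imprint a period-2 checkerboard even on
    constant input), so valid-mode networks map constant inputs to constant
    outputs and overlap-tile stitching cannot fabricate texture.
    """

    def __init__(self, name: str, in_ch: int, out_ch: int,
                 factors: Tuple[int, int, int],
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__(name)
        self.factors = tuple(factors)
        self.out_ch = out_ch
        limit = math.sqrt(6.0 / in_ch)
        self.W = Param(name + ".W",
                       rng.uniform(-limit, limit, (in_ch, out_ch)).astype(dtype))
        self.b = Param(name + ".b", np.zeros(out_ch, dtype))

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def _upsample(self, x: np.ndarray) -> np.ndarray:
        for ax, f in zip((2, 3, 4), self.factors):
            if f > 1:
                x = np.repeat(x, f, axis=ax)
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        up = self._upsample(x)
        self._up = up if training else None
        t = np.tensordot(up, self.W.value, axes=([1], [0]))  # (N,Z,Y,X,O)
        t = np.moveaxis(t, 4, 1) + self.b.value[None, :, None, None, None]
        return np.ascontiguousarray(t)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad = np.tensordot(self._up, dy,
                                   axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        self.b.grad = dy.sum(axis=(0, 2, 3, 4))
        dup = np.tensordot(dy, self.W.value, axes=([1], [1]))  # (N,Z,Y,X,C)
        dup = np.moveaxis(dup, 4, 1)
        fz, fy, fx = self.factors
        N, C, Z, Y, X = self._in_shape
        dx = dup.reshape(N, C, Z, fz, Y, fy, X, fx).sum(axis=(3, 5, 7))
        self._up = None
        return np.ascontiguousarray(dx)


class CropConcat(Layer):
    """Center-crop the encoder skip tensor and concatenate along channels.

    Odd crop amounts remove the extra voxel from the high-index side.
    Takes two inputs (skip, x) and returns gradients for both.
    """

    def forward(self, skip: np.ndarray, x: np.ndarray,
                training: bool = False) -> np.ndarray:
        self._skip_shape = skip.shape
        slices = []
        for ax in (2, 3, 4):
            off = skip.shape[ax] - x.shape[ax]
            if off < 0:
                raise ValueError(
                    f"{self.name}: skip tensor smaller than decoder tensor "
                    f"({skip.shape} vs {x.shape})")
            lo = off // 2
            slices.append(slice(lo, lo + x.shape[ax]))
        self._slices = tuple(slices)
        sk = skip[(slice(None), slice(None)) + self._slices]
        self._split = sk.shape[1]
        return np.concatenate([sk, x], axis=1)

    def backward(self, dy: np.ndarray) -> List[np.ndarray]:
        dsk = dy[:, :self._split]
        dx = np.ascontiguousarray(dy[:, self._split:])
        dskip = np.zeros(self._skip_shape, dy.dtype)
        dskip[(slice(None), slice(None)) + self._slices] = dsk
        return [dskip, dx]


class Softmax(Layer):
    """Numerically stable softmax over the channel (class) axis."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        e = np.exp(x - x.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        self._p = p if training else None
        return p

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self._p
        return p * (dy - (dy * p).sum(axis=1, keepdims=True))


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray,
                          class_weights: Optional[np.ndarray] = None
                          ) -> Tuple[float, np.ndarray]:
    """Voxelwise (optionally class-weighted) cross-entropy from logits.

    Returns ``(loss, dlogits)``.  The gradient is taken with respect to the
    logits for numerical stability; the weighted mean divides by the total
    weight so uniform weights reduce to the plain mean.
    """
    n_cls = logits.shape[1]
    m = logits.max(axis=1, keepdims=True)
    logp = logits - m - np.log(np.exp(logits - m).sum(axis=1, keepdims=True))
    p = np.exp(logp)
    onehot_idx = target[:, None]  # (N,1,Z,Y,X)
    logp_t = np.take_along_axis(logp, onehot_idx, axis=1)[:, 0]
    if class_weights is None:
        w_vox = np.ones_like(logp_t)
    else:
        class_weights = np.asarray(class_weights, dtype=logits.dtype)
        if class_weights.shape != (n_cls,):
            raise ValueError(
                f"class_weights length {class_weights.shape} != n_classes {n_cls}")
        w_vox = class_weights[target]
    denom = float(w_vox.sum())
    if denom == 0.0:
        return 0.0, np.zeros_like(logits)
    loss = float(-(w_vox * logp_t).sum() / denom)
    onehot = np.zeros_like(logits)
    np.put_along_axis(onehot, onehot_idx, 1.0, axis=1)
    dlogits = (p - onehot) * w_vox[:, None] / denom
    return loss, dlogits.astype(logits.dtype, copy=False)


class Adam:
    """Adam optimizer with serializable state for exact resumption."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}

    def step(self, params: Sequence[Param]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p in params:
            g = p.grad
            m = self.m.get(p.name)
            if m is None:
                m = np.zeros_like(p.value)
                self.m[p.name] = m
                self.v[p.name] = np.zeros_like(p.value)
            v = self.v[p.name]
            m[...] = b1 * m + (1.0 - b1) * g
            v[...] = b2 * v + (1.0 - b2) * g * g
            p.value = (p.value
                       - self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
                       ).astype(p.value.dtype, copy=False)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": {k: v.copy() for k, v in self.m.items()},
                "v": {k: v.copy() for k, v in self.v.items()}}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = {k: np.array(v) for k, v in state["m"].items()}
        self.v = {k: np.array(v) for k, v in state["v"].items()}
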