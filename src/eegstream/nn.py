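"""Minimal 3D convolutional network engine on numpy.

Layers cover exactly what the two classifiers need: 3D convolution (arbitrary
kernel/stride/padding), 3D batch normalization, ReLU, 2x2x2 max pooling,
global average pooling, dropout, fully connected layers, and residual blocks
with optional projection shortcuts.  Each layer implements ``forward`` and
``backward`` explicitly; activations are cached only when ``training=True``,
so inference on large inputs does not retain intermediates.

Convolution is evaluated by kernel-offset decomposition: for every kernel
offset the (possibly strided) shifted input slab is contracted with the
corresponding weight slice via a batched matrix product.  This keeps peak
memory at one input/output slab (no im2col materialization) while all heavy
lifting stays inside BLAS.

All computation is float32.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "GlobalAvgPool3d",
    "Flatten",
    "Dropout",
    "Linear",
    "Sequential",
    "Residual",
    "softmax_cross_entropy",
    "SGD",
]


class Param:
    """A trainable tensor and its gradient buffer."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def modules(self) -> Iterable["Layer"]:
        yield self

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training)


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(u) for u in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3 tuple, got {v!r}")
    return t


class Conv3d(Layer):
    """3D convolution (cross-correlation) over (batch, channels, T, H, W)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        stride=1,
        padding=0,
        bias: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel_size = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        rng = rng or np.random.default_rng(0)
        fan_in = self.in_channels * int(np.prod(self.kernel_size))
        std = np.sqrt(2.0 / fan_in)
        self.weight = Param(
            rng.normal(0.0, std, (self.out_channels, self.in_channels, *self.kernel_size)),
            "conv.weight",
        )
        self.bias = Param(np.zeros(self.out_channels), "conv.bias") if bias else None
        self._cache = None

    def _out_shape(self, T: int, H: int, W: int) -> tuple[int, int, int]:
        kt, kh, kw = self.kernel_size
        st, sh, sw = self.stride
        pt, ph, pw = self.padding
        To = (T + 2 * pt - kt) // st + 1
        Ho = (H + 2 * ph - kh) // sh + 1
        Wo = (W + 2 * pw - kw) // sw + 1
        if To < 1 or Ho < 1 or Wo < 1:
            raise ValueError(
                f"input {T}x{H}x{W} too small for kernel {self.kernel_size} "
                f"with padding {self.padding}"
            )
        return To, Ho, Wo

    #: ceiling (bytes) on the unfolded column matrix before falling back to
    #: the per-offset accumulation path
    IM2COL_LIMIT = 192 * 1024**2

    def _im2col(self, xp: np.ndarray, out_sp: tuple[int, int, int]) -> np.ndarray:
        """Unfold the padded input into (b, ci*k^3, positions), one copy."""
        b, ci = xp.shape[:2]
        To, Ho, Wo = out_sp
        st, sh, sw = self.stride
        win = np.lib.stride_tricks.sliding_window_view(
            xp, self.kernel_size, axis=(2, 3, 4)
        )[:, :, ::st, ::sh, ::sw]
        # (b, ci, To, Ho, Wo, kt, kh, kw) -> (b, ci*k^3, P)
        col = win.transpose(0, 1, 5, 6, 7, 2, 3, 4)
        return np.ascontiguousarray(col).reshape(b, -1, To * Ho * Wo)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        b, ci, T, H, W = x.shape
        if ci != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {ci}")
        kt, kh, kw = self.kernel_size
        st, sh, sw = self.stride
        pt, ph, pw = self.padding
        To, Ho, Wo = self._out_shape(T, H, W)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        P = To * Ho * Wo
        w = self.weight.value
        k3 = kt * kh * kw
        col_bytes = b * ci * k3 * P * 4
        if col_bytes <= self.IM2COL_LIMIT:
            col = self._im2col(xp, (To, Ho, Wo))
            out = w.reshape(self.out_channels, ci * k3) @ col
            if training:
                self._cache = ("col", col, x.shape, xp.shape, (To, Ho, Wo))
        else:
            out = np.zeros((b, self.out_channels, P), dtype=np.float32)
            for i, j, k in product(range(kt), range(kh), range(kw)):
                xs = xp[:, :, i : i + st * To : st, j : j + sh * Ho : sh,
                        k : k + sw * Wo : sw]
                out += w[:, :, i, j, k] @ np.ascontiguousarray(xs).reshape(b, ci, P)
            if training:
                self._cache = ("slab", xp, x.shape, xp.shape, (To, Ho, Wo))
        out = out.reshape(b, self.out_channels, To, Ho, Wo)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kind, stash, x_shape, xp_shape, (To, Ho, Wo) = self._cache
        b, ci = x_shape[0], x_shape[1]
        kt, kh, kw = self.kernel_size
        st, sh, sw = self.stride
        pt, ph, pw = self.padding
        P = To * Ho * Wo
        k3 = kt * kh * kw
        g = np.ascontiguousarray(grad, dtype=np.float32).reshape(b, self.out_channels, P)
        gxp = np.zeros(xp_shape, dtype=np.float32)
        w = self.weight.value
        if kind == "col":
            col = stash  # (b, ci*k^3, P)
            gw = (g @ col.transpose(0, 2, 1)).sum(axis=0)
            self.weight.grad += gw.reshape(self.weight.value.shape)
            gcol = (
                w.reshape(self.out_channels, ci * k3).T @ g
            ).reshape(b, ci, kt, kh, kw, To, Ho, Wo)
            for i, j, k in product(range(kt), range(kh), range(kw)):
                gxp[:, :, i : i + st * To : st, j : j + sh * Ho : sh,
                    k : k + sw * Wo : sw] += gcol[:, :, i, j, k]
        else:
            xp = stash
            for i, j, k in product(range(kt), range(kh), range(kw)):
                sl = (
                    slice(None),
                    slice(None),
                    slice(i, i + st * To, st),
                    slice(j, j + sh * Ho, sh),
                    slice(k, k + sw * Wo, sw),
                )
                xs = np.ascontiguousarray(xp[sl]).reshape(b, ci, P)
                self.weight.grad[:, :, i, j, k] += (g @ xs.transpose(0, 2, 1)).sum(axis=0)
                gxp[sl] += (w[:, :, i, j, k].T @ g).reshape(b, ci, To, Ho, Wo)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        T, H, W = x_shape[2:]
        return gxp[:, :, pt : pt + T, ph : ph + H, pw : pw + W]

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (batch, T, H, W) statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._axes = (0, 2, 3, 4)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        shape = (1, self.channels, 1, 1, 1)
        if training:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        out = self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)
        if training:
            self._cache = (xhat, inv_std)
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        shape = (1, self.channels, 1, 1, 1)
        g = np.asarray(grad, dtype=np.float32)
        self.gamma.grad += (g * xhat).sum(axis=self._axes)
        self.beta.grad += g.sum(axis=self._axes)
        mean_g = g.mean(axis=self._axes).reshape(shape)
        mean_gx = (g * xhat).mean(axis=self._axes).reshape(shape)
        coef = (self.gamma.value * inv_std).reshape(shape)
        return (coef * (g - mean_g - xhat * mean_gx)).astype(np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling; odd trailing samples along any axis are dropped."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, T, H, W = x.shape
        To, Ho, Wo = T // 2, H // 2, W // 2
        if To < 1 or Ho < 1 or Wo < 1:
            raise ValueError(f"input {T}x{H}x{W} too small for 2x2x2 pooling")
        xt = x[:, :, : To * 2, : Ho * 2, : Wo * 2]
        xr = (
            xt.reshape(b, c, To, 2, Ho, 2, Wo, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(b, c, To, Ho, Wo, 8)
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache
        b, c, T, H, W = x_shape
        To, Ho, Wo = T // 2, H // 2, W // 2
        g8 = np.zeros((b, c, To, Ho, Wo, 8), dtype=np.float32)
        np.put_along_axis(g8, idx[..., None], grad[..., None].astype(np.float32), axis=-1)
        gx_t = (
            g8.reshape(b, c, To, Ho, Wo, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(b, c, To * 2, Ho * 2, Wo * 2)
        )
        gx = np.zeros(x_shape, dtype=np.float32)
        gx[:, :, : To * 2, : Ho * 2, : Wo * 2] = gx_t
        return gx


class GlobalAvgPool3d(Layer):
    """Mean over all spatio-temporal positions -> (batch, channels)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, T, H, W = self._shape
        return np.broadcast_to(
            grad[:, :, None, None, None] / (T * H * W), self._shape
        ).astype(np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout with *keep* probability (active only in training)."""

    def __init__(self, keep: float = 0.5, rng: Optional[np.random.Generator] = None) -> None:
        if not (0.0 < keep <= 1.0):
            raise ValueError("keep probability must be in (0, 1]")
        self.keep = keep
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.keep >= 1.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) < self.keep).astype(np.float32) / self.keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, std, (out_features, in_features)), "fc.weight")
        self.bias = Param(np.zeros(out_features), "fc.bias") if bias else None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if training:
            self._x = x
        out = x @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = np.asarray(grad, dtype=np.float32)
        self.weight.grad += g.T @ self._x
        if self.bias is not None:
            self.bias.grad += g.sum(axis=0)
        return g @ self.weight.value

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def modules(self) -> Iterable[Layer]:
        yield self
        for layer in self.layers:
            yield from layer.modules()


class Residual(Layer):
    """z_out = relu(main(x) + shortcut(x)); identity shortcut when None."""

    def __init__(self, main: Layer, shortcut: Optional[Layer] = None) -> None:
        self.main = main
        self.shortcut = shortcut

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = self.main.forward(x, training)
        skip = x if self.shortcut is None else self.shortcut.forward(x, training)
        summed = out + skip
        if training:
            self._mask = summed > 0
        return np.maximum(summed, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        gx = self.main.backward(g)
        gx = gx + (g if self.shortcut is None else self.shortcut.backward(g))
        return gx

    def params(self) -> list[Param]:
        ps = self.main.params()
        if self.shortcut is not None:
            ps = ps + self.shortcut.params()
        return ps

    def modules(self) -> Iterable[Layer]:
        yield self
        yield from self.main.modules()
        if self.shortcut is not None:
            yield from self.shortcut.modules()


def set_dropout_rng(model: Layer, rng: np.random.Generator) -> None:
    """Point every dropout layer in the graph at the given generator."""
    for m in model.modules():
        if isinstance(m, Dropout):
            m.rng = rng


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    log_p = shifted - log_z
    n = logits.shape[0]
    loss = -log_p[np.arange(n), labels].mean()
    grad = np.exp(log_p)
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class SGD:
    """Plain SGD with optional momentum; the learning rate is passed per step."""

    def __init__(self, params: Sequence[Param], momentum: float = 0.0) -> None:
        self.params = list(params)
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self._velocity):
            if self.momentum:
                v *= self.momentum
                v -= lr * p.grad
                p.value += v
            else:
                p.value -= lr * p.grad
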