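"""The two 3D-CNN classifier graphs.

Both networks consume a 3D EEG stream tensor of shape (1, t, h, w) — one
input channel, t stacked frames of h x w pixels (default 1 x 128 x 64 x 64) —
and emit class logits.  Both use a 7x3x3 kernel by default, padded 3x1x1 so
convolutions preserve resolution: the temporal axis of an EEG stream is much
longer than its spatial extent, so the kernel is deeper in time than the
3x3x3 customary for video.

C3D-style: five [conv -> batchnorm -> ReLU -> 2x2x2 maxpool] blocks with
channel progression 64, 128, 256, 256, 256, then two fully connected blocks
(width 4096, ReLU, dropout) and a final fully connected classifier.

R(2+1)D-style: a stem of a spatial (1x3x3, 45 channels) and a temporal
(7x1x1, 64 channels) convolution, then four residual blocks

    z_i = z_{i-1} + F(z_{i-1}; theta_i)

whose mapping F is two factorized (2+1)D layers.  A t x d x d convolution is
factorized into a 1 x d x d spatial convolution to ``mid`` channels followed
by a t x 1 x 1 temporal convolution, with

    mid = floor(t d^2 n_in n_out / (d^2 n_in + t n_out))

so the factorized pair spends the same parameter budget as the full 3D
kernel while doubling the nonlinearities.  Blocks 2-4 downsample all three
axes by stride 2 with a projection shortcut; global average pooling and two
fully connected layers (512, then the class count) close the network.

The printed channel constants are defaults of :class:`ModelConfig`; narrower
channel lists, shallower kernels and smaller streams are legal configurations
for reduced-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import nn

__all__ = [
    "ModelConfig",
    "mid_channels",
    "build_c3d",
    "build_r2plus1d",
    "count_parameters",
    "first_conv_out_channels",
    "layer_table",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters shared by both classifiers."""

    input_shape: tuple[int, int, int, int] = (1, 128, 64, 64)
    num_classes: int = 2
    kernel_temporal_depth: int = 7
    kernel_spatial: int = 3
    c3d_block_channels: tuple[int, ...] = (64, 128, 256, 256, 256)
    c3d_fc_width: int = 4096
    r21d_block_channels: tuple[int, ...] = (64, 128, 256, 512)
    r21d_stem_spatial_channels: int = 45
    r21d_stem_temporal_channels: int = 64
    r21d_fc_width: int = 512
    dropout_keep: float = 0.5

    def __post_init__(self) -> None:
        if len(self.input_shape) != 4:
            raise ValueError("input_shape must be (channels, length, height, width)")
        for name in ("kernel_temporal_depth", "kernel_spatial"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be an odd integer >= 1, got {k}")
        if not self.c3d_block_channels or not self.r21d_block_channels:
            raise ValueError("channel progressions must be non-empty")
        if not (0.0 < self.dropout_keep <= 1.0):
            raise ValueError("dropout_keep must be in (0, 1]")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


def mid_channels(in_ch: int, out_ch: int, t: int, d: int) -> int:
    """Intermediate width of a factorized (2+1)D convolution.

    floor(t * d^2 * in * out / (d^2 * in + t * out)), clamped to at least 1 —
    the width at which the spatial+temporal pair matches the parameter count
    of the full t x d x d kernel.
    """
    for name, v in (("in_ch", in_ch), ("out_ch", out_ch), ("t", t), ("d", d)):
        if int(v) != v or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v}")
    num = t * d * d * in_ch * out_ch
    den = d * d * in_ch + t * out_ch
    return max(1, num // den)


def _pool_shape(shape: tuple[int, int, int]) -> tuple[int, int, int]:
    return (shape[0] // 2, shape[1] // 2, shape[2] // 2)


def build_c3d(cfg: ModelConfig, seed: int = 0) -> nn.Sequential:
    """Five conv/pool blocks, two FC blocks with dropout, and a classifier head."""
    rng = np.random.default_rng(seed)
    t, s = cfg.kernel_temporal_depth, cfg.kernel_spatial
    pad = ((t - 1) // 2, (s - 1) // 2, (s - 1) // 2)
    c, T, H, W = cfg.input_shape
    n_blocks = len(cfg.c3d_block_channels)
    min_side = 2**n_blocks
    if min(T, H, W) < min_side:
        raise ValueError(
            f"input {T}x{H}x{W} too small for {n_blocks} pooling stages; "
            f"every axis must be at least {min_side}"
        )
    layers: list[nn.Layer] = []
    in_ch, shape = c, (T, H, W)
    for out_ch in cfg.c3d_block_channels:
        layers += [
            nn.Conv3d(in_ch, out_ch, (t, s, s), stride=1, padding=pad, bias=False, rng=rng),
            nn.BatchNorm3d(out_ch),
            nn.ReLU(),
            nn.MaxPool3d(),
        ]
        in_ch, shape = out_ch, _pool_shape(shape)
    flat = in_ch * shape[0] * shape[1] * shape[2]
    layers.append(nn.Flatten())
    width = flat
    for _ in range(2):
        layers += [
            nn.Linear(width, cfg.c3d_fc_width, rng=rng),
            nn.ReLU(),
            nn.Dropout(cfg.dropout_keep),
        ]
        width = cfg.c3d_fc_width
    layers.append(nn.Linear(width, cfg.num_classes, rng=rng))
    return nn.Sequential(*layers)


def _factorized_conv(
    in_ch: int,
    out_ch: int,
    t: int,
    s: int,
    stride: int,
    rng: np.random.Generator,
) -> list[nn.Layer]:
    """Spatial (1 x s x s) then temporal (t x 1 x 1) convolution pair via mid width."""
    mid = mid_channels(in_ch, out_ch, t, s)
    sp = (s - 1) // 2
    tp = (t - 1) // 2
    return [
        nn.Conv3d(in_ch, mid, (1, s, s), stride=(1, stride, stride),
                  padding=(0, sp, sp), bias=False, rng=rng),
        nn.BatchNorm3d(mid),
        nn.ReLU(),
        nn.Conv3d(mid, out_ch, (t, 1, 1), stride=(stride, 1, 1),
                  padding=(tp, 0, 0), bias=False, rng=rng),
    ]


def build_r2plus1d(cfg: ModelConfig, seed: int = 0) -> nn.Sequential:
    """Factorized stem, four residual blocks, global pooling, two FC layers."""
    rng = np.random.default_rng(seed)
    t, s = cfg.kernel_temporal_depth, cfg.kernel_spatial
    sp = (s - 1) // 2
    tp = (t - 1) // 2
    c = cfg.input_shape[0]
    stem = [
        nn.Conv3d(c, cfg.r21d_stem_spatial_channels, (1, s, s),
                  padding=(0, sp, sp), bias=False, rng=rng),
        nn.BatchNorm3d(cfg.r21d_stem_spatial_channels),
        nn.ReLU(),
        nn.Conv3d(cfg.r21d_stem_spatial_channels, cfg.r21d_stem_temporal_channels,
                  (t, 1, 1), padding=(tp, 0, 0), bias=False, rng=rng),
        nn.BatchNorm3d(cfg.r21d_stem_temporal_channels),
        nn.ReLU(),
    ]
    blocks: list[nn.Layer] = []
    in_ch = cfg.r21d_stem_temporal_channels
    for i, out_ch in enumerate(cfg.r21d_block_channels):
        stride = 1 if i == 0 else 2
        main = nn.Sequential(
            *_factorized_conv(in_ch, out_ch, t, s, stride, rng),
            nn.BatchNorm3d(out_ch),
            nn.ReLU(),
            *_factorized_conv(out_ch, out_ch, t, s, 1, rng),
            nn.BatchNorm3d(out_ch),
        )
        shortcut = None
        if stride != 1 or in_ch != out_ch:
            shortcut = nn.Sequential(
                nn.Conv3d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm3d(out_ch),
            )
        blocks.append(nn.Residual(main, shortcut))
        in_ch = out_ch
    head = [
        nn.GlobalAvgPool3d(),
        nn.Linear(in_ch, cfg.r21d_fc_width, rng=rng),
        nn.ReLU(),
        nn.Linear(cfg.r21d_fc_width, cfg.num_classes, rng=rng),
    ]
    return nn.Sequential(*stem, *blocks, *head)


def _state_arrays(model: nn.Layer) -> dict[str, np.ndarray]:
    """Flat name->array mapping of all trainable and running state, in
    deterministic module-traversal order."""
    state: dict[str, np.ndarray] = {}
    for i, m in enumerate(model.modules()):
        for j, p in enumerate(m.params()):
            state[f"m{i:03d}.p{j}"] = p.value
        if isinstance(m, nn.BatchNorm3d):
            state[f"m{i:03d}.running_mean"] = m.running_mean
            state[f"m{i:03d}.running_var"] = m.running_var
    return state


def save_weights(model: nn.Layer, path) -> None:
    """Serialize model state (weights + batch-norm running statistics) to .npz."""
    np.savez(path, **_state_arrays(model))


def load_weights(model: nn.Layer, path) -> nn.Layer:
    """Load state saved by :func:`save_weights` into an identically built graph."""
    with np.load(path) as data:
        stored = dict(data)
    expected = _state_arrays(model)
    if set(stored) != set(expected):
        raise ValueError(
            "weight file does not match the model graph "
            f"(stored {len(stored)} arrays, model expects {len(expected)})"
        )
    for i, m in enumerate(model.modules()):
        for j, p in enumerate(m.params()):
            arr = stored[f"m{i:03d}.p{j}"]
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for m{i:03d}.p{j}")
            p.value[...] = arr
        if isinstance(m, nn.BatchNorm3d):
            m.running_mean = stored[f"m{i:03d}.running_mean"]
            m.running_var = stored[f"m{i:03d}.running_var"]
    return model


def count_parameters(model: nn.Layer) -> int:
    """Total trainable scalar parameter count of a built graph."""
    return int(sum(p.value.size for p in model.params()))


def first_conv_out_channels(model: nn.Layer) -> int:
    """Output-channel count of the first convolution in the graph (stem inspection)."""
    for m in model.modules():
        if isinstance(m, nn.Conv3d):
            return m.out_channels
    raise ValueError("model contains no convolution layer")


def layer_table(model: nn.Layer) -> list[str]:
    """Human-readable one-line-per-layer description (used by the CLI inspect command)."""
    rows = []
    for m in model.modules():
        if isinstance(m, nn.Conv3d):
            rows.append(
                f"Conv3d {m.in_channels}->{m.out_channels} k={m.kernel_size} "
                f"s={m.stride} p={m.padding}"
            )
        elif isinstance(m, nn.Linear):
            rows.append(f"Linear {m.in_features}->{m.out_features}")
        elif isinstance(m, nn.BatchNorm3d):
            rows.append(f"BatchNorm3d {m.channels}")
        elif isinstance(m, (nn.ReLU, nn.MaxPool3d, nn.GlobalAvgPool3d, nn.Flatten)):
            rows.append(type(m).__name__)
        elif isinstance(m, nn.Dropout):
            rows.append(f"Dropout keep={m.keep}")
        elif isinstance(m, nn.Residual):
            rows.append("Residual block")
    return rows
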