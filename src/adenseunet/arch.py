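"""The A-DenseUNet architecture.

Encoder: a densely connected convolutional network — a 7x7/96 stride-2
dilated stem, 3x3 stride-2 max pooling, then four dense blocks (growth rate
k, bottleneck 4k, layer ``t`` consuming the concatenation of all previous
layer outputs) separated by compressing transitions (1x1 conv to
``floor(theta * c)`` channels, 2x2 stride-2 average pooling).  With the
default configuration the per-level feature sides are [112, 56, 28, 14, 7]
for a 224x224 input.

Decoder: a nested grid of refinement nodes (UNet++-style).  Node (i, j) at
level ``i``, column ``j`` gates its same-level predecessors with an additive
attention gate driven by the deeper node's pre-upsample features, upsamples
the deeper node by a 2x2/stride-2 transposed convolution, concatenates, and
applies a residual refinement block of dilated convolutions.  Disabling the
dense decoder links collapses the grid to a single-column U-Net decoder.

Head: every top-row node is projected to a common width, upsampled to full
resolution, averaged (deep supervision), then a 1x1 convolution and a
sigmoid produce the probability mask, so outputs always lie in [0, 1].

When dilation is enabled every 3x3 convolution uses rate ``l`` (default 2)
and a multi-rate atrous pyramid (parallel dilated convolutions, rates
[1, 2, 4] by default, fused back to the input width) sits at the encoder
bottleneck; the ``use_dilation`` ablation removes the pyramid and resets
every rate to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import ModelConfig
from .nn import functional as F
from .nn.tensor import Tensor


@dataclass(frozen=True)
class LevelShape:
    """(spatial side, channel count) contract for one encoder level."""

    level_index: int
    spatial_side: int
    channels: int


# ---------------------------------------------------------------------------
# shape inference
# ---------------------------------------------------------------------------


def encoder_channels(config: ModelConfig) -> list[int]:
    """Channel count at each encoder level, before transitions."""
    config.validate()
    ch = [config.stem_filters]
    c = config.stem_filters
    for i, n in enumerate(config.block_layers):
        if i > 0:
            c = int(np.floor(config.compression_theta * c))
        c = c + n * config.growth_rate_k
        ch.append(c)
    return ch


def infer_encoder_shapes(config: ModelConfig) -> list[LevelShape]:
    """Per-level (spatial, channels) contract without building the network."""
    chans = encoder_channels(config)
    return [
        LevelShape(i + 1, config.input_side // 2 ** (i + 1), c)
        for i, c in enumerate(chans)
    ]


def decoder_out_channels(config: ModelConfig, level: int) -> int:
    if config.decoder_channel_rule == "match-encoder-level":
        return encoder_channels(config)[level - 1]
    return min(64 * 2 ** (level - 1), config.decoder_channel_cap)


def grid_columns(config: ModelConfig, level: int) -> list[int]:
    """Decoder columns present at ``level`` (1-based, level < depth_s)."""
    s = config.depth_s
    if not (1 <= level <= s - 1):
        raise ValueError(f"decoder level must lie in [1, {s - 1}]")
    if config.use_dense_decoder_links:
        return list(range(1, s - level + 1))
    return [s - level]


def node_channels(config: ModelConfig, level: int, column: int) -> tuple[int, int, int]:
    """(skip, deeper, out) channel counts for decoder node (level, column)."""
    if column not in grid_columns(config, level):
        raise ValueError(
            f"decoder node (level={level}, column={column}) not in the topology"
        )
    enc = encoder_channels(config)
    out_ch = decoder_out_channels(config, level)
    skip_ch = enc[level - 1]
    if config.use_dense_decoder_links:
        skip_ch += (column - 1) * out_ch
    if column == 1:
        deeper_ch = enc[level]  # encoder (pyramid preserves the width)
    else:
        deeper_ch = decoder_out_channels(config, level + 1)
    return skip_ch, deeper_ch, out_ch


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


class DenseLayer(nn.Module):
    """BN / 1x1 bottleneck conv (4k) / BN / 3x3 dilated conv (k) unit."""

    def __init__(self, in_ch, k, bottleneck, rate, order, rng):
        super().__init__()
        self.order = order
        self.bn1 = nn.BatchNorm2d(in_ch)
        self.conv1 = nn.Conv2d(in_ch, bottleneck, 1, rng)
        self.bn2 = nn.BatchNorm2d(bottleneck)
        self.conv2 = nn.Conv2d(bottleneck, k, 3, rng, dilation=rate)

    def forward(self, x):
        if self.order == "bn-conv-relu":
            h = F.relu(self.conv1(self.bn1(x)))
            return F.relu(self.conv2(self.bn2(h)))
        h = self.conv1(F.relu(self.bn1(x)))
        return self.conv2(F.relu(self.bn2(h)))


class DenseBlock(nn.Module):
    """Stack of dense layers; layer t consumes concat([x0, ..., x_{t-1}])."""

    def __init__(self, in_ch, n_layers, k, rate, rng, bottleneck_factor=4,
                 order="bn-conv-relu"):
        super().__init__()
        if n_layers < 0:
            raise ValueError("n_layers must be >= 0")
        self.layers = [
            DenseLayer(in_ch + t * k, k, bottleneck_factor * k, rate, order, rng)
            for t in range(n_layers)
        ]
        self.out_channels = in_ch + n_layers * k

    def forward(self, x):
        feats = [x]
        state = x
        for layer in self.layers:
            feats.append(layer(state))
            state = F.concat(feats, axis=1)
        return state


class Transition(nn.Module):
    """1x1 compression conv (floor(theta * c) channels) + 2x2 average pool."""

    def __init__(self, in_ch, theta, rng):
        super().__init__()
        if not (0.0 < theta <= 1.0):
            raise ValueError("theta must lie in (0, 1]")
        self.out_channels = int(np.floor(theta * in_ch))
        self.bn = nn.BatchNorm2d(in_ch)
        self.conv = nn.Conv2d(in_ch, self.out_channels, 1, rng)

    def forward(self, x):
        return F.avg_pool2d(F.relu(self.conv(self.bn(x))))


class AtrousPyramid(nn.Module):
    """Parallel dilated 3x3 convolutions at several rates, fused by a 1x1
    convolution back to the input width (bottleneck context block)."""

    def __init__(self, channels, rates, rng):
        super().__init__()
        mid = max(channels // 8, 8)
        self.branches = [
            nn.Sequential(
                nn.Conv2d(channels, mid, 3, rng, dilation=r),
                nn.BatchNorm2d(mid),
                nn.ReLU(),
            )
            for r in rates
        ]
        self.fuse = nn.Sequential(
            nn.Conv2d(mid * len(rates), channels, 1, rng),
            nn.BatchNorm2d(channels),
            nn.ReLU(),
        )

    def forward(self, x):
        return self.fuse(F.concat([b(x) for b in self.branches], axis=1))


class AttentionGate(nn.Module):
    """Additive attention gate.

    Skip and gating features are projected by 1x1 convolutions to a common
    intermediate width (the gate is first upsampled to the skip resolution),
    summed, passed through ReLU and a 1x1 convolution to one channel, and
    squashed by a sigmoid; the skip features are multiplied elementwise by
    the resulting coefficients in [0, 1].
    """

    def __init__(self, skip_channels, gate_channels, inter_channels, rng):
        super().__init__()
        if min(skip_channels, gate_channels, inter_channels) < 1:
            raise ValueError("attention gate channel counts must be >= 1")
        self.theta = nn.Conv2d(skip_channels, inter_channels, 1, rng, bias=False)
        self.phi = nn.Conv2d(gate_channels, inter_channels, 1, rng)
        self.psi = nn.Conv2d(inter_channels, 1, 1, rng)

    def coefficients(self, skip: Tensor, gate: Tensor) -> Tensor:
        g = gate
        while g.shape[2] < skip.shape[2] and g.shape[3] < skip.shape[3]:
            g = F.upsample_nearest2(g)
        if g.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"gate spatial {tuple(gate.shape[2:])} cannot be resampled to "
                f"skip spatial {tuple(skip.shape[2:])}"
            )
        a = F.relu(F.add(self.theta(skip), self.phi(g)))
        return F.sigmoid(self.psi(a))

    def forward(self, skip, gate):
        return F.mul(skip, self.coefficients(skip, gate))

    def saturate(self) -> None:
        """Force coefficients to exactly 1 (identity-gate test mode)."""
        self.psi.weight.data[...] = 0.0
        self.psi.bias.data[...] = 1e4

    def zero_weights(self) -> None:
        for p in self.parameters():
            p.data[...] = 0.0


class DecoderNode(nn.Module):
    """One decoder grid node: gate skips, upsample deeper, concat, refine.

    The refinement block is residual: two dilated 3x3 conv + BN stages with
    an inner ReLU, added to a 1x1-projected shortcut of the concatenated
    input (no activation after the add, so zeroed convolutions make the
    node an exact projected-shortcut pass-through).
    """

    def __init__(self, skip_ch, deeper_ch, out_ch, rate, use_attention, rng):
        super().__init__()
        self.up = nn.ConvTranspose2d(deeper_ch, out_ch, rng)
        self.gate = (
            AttentionGate(skip_ch, deeper_ch, max(out_ch // 2, 4), rng)
            if use_attention
            else None
        )
        in_ch = skip_ch + out_ch
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, dilation=rate)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, dilation=rate)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.shortcut = nn.Conv2d(in_ch, out_ch, 1, rng)

    def forward(self, skips: list[Tensor], deeper: Tensor) -> Tensor:
        skip = skips[0] if len(skips) == 1 else F.concat(skips, axis=1)
        if self.gate is not None:
            skip = self.gate(skip, deeper)
        x = F.concat([skip, self.up(deeper)], axis=1)
        h = F.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(h))
        return F.add(y, self.shortcut(x))


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def build_dense_block(
    in_channels: int,
    n_layers: int,
    k: int,
    rate: int = 1,
    seed: int = 0,
    bottleneck_factor: int = 4,
    order: str = "bn-conv-relu",
) -> tuple[DenseBlock, int]:
    """Build a dense block; returns (block, output channel count)."""
    block = DenseBlock(in_channels, n_layers, k, rate, _rng(seed),
                       bottleneck_factor, order)
    return block, block.out_channels


def build_transition(in_channels: int, theta: float, seed: int = 0) -> tuple[Transition, int]:
    t = Transition(in_channels, theta, _rng(seed))
    return t, t.out_channels


def build_attention_gate(
    skip_channels: int, gate_channels: int, inter_channels: int, seed: int = 0
) -> AttentionGate:
    return AttentionGate(skip_channels, gate_channels, inter_channels, _rng(seed))


def build_decoder_node(level: int, column: int, config: ModelConfig, seed: int = 0) -> DecoderNode:
    skip_ch, deeper_ch, out_ch = node_channels(config, level, column)
    rate = config.dilation_rate_l if config.use_dilation else 1
    return DecoderNode(skip_ch, deeper_ch, out_ch, rate, config.use_attention, _rng(seed))


class ADenseUNet(nn.Module):
    """Full network; forward maps (N, 3, S, S) to (N, 1, S, S) in [0, 1]."""

    def __init__(self, config: ModelConfig, seed: int | None = None):
        super().__init__()
        config.validate()
        self.config = config
        rng = _rng(config.seed if seed is None else seed)
        s = config.depth_s
        stem_rate = config.dilation_rate_l if config.use_dilation else 1

        # ---- encoder
        self.stem = nn.Sequential(
            nn.Conv2d(config.input_channels, config.stem_filters,
                      config.stem_kernel, rng, stride=2, dilation=stem_rate),
            nn.BatchNorm2d(config.stem_filters),
            nn.ReLU(),
        )
        self.blocks: list[DenseBlock] = []
        self.transitions: list[Transition] = []
        c = config.stem_filters
        for b, n in enumerate(config.block_layers):
            if b > 0:
                t = Transition(c, config.compression_theta, rng)
                self.transitions.append(t)
                c = t.out_channels
            blk = DenseBlock(c, n, config.growth_rate_k, config.block_rate(b),
                             rng, config.bottleneck_factor, config.dense_layer_order)
            self.blocks.append(blk)
            c = blk.out_channels
        self.pyramid = (
            AtrousPyramid(c, config.pyramid_rates, rng)
            if config.use_dilation
            else nn.Identity()
        )

        # ---- decoder grid
        dec_rate = config.dilation_rate_l if config.use_dilation else 1
        self.nodes: dict[str, DecoderNode] = {}
        for level in range(1, s):
            for column in grid_columns(config, level):
                skip_ch, deeper_ch, out_ch = node_channels(config, level, column)
                self.nodes[f"{level},{column}"] = DecoderNode(
                    skip_ch, deeper_ch, out_ch, dec_rate, config.use_attention, rng
                )

        # ---- deep-supervision head
        top_ch = decoder_out_channels(config, 1)
        self.head_branches: dict[str, nn.Sequential] = {
            str(j): nn.Sequential(
                nn.Conv2d(top_ch, config.head_width, 1, rng),
                nn.ReLU(),
                nn.ConvTranspose2d(config.head_width, config.head_width, rng),
            )
            for j in grid_columns(config, 1)
        }
        self.final = nn.Conv2d(config.head_width, 1, 1, rng)

    # -- forward -------------------------------------------------------
    def encoder_features(self, x: Tensor) -> list[Tensor]:
        """Per-level encoder feature maps (level 1 = stem output)."""
        feats = [self.stem(x)]
        h = F.max_pool2d(feats[0])
        for b, blk in enumerate(self.blocks):
            if b > 0:
                h = self.transitions[b - 1](h)
            h = blk(h)
            feats.append(h)
        return feats

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != self.config.input_channels:
            raise ValueError(
                f"expected input (N, {self.config.input_channels}, S, S), "
                f"got {tuple(x.shape)}"
            )
        s = self.config.depth_s
        feats = self.encoder_features(x)
        feats[s - 1] = self.pyramid(feats[s - 1])

        grid: dict[tuple[int, int], Tensor] = {
            (level, 0): feats[level - 1] for level in range(1, s + 1)
        }
        for column in range(1, s):
            for level in range(1, s):
                key = f"{level},{column}"
                if key not in self.nodes:
                    continue
                if self.config.use_dense_decoder_links:
                    skips = [grid[(level, jj)] for jj in range(column)]
                else:
                    skips = [grid[(level, 0)]]
                grid[(level, column)] = self.nodes[key](
                    skips, grid[(level + 1, column - 1)]
                )

        tops = [
            self.head_branches[str(j)](grid[(1, j)]) for j in grid_columns(self.config, 1)
        ]
        agg = tops[0]
        for t in tops[1:]:
            agg = F.add(agg, t)
        agg = F.scale(agg, 1.0 / len(tops))
        return F.sigmoid(self.final(agg))


def build_model(config: ModelConfig, seed: int | None = None) -> ADenseUNet:
    """Construct the network from a configuration (seeded He init)."""
    return ADenseUNet(config, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalar parameters."""
    return model.num_parameters()
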