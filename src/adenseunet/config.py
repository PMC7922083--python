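"""Configuration objects for the architecture, training, augmentation and
the synthetic phantom generator, with flat YAML/JSON (de)serialisation.

Unknown keys in a config file are rejected rather than ignored, so typos in
experiment configs fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ModelConfig:
    """Hyperparameters of the attention-gated dense atrous U-Net.

    The defaults reproduce the reference layout: a 7x7/96 stride-2 stem,
    four dense blocks of [6, 12, 36, 24] layers with growth rate k = 48,
    0.5-compression transitions, network depth s = 5 (stem level plus one
    level per dense block) and dilation rate l = 2 in every 3x3 convolution.
    """

    input_side: int = 224
    input_channels: int = 3
    stem_filters: int = 96
    stem_kernel: int = 7
    growth_rate_k: int = 48
    block_layers: list[int] = field(default_factory=lambda: [6, 12, 36, 24])
    bottleneck_factor: int = 4
    compression_theta: float = 0.5
    dilation_rate_l: int = 2
    block_dilation_rates: list[int] | None = None  # per-dense-block override
    pyramid_rates: list[int] = field(default_factory=lambda: [1, 2, 4])
    depth_s: int = 5
    use_attention: bool = True
    use_dilation: bool = True
    use_dense_decoder_links: bool = True
    decoder_channel_rule: str = "halve-per-up"  # or "match-encoder-level"
    dense_layer_order: str = "bn-conv-relu"  # or "bn-relu-conv"
    head_width: int = 32
    decoder_channel_cap: int = 512
    seed: int = 0

    def validate(self) -> None:
        if len(self.block_layers) + 1 != self.depth_s:
            raise ValueError(
                "len(block_layers) + 1 must equal depth_s "
                f"({len(self.block_layers)} + 1 != {self.depth_s})"
            )
        if self.input_side % (2**self.depth_s) != 0:
            raise ValueError(
                f"input_side {self.input_side} not divisible by 2^depth_s "
                f"= {2**self.depth_s}"
            )
        if self.growth_rate_k < 1:
            raise ValueError("growth_rate_k must be >= 1")
        if self.dilation_rate_l < 1:
            raise ValueError("dilation_rate_l must be >= 1")
        if not (0.0 < self.compression_theta <= 1.0):
            raise ValueError("compression_theta must lie in (0, 1]")
        if any(n < 0 for n in self.block_layers):
            raise ValueError("block_layers entries must be >= 0")
        if self.block_dilation_rates is not None and len(
            self.block_dilation_rates
        ) != len(self.block_layers):
            raise ValueError("block_dilation_rates must match block_layers length")
        if self.decoder_channel_rule not in ("halve-per-up", "match-encoder-level"):
            raise ValueError(f"unknown decoder_channel_rule {self.decoder_channel_rule!r}")
        if self.dense_layer_order not in ("bn-conv-relu", "bn-relu-conv"):
            raise ValueError(f"unknown dense_layer_order {self.dense_layer_order!r}")

    def block_rate(self, block_index: int) -> int:
        """Dilation rate for dense block ``block_index`` (0-based)."""
        if not self.use_dilation:
            return 1
        if self.block_dilation_rates is not None:
            return self.block_dilation_rates[block_index]
        return self.dilation_rate_l


@dataclass
class TrainConfig:
    """Training protocol: Adam, lr 0.01 reduced x0.1 after a 5-epoch
    validation plateau, early stopping, batch size 10, BCE loss."""

    batch_size: int = 10
    epochs: int = 100
    initial_lr: float = 0.01
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    plateau_min_delta: float = 1e-4
    early_stop_patience: int = 15
    optimizer: str = "adam"
    loss: str = "bce"  # bce | dice | jaccard | mse
    max_steps: int | None = None
    seed: int = 0
    checkpoint_dir: str | None = None

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss not in ("bce", "dice", "jaccard", "mse"):
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass
class AugmentConfig:
    """Mask-aware augmentation protocol: aspect-preserving resize with random
    crop, rotation in [0, 90] degrees, horizontal/vertical reflection,
    elastic deformation on a fixed 10x10 grid, random gamma."""

    target_side: int = 224
    rotation_range: float = 90.0
    flip_horizontal: bool = True
    flip_vertical: bool = True
    elastic_grid: int = 10
    elastic_magnitude: float = 6.0
    gamma_range: tuple[float, float] = (0.7, 1.5)
    multiplier: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if not (0.0 <= self.rotation_range <= 90.0):
            raise ValueError("rotation_range must lie in [0, 90] degrees")
        if self.elastic_grid < 2:
            raise ValueError("elastic_grid must be >= 2")
        if not (0.0 < self.gamma_range[0] <= self.gamma_range[1]):
            raise ValueError("gamma_range must be a positive increasing interval")


@dataclass
class PhantomConfig:
    """Synthetic colonoscopy phantom: mucosa-textured background, 1-2
    elliptical polyps with exact masks, specular highlights, vignetting."""

    side: int = 224
    n_polyps: tuple[int, int] = (1, 2)
    polyp_axis_range: tuple[float, float] | None = None  # default 8-25% of side
    texture_scale: float = 24.0
    specular_spots: tuple[int, int] = (2, 6)
    vignette_strength: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        if self.side < 8:
            raise ValueError("side must be >= 8")
        if self.n_polyps[0] < 0 or self.n_polyps[1] < self.n_polyps[0]:
            raise ValueError("n_polyps must be a non-decreasing non-negative range")
        lo, hi = self.axis_range()
        if not (0 < lo <= hi) or 2 * hi >= self.side:
            raise ValueError("polyp axes must be positive and fit inside the frame")

    def axis_range(self) -> tuple[float, float]:
        if self.polyp_axis_range is not None:
            return self.polyp_axis_range
        return (0.08 * self.side, 0.25 * self.side)


_TUPLE_FIELDS = {"gamma_range", "n_polyps", "polyp_axis_range", "specular_spots"}


def config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def config_from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {
        k: (tuple(v) if k in _TUPLE_FIELDS and v is not None else v)
        for k, v in data.items()
    }
    cfg = cls(**kwargs)
    cfg.validate()
    return cfg


def save_config(cfg, path: str | Path) -> None:
    path = Path(path)
    payload = config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(cls, path: str | Path):
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(cls, data or {})
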