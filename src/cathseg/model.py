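"""Light U-Net construction, parameter accounting and layer selection.

The default architecture is the lightweight variant of the classic
biomedical U-Net: one 3x3 convolution block (conv -> batch-norm ->
ReLU) per step instead of two, stride-2 convolutions for downsampling,
bare stride-2 transposed convolutions for upsampling, skip
concatenations, and a 3x3 convolution + sigmoid head emitting two
complementary full-scale maps (catheter / background).  Counting every
convolution, batch normalization and activation as one layer, the
default network has 55 layers and 687,634 trainable parameters.

Fine-tuning operates on named selections ("7-layers", "13-layers",
"19-layers"): a contiguous span of registry layers centered on the
bottleneck convolution, symmetric with respect to the encoder and
decoder.  The spans are nested by construction.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import LightUNet

__all__ = [
    "ArchitectureConfig",
    "build_model",
    "count_parameters",
    "count_layers",
    "finetune_selection",
    "select_finetune_layers",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1

#: registry-span sizes for the named fine-tuning configurations
FINETUNE_CONFIGS = {"7-layers": 7, "13-layers": 13, "19-layers": 19}

_COUNTED_KINDS = ("conv", "bn", "activation")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Declarative description of the light U-Net.

    ``channels_per_level`` runs from full resolution down to the
    bottleneck; its length minus one is the number of stride-2
    downsamplings, so ``input_size`` must be divisible by
    ``2 ** (len(channels_per_level) - 1)``.
    """

    input_size: int = 256
    in_channels: int = 1
    channels_per_level: tuple[int, ...] = (8, 16, 32, 44, 64, 156)
    kernel_size: int = 3
    n_output_maps: int = 2
    downsample: str = "strided_conv"
    upsample: str = "transposed_conv"

    def __post_init__(self):
        if len(self.channels_per_level) < 2:
            raise ValueError("channels_per_level needs at least two entries")
        if self.kernel_size != 3:
            raise ValueError("the architecture uses 3x3 kernels throughout")
        div = 2 ** (len(self.channels_per_level) - 1)
        if self.input_size % div:
            raise ValueError(
                f"input_size {self.input_size} not divisible by {div} "
                f"({len(self.channels_per_level) - 1} downsamplings)"
            )
        if self.downsample != "strided_conv" or self.upsample != "transposed_conv":
            raise ValueError("supported modes: strided_conv down, transposed_conv up")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels_per_level"] = list(self.channels_per_level)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        d = dict(d)
        d["channels_per_level"] = tuple(d["channels_per_level"])
        return cls(**d)

    def expected_parameters(self) -> int:
        """Closed-form parameter count (k*k*c_in*c_out + c_out per conv,
        2*c_out per batch-norm) over the architecture table."""
        k2 = self.kernel_size**2
        ch = self.channels_per_level
        total = 0

        def conv(ci, co):
            return k2 * ci * co + co

        prev = self.in_channels
        for i in range(len(ch) - 1):
            total += conv(prev, ch[i]) + 2 * ch[i]  # level conv + BN
            total += conv(ch[i], ch[i + 1]) + 2 * ch[i + 1]  # strided conv + BN
            prev = ch[i + 1]
        total += conv(ch[-1], ch[-1]) + 2 * ch[-1]  # bottleneck
        for i in range(len(ch) - 2, -1, -1):
            total += conv(ch[i + 1], ch[i])  # transposed conv (no BN)
            total += conv(2 * ch[i], ch[i]) + 2 * ch[i]  # conv after concat + BN
        total += conv(ch[0], self.n_output_maps)  # head
        return total


def build_model(config: ArchitectureConfig | None = None, rng_seed: int = 0) -> LightUNet:
    """Instantiate the network with seeded He initialisation."""
    cfg = config or ArchitectureConfig()
    model = LightUNet(
        cfg.channels_per_level,
        in_channels=cfg.in_channels,
        n_output_maps=cfg.n_output_maps,
        kernel_size=cfg.kernel_size,
        rng=np.random.default_rng(rng_seed),
    )
    model.config = cfg
    return model


def count_parameters(model: LightUNet, trainable_only: bool = False) -> int:
    """Total scalar weights: conv kernels and biases, BN scales and shifts."""
    return model.count_parameters(trainable_only=trainable_only)


def count_layers(model: LightUNet) -> int:
    """Layers under the convention that each convolution, each batch
    normalization and each activation counts as one."""
    return sum(1 for l in model.layers if l.kind in _COUNTED_KINDS)


def finetune_selection(model: LightUNet, config_name: str) -> list[int]:
    """Registry indices of the deepest ``N`` layers for a named config.

    The span is contiguous and centered on the bottleneck convolution,
    so it grows symmetrically into the encoder and decoder; selections
    are nested (7-layers within 13-layers within 19-layers).
    """
    if config_name not in FINETUNE_CONFIGS:
        raise ValueError(
            f"unknown fine-tune config {config_name!r}; "
            f"choose from {sorted(FINETUNE_CONFIGS)}"
        )
    n = FINETUNE_CONFIGS[config_name]
    center = next(i for i, l in enumerate(model.layers) if l.name == "bottleneck_conv")
    lo = center - (n - 1) // 2
    hi = lo + n
    if lo < 0 or hi > model.n_layers:
        raise ValueError(f"{config_name} selection does not fit this architecture")
    return list(range(lo, hi))


def select_finetune_layers(model: LightUNet, config_name: str) -> list[int]:
    """Mark only the named deepest-layer selection trainable; freeze the rest."""
    selection = finetune_selection(model, config_name)
    model.set_trainable(selection)
    return selection


# ------------------------------------------------------------- checkpointing
def save_checkpoint(path: str | Path, model: LightUNet, extra: dict | None = None) -> None:
    """Write a self-describing archive: format version, architecture
    config, all weights and batch-norm buffers, plus optional metadata
    (e.g. normalization statistics, training stage)."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": model.config.to_dict(),
        "n_parameters": count_parameters(model),
        "extra": extra or {},
    }
    state = model.state_dict()
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[LightUNet, dict]:
    """Rebuild a model from an archive; verifies the stored parameter
    count matches the architecture config.  Returns (model, extra)."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]))
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint format {meta['format_version']}")
    cfg = ArchitectureConfig.from_dict(meta["config"])
    model = build_model(cfg)
    model.load_state_dict(state)
    actual = count_parameters(model)
    if actual != meta["n_parameters"]:
        raise ValueError(
            f"checkpoint parameter count {meta['n_parameters']} does not match "
            f"rebuilt model ({actual})"
        )
    return model, meta["extra"]
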