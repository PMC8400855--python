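"""Configuration dataclasses mirroring the published hyper-parameters.

The segmentation network follows the published table: 64 base features,
3x3 filters, 2x2 pooling, stride 1, Adam.  The "3 layers" entry is read
as three resolution levels, i.e. two 2x2 pooling stages — the only
reading under which unpadded convolutions map a 170x170 input to the
published 128x128 output (see ``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["SegNetConfig", "ClassifierConfig", "TrainConfig", "load_config",
           "save_config"]


@dataclass
class SegNetConfig:
    """Architecture of the segmentation network.

    ``depth`` counts 2x2 pooling stages; the encoder has ``depth + 1``
    resolution levels.  ``padding_mode="valid"`` uses unpadded
    convolutions with centre crops at the skip connections (the
    published 170 -> 128 contract); ``"same"`` preserves spatial size.
    """

    depth: int = 2
    base_features: int = 64
    kernel: int = 3
    pool: int = 2
    stride: int = 1
    padding_mode: str = "valid"
    nested: bool = False
    deep_supervision: bool = False
    in_channels: int = 3
    n_classes: int = 2

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_features < 1:
            raise ValueError("base_features must be >= 1")
        if self.padding_mode not in ("valid", "same"):
            raise ValueError("padding_mode must be 'valid' or 'same'")
        if self.pool != 2 or self.stride != 1:
            raise ValueError("only pool=2, stride=1 are supported")
        if self.nested and self.padding_mode != "same":
            raise ValueError("the nested network requires padding_mode='same'")
        if self.deep_supervision and not self.nested:
            raise ValueError("deep_supervision requires nested=True")


@dataclass
class ClassifierConfig:
    """The malignant/benign CNN: conv blocks of (conv, batch-norm, ReLU,
    2x2 max-pool), then global average pooling and a 2-class head."""

    conv_layers: int = 4
    kernels_per_layer: int = 64
    kernel: int = 3
    batch_norm: bool = True
    in_channels: int = 3
    n_classes: int = 2

    def __post_init__(self):
        if self.conv_layers < 1:
            raise ValueError("conv_layers must be >= 1")


@dataclass
class TrainConfig:
    """Optimisation settings shared by both training stages."""

    epochs: int = 50
    batch_size: int = 16
    lr: float = 1e-3
    omega0: float = 10.0     # boundary-weight amplitude
    sigma: float = 5.0       # boundary-weight length scale, pixels
    loss_variant: str = "printed"   # deep-supervision loss reading
    standard_bce_dice: bool = False

    def __post_init__(self):
        if self.standard_bce_dice:
            self.loss_variant = "standard"


@dataclass
class PipelineConfig:
    segnet: SegNetConfig = field(default_factory=SegNetConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    train: TrainConfig = field(default_factory=TrainConfig)


def _from_dict(cls, d: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML/JSON config with optional segnet/classifier/train blocks."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(
        segnet=_from_dict(SegNetConfig, raw.get("segnet", {})),
        classifier=_from_dict(ClassifierConfig, raw.get("classifier", {})),
        train=_from_dict(TrainConfig, raw.get("train", {})),
    )


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "segnet": asdict(cfg.segnet),
        "classifier": asdict(cfg.classifier),
        "train": asdict(cfg.train),
    }))
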