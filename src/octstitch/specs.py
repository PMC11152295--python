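"""Declarative model specifications for the micro/tiny hybrid backbones.

A :class:`ModelSpec` fully determines a buildable network: the 4-layer
convolutional stem, four stages (each an optional patch embedding followed
by repeated groups of ECB/LTB blocks), stochastic-depth rate and classifier
head.  The micro and tiny variants differ only in the number of repeats of
the stage-3 block group (1 vs 2) and the path-dropout rate (0.05 vs 0.1).

Block internals that the stage table does not pin down (feed-forward
expansion ratios, attention head width, key/value pooling strides) live in
:class:`BlockConventions` and are explicit, serializable knobs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a model/stitching specification is internally invalid."""


@dataclass
class ConvSpec:
    """A convolution in the stem or a patch embedding."""
    kernel: int
    out_channels: int
    stride: int = 1
    depthwise: bool = False

    def validate(self, where: str) -> None:
        if self.kernel not in (1, 3):
            raise ConfigurationError(f"{where}: kernel must be 1 or 3")
        if self.out_channels < 1:
            raise ConfigurationError(f"{where}: out_channels must be >= 1")
        if self.stride not in (1, 2):
            raise ConfigurationError(f"{where}: stride must be 1 or 2")


@dataclass
class BlockGroupSpec:
    """`repeat` consecutive blocks of one kind at output width `dim`."""
    block_kind: str  # "ECB" | "LTB"
    dim: int
    repeat: int = 1

    def validate(self, where: str) -> None:
        if self.block_kind not in ("ECB", "LTB"):
            raise ConfigurationError(
                f"{where}: block_kind must be ECB or LTB, got "
                f"{self.block_kind!r}")
        if self.dim < 1 or self.repeat < 1:
            raise ConfigurationError(f"{where}: dim and repeat must be >= 1")


@dataclass
class StageSpec:
    """One backbone stage: optional patch embedding + block groups.

    `pool_stride` is the average-pool stride of the patch embedding
    (1 means no pooling, as in stage 1); `embed_channels` is the width of
    its 1x1 convolution.  The bracketed group list is repeated
    `group_repeat` times.
    """
    embed_channels: int
    groups: list[BlockGroupSpec]
    pool_stride: int = 2
    group_repeat: int = 1

    def validate(self, where: str) -> None:
        if self.group_repeat < 1:
            raise ConfigurationError(f"{where}: group_repeat must be >= 1")
        if not self.groups:
            raise ConfigurationError(f"{where}: block group list is empty")
        for i, g in enumerate(self.groups):
            g.validate(f"{where}.groups[{i}]")

    def block_dims(self) -> list[tuple[str, int]]:
        """Flattened (kind, dim) list for one full stage."""
        out: list[tuple[str, int]] = []
        for _ in range(self.group_repeat):
            for g in self.groups:
                out.extend((g.block_kind, g.dim) for _ in range(g.repeat))
        return out


@dataclass
class BlockConventions:
    """Block internals not fixed by the stage table.

    head_dim: channels per attention head (convolutional and self-attention
    alike).  ecb_expansion / ltb_expansion: hidden-width ratios of the
    locally-enhanced feed-forward network in each block kind.
    esa_pool_strides: per-stage stride of the average pooling applied to
    keys/values in efficient self-attention.  qkv_bias: bias on the
    query/key/value projections.
    """
    head_dim: int = 32
    ecb_expansion: float = 3.0
    ltb_expansion: float = 0.284375
    esa_pool_strides: tuple[int, int, int, int] = (8, 4, 2, 1)
    qkv_bias: bool = True

    def validate(self) -> None:
        if self.head_dim < 1:
            raise ConfigurationError("head_dim must be >= 1")
        if self.ecb_expansion <= 0 or self.ltb_expansion <= 0:
            raise ConfigurationError("expansion ratios must be positive")
        if len(self.esa_pool_strides) != 4:
            raise ConfigurationError("esa_pool_strides must list 4 stages")


@dataclass
class ModelSpec:
    name: str
    stem: list[ConvSpec]
    stages: list[StageSpec]
    path_dropout: float
    num_classes: int = 3
    input_channels: int = 3
    conventions: BlockConventions = field(default_factory=BlockConventions)

    def validate(self) -> None:
        if len(self.stages) != 4:
            raise ConfigurationError(
                f"model {self.name!r}: expected exactly 4 stages, got "
                f"{len(self.stages)}")
        if not 0.0 <= self.path_dropout <= 1.0:
            raise ConfigurationError(
                f"model {self.name!r}: path_dropout must be in [0, 1]")
        if self.num_classes < 2:
            raise ConfigurationError(
                f"model {self.name!r}: num_classes must be >= 2")
        for i, c in enumerate(self.stem):
            c.validate(f"model {self.name!r} stem[{i}]")
        for i, s in enumerate(self.stages):
            s.validate(f"model {self.name!r} stage {i + 1}")
        self.conventions.validate()
        hd = self.conventions.head_dim
        for i, s in enumerate(self.stages):
            for kind, dim in s.block_dims():
                if dim % hd:
                    raise ConfigurationError(
                        f"model {self.name!r} stage {i + 1}: {kind}{dim} "
                        f"channel count not divisible by head_dim {hd}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        conv = d.get("conventions", {})
        conv = dict(conv)
        if "esa_pool_strides" in conv:
            conv["esa_pool_strides"] = tuple(conv["esa_pool_strides"])
        return cls(
            name=d["name"],
            stem=[ConvSpec(**c) for c in d["stem"]],
            stages=[StageSpec(
                embed_channels=s["embed_channels"],
                groups=[BlockGroupSpec(**g) for g in s["groups"]],
                pool_stride=s.get("pool_stride", 2),
                group_repeat=s.get("group_repeat", 1),
            ) for s in d["stages"]],
            path_dropout=d["path_dropout"],
            num_classes=d.get("num_classes", 3),
            input_channels=d.get("input_channels", 3),
            conventions=BlockConventions(**conv),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# The published micro / tiny stage tables.
# ---------------------------------------------------------------------------

_STEM = [
    ConvSpec(3, 64, 2),
    ConvSpec(3, 32, 1),
    ConvSpec(3, 64, 1),
    ConvSpec(3, 64, 2),
]

# Feed-forward expansion ratios calibrated so the fully built 3-class
# micro/tiny networks land on their published parameter counts
# (24.50M / 31.14M); see docs/methods.md.
_CONVENTIONS = BlockConventions()


def _stages(stage3_group_repeat: int) -> list[StageSpec]:
    return [
        StageSpec(96, [BlockGroupSpec("ECB", 96, 3)], pool_stride=1),
        StageSpec(192, [BlockGroupSpec("ECB", 192, 3),
                        BlockGroupSpec("LTB", 256, 1)]),
        StageSpec(384, [BlockGroupSpec("ECB", 384, 4),
                        BlockGroupSpec("LTB", 512, 1)],
                  group_repeat=stage3_group_repeat),
        StageSpec(768, [BlockGroupSpec("ECB", 768, 2),
                        BlockGroupSpec("LTB", 1024, 1)]),
    ]


def _stem() -> list[ConvSpec]:
    return [dataclasses.replace(c) for c in _STEM]


def micro_spec(num_classes: int = 3) -> ModelSpec:
    return ModelSpec(name="micro", stem=_stem(),
                     stages=_stages(1), path_dropout=0.05,
                     num_classes=num_classes,
                     conventions=dataclasses.replace(_CONVENTIONS))


def tiny_spec(num_classes: int = 3) -> ModelSpec:
    return ModelSpec(name="tiny", stem=_stem(),
                     stages=_stages(2), path_dropout=0.1,
                     num_classes=num_classes,
                     conventions=dataclasses.replace(_CONVENTIONS))


def reduced_spec(kind: str = "micro", num_classes: int = 3,
                 divisor: int = 8) -> ModelSpec:
    """Desk-scale variant: channels / `divisor`, inner repeats collapsed
    to 1, tiny's doubled stage-3 group retained so the two reduced anchors
    still have unequal stage-3 depth (exercising the unpaired strategy)."""
    d = divisor
    stages = [
        StageSpec(96 // d, [BlockGroupSpec("ECB", 96 // d, 1)],
                  pool_stride=1),
        StageSpec(192 // d, [BlockGroupSpec("ECB", 192 // d, 1),
                             BlockGroupSpec("LTB", 256 // d, 1)]),
        StageSpec(384 // d, [BlockGroupSpec("ECB", 384 // d, 1),
                             BlockGroupSpec("LTB", 512 // d, 1)],
                  group_repeat=2 if kind == "tiny" else 1),
        StageSpec(768 // d, [BlockGroupSpec("ECB", 768 // d, 1),
                             BlockGroupSpec("LTB", 1024 // d, 1)]),
    ]
    conv = BlockConventions(head_dim=4, esa_pool_strides=(8, 4, 2, 1),
                            ecb_expansion=_CONVENTIONS.ecb_expansion,
                            ltb_expansion=_CONVENTIONS.ltb_expansion)
    stem = [ConvSpec(3, 64 // d, 2), ConvSpec(3, 32 // d, 1),
            ConvSpec(3, 64 // d, 1), ConvSpec(3, 64 // d, 2)]
    return ModelSpec(name=f"reduced-{kind}", stem=stem, stages=stages,
                     path_dropout=0.05 if kind == "micro" else 0.1,
                     num_classes=num_classes, conventions=conv)


def get_spec(kind: str, num_classes: int = 3) -> ModelSpec:
    if kind == "micro":
        return micro_spec(num_classes)
    if kind == "tiny":
        return tiny_spec(num_classes)
    if kind in ("reduced", "reduced-micro"):
        return reduced_spec("micro", num_classes)
    if kind == "reduced-tiny":
        return reduced_spec("tiny", num_classes)
    raise ConfigurationError(f"unknown model kind {kind!r}")
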