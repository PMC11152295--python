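"""Hybrid convolution/transformer backbone blocks and the model builder.

The backbone family interleaves two block kinds inside a 4-stage pyramid:

* **ECB** (efficient convolutional block): multi-head convolutional
  attention (MHCA) followed by a locally-enhanced feed-forward network
  (LFFN), each behind a pre-norm residual branch with stochastic depth.
* **LTB** (local transformer block): an efficient self-attention (ESA)
  whose keys/values are average-pooled to cut token count, then MHCA and
  LFFN, again as pre-norm residual branches.

MHCA realizes per-head "convolutional attention": each head aggregates a
token with its 3x3 neighbourhood through learnable weights (a grouped 3x3
convolution with one group per head), the head outputs are concatenated
and mixed by a 1x1 output projection W^O.  ESA is standard scaled
dot-product attention with queries from all tokens and keys/values taken
from an average-pooled (stride s) copy of the feature map.

A declarative :class:`~octstitch.specs.ModelSpec` is turned into a runnable
network by :func:`build_medvit`; :func:`count_parameters` reports exact
trainable-scalar counts, which for the micro/tiny specifications with a
3-class head reproduce the published 24.50M / 31.14M figures.
"""
from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .specs import ConfigurationError, ModelSpec, get_spec


class ConvBNReLU(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, kernel, stride=stride,
                              bias=False)
        self.norm = nn.BatchNorm2d(out_ch)
        self.act = nn.ReLU()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.norm(self.conv(x)))


class MHCA(nn.Module):
    """Multi-head convolutional attention.

    Head h sees a `head_dim`-channel slice of the input; its learnable
    weights aggregate every token with its adjacent (3x3) tokens.  Heads
    are concatenated (implicitly, by the grouped convolution layout) and
    mixed by the 1x1 output projection.
    """

    def __init__(self, dim: int, head_dim: int, block_name: str = "MHCA"):
        super().__init__()
        if dim % head_dim:
            raise ConfigurationError(
                f"{block_name}: channel count {dim} not divisible by "
                f"head_dim {head_dim}")
        self.heads = dim // head_dim
        self.aggregate = nn.Conv2d(dim, dim, 3, groups=self.heads,
                                   bias=False)
        self.norm = nn.BatchNorm2d(dim)
        self.act = nn.ReLU()
        self.project = nn.Conv2d(dim, dim, 1, bias=True)
        self.project.weight.data[...] = 0.0  # branch starts as identity

    def forward(self, x: Tensor) -> Tensor:
        return self.project(self.act(self.norm(self.aggregate(x))))


class ESA(nn.Module):
    """Efficient self-attention: pooled keys/values, full-resolution queries.

    With pool_stride 1 this is exactly standard multi-head self-attention.
    If the feature map is not divisible by the configured stride the
    pooling falls back to identity (only relevant far off the published
    224x224 geometry).
    """

    def __init__(self, dim: int, head_dim: int, pool_stride: int = 1,
                 qkv_bias: bool = True, block_name: str = "ESA"):
        super().__init__()
        if dim % head_dim:
            raise ConfigurationError(
                f"{block_name}: channel count {dim} not divisible by "
                f"head_dim {head_dim}")
        self.dim = dim
        self.heads = dim // head_dim
        self.head_dim = head_dim
        self.pool_stride = pool_stride
        self.q = nn.Linear(dim, dim, bias=qkv_bias)
        self.k = nn.Linear(dim, dim, bias=qkv_bias)
        self.v = nn.Linear(dim, dim, bias=qkv_bias)
        self.project = nn.Linear(dim, dim, bias=True)
        self.project.weight.data[...] = 0.0  # branch starts as identity

    def _tokens(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        return x.reshape(b, c, h * w).transpose(0, 2, 1)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        s = self.pool_stride
        if s > 1 and (h % s or w % s):
            s = 1
        tok = self._tokens(x)                              # (B, T, C)
        kv_src = self._tokens(nn.avg_pool2d(x, s)) if s > 1 else tok
        nh, hd = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(t.shape[0], t.shape[1], nh, hd).transpose(
                0, 2, 1, 3)                                # (B, h, T, d)

        q = split(self.q(tok))
        k = split(self.k(kv_src))
        v = split(self.v(kv_src))
        attn = nn.softmax((q @ k.transpose(0, 1, 3, 2)) * (hd ** -0.5))
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, h * w, c)
        out = self.project(out)
        return out.transpose(0, 2, 1).reshape(b, c, h, w)


class LFFN(nn.Module):
    """Locally-enhanced feed-forward: 1x1 expand -> 3x3 depthwise -> 1x1."""

    def __init__(self, dim: int, expansion: float):
        super().__init__()
        hidden = int(round(dim * expansion))
        self.expand = nn.Conv2d(dim, hidden, 1, bias=True)
        self.dwc = nn.Conv2d(hidden, hidden, 3, groups=hidden, bias=True)
        self.act = nn.ReLU()
        self.project = nn.Conv2d(hidden, dim, 1, bias=True)
        self.project.weight.data[...] = 0.0  # branch starts as identity

    def forward(self, x: Tensor) -> Tensor:
        return self.project(self.act(self.dwc(self.expand(x))))


class _ChannelAdapt(nn.Module):
    """1x1 projection used when a block's input width differs from its dim."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 1, bias=False)
        self.norm = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x))


class ECB(nn.Module):
    def __init__(self, in_channels: int, dim: int, path_dropout: float,
                 head_dim: int, expansion: float, name: str = "ECB"):
        super().__init__()
        self.dim = dim
        self.adapt = (_ChannelAdapt(in_channels, dim)
                      if in_channels != dim else nn.Identity())
        self.norm1 = nn.BatchNorm2d(dim)
        self.mhca = MHCA(dim, head_dim, block_name=name)
        self.drop1 = nn.DropPath(path_dropout)
        self.norm2 = nn.BatchNorm2d(dim)
        self.lffn = LFFN(dim, expansion)
        self.drop2 = nn.DropPath(path_dropout)

    def forward(self, x: Tensor) -> Tensor:
        x = self.adapt(x)
        x = x + self.drop1(self.mhca(self.norm1(x)))
        x = x + self.drop2(self.lffn(self.norm2(x)))
        return x


class LTB(nn.Module):
    def __init__(self, in_channels: int, dim: int, path_dropout: float,
                 head_dim: int, expansion: float, pool_stride: int,
                 qkv_bias: bool, name: str = "LTB"):
        super().__init__()
        self.dim = dim
        self.adapt = (_ChannelAdapt(in_channels, dim)
                      if in_channels != dim else nn.Identity())
        self.norm0 = nn.BatchNorm2d(dim)
        self.esa = ESA(dim, head_dim, pool_stride, qkv_bias, block_name=name)
        self.drop0 = nn.DropPath(path_dropout)
        self.norm1 = nn.BatchNorm2d(dim)
        self.mhca = MHCA(dim, head_dim, block_name=name)
        self.drop1 = nn.DropPath(path_dropout)
        self.norm2 = nn.BatchNorm2d(dim)
        self.lffn = LFFN(dim, expansion)
        self.drop2 = nn.DropPath(path_dropout)

    def forward(self, x: Tensor) -> Tensor:
        x = self.adapt(x)
        x = x + self.drop0(self.esa(self.norm0(x)))
        x = x + self.drop1(self.mhca(self.norm1(x)))
        x = x + self.drop2(self.lffn(self.norm2(x)))
        return x


class PatchEmbed(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, pool_stride: int):
        super().__init__()
        self.pool = (nn.AvgPool2d(pool_stride) if pool_stride > 1
                     else nn.Identity())
        self.conv = nn.Conv2d(in_ch, out_ch, 1, bias=False)
        self.norm = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(self.pool(x)))


class BlockInfo:
    """Metadata for one flattened block (1-based depth index)."""

    __slots__ = ("index", "stage", "index_in_stage", "kind", "dim",
                 "in_channels", "stride_so_far")

    def __init__(self, index, stage, index_in_stage, kind, dim, in_channels,
                 stride_so_far):
        self.index = index
        self.stage = stage
        self.index_in_stage = index_in_stage
        self.kind = kind
        self.dim = dim
        self.in_channels = in_channels
        self.stride_so_far = stride_so_far

    def __repr__(self) -> str:  # pragma: no cover
        return (f"BlockInfo({self.index}: stage {self.stage} "
                f"{self.kind}{self.dim})")


class MedViT(nn.Module):
    """The assembled backbone: stem -> 4 stages -> pooled classifier head."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        spec.validate()
        self.spec = spec
        conv = spec.conventions

        chans = spec.input_channels
        stem_layers = []
        for cs in spec.stem:
            stem_layers.append(ConvBNReLU(chans, cs.out_channels, cs.kernel,
                                          cs.stride))
            chans = cs.out_channels
        self.stem = nn.Sequential(*stem_layers)

        self.embeds: list[nn.Module] = []
        self.blocks: list[nn.Module] = []
        self.block_infos: list[BlockInfo] = []
        self._stage_of_block: list[int] = []
        stride = int(np.prod([c.stride for c in spec.stem]))
        flat = 0
        for si, stage in enumerate(spec.stages):
            self.embeds.append(PatchEmbed(chans, stage.embed_channels,
                                          stage.pool_stride))
            stride *= stage.pool_stride
            chans = stage.embed_channels
            for bi, (kind, dim) in enumerate(stage.block_dims()):
                flat += 1
                name = f"stage{si + 1}.{kind}{dim}[{bi + 1}]"
                if kind == "ECB":
                    block = ECB(chans, dim, spec.path_dropout, conv.head_dim,
                                conv.ecb_expansion, name=name)
                else:
                    block = LTB(chans, dim, spec.path_dropout, conv.head_dim,
                                conv.ltb_expansion,
                                conv.esa_pool_strides[si], conv.qkv_bias,
                                name=name)
                self.blocks.append(block)
                self.block_infos.append(BlockInfo(
                    flat, si + 1, bi + 1, kind, dim, chans, stride))
                self._stage_of_block.append(si + 1)
                chans = dim
        self.out_channels = chans
        self.head_norm = nn.LayerNorm(chans)
        self.head = nn.Linear(chans, spec.num_classes)
        self._stage_first_block: dict[int, int] = {}
        for info in self.block_infos:
            self._stage_first_block.setdefault(info.stage, info.index)

    # -- execution --------------------------------------------------------
    def num_blocks(self, stage: int | None = None) -> int:
        if stage is None:
            return len(self.blocks)
        return sum(1 for s in self._stage_of_block if s == stage)

    def forward_features(self, x: Tensor) -> Tensor:
        return self.run_prefix(x, len(self.blocks))

    def run_prefix(self, x: Tensor, last_block: int) -> Tensor:
        """Stem + everything up to and including flat block `last_block`."""
        if not 1 <= last_block <= len(self.blocks):
            raise ConfigurationError(
                f"block index {last_block} out of range "
                f"1..{len(self.blocks)}")
        x = self.stem(x)
        for i, block in enumerate(self.blocks, start=1):
            stage = self._stage_of_block[i - 1]
            if i == self._stage_first_block[stage]:
                x = self.embeds[stage - 1](x)
            x = block(x)
            if i == last_block:
                return x
        return x

    def run_suffix(self, x: Tensor, first_block: int) -> Tensor:
        """Execute from flat block `first_block` through the head."""
        if not 1 <= first_block <= len(self.blocks):
            raise ConfigurationError(
                f"block index {first_block} out of range "
                f"1..{len(self.blocks)}")
        for i in range(first_block, len(self.blocks) + 1):
            stage = self._stage_of_block[i - 1]
            if i == self._stage_first_block[stage] and i != first_block:
                x = self.embeds[stage - 1](x)
            x = self.blocks[i - 1](x)
        return self.classify(x)

    def classify(self, feats: Tensor) -> Tensor:
        pooled = feats.mean(axis=(2, 3))
        return self.head(self.head_norm(pooled))

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        return self.classify(self.forward_features(x))


def build_medvit(spec: ModelSpec | str, seed: int | None = None,
                 num_classes: int = 3) -> MedViT:
    """Build a runnable network from a spec or a named variant."""
    if isinstance(spec, str):
        spec = get_spec(spec, num_classes=num_classes)
    if seed is not None:
        nn.manual_seed(seed)
    return MedViT(spec)


def count_parameters(model: nn.Module) -> int:
    """Exact count of trainable scalar parameters."""
    return sum(p.data.size for p in model.parameters())


def parameters_millions(model: nn.Module) -> float:
    """Count in millions, rounded to two decimals (reporting convention)."""
    return round(count_parameters(model) / 1e6, 2)
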