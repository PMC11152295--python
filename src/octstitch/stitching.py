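"""Model stitching: candidate enumeration, least-squares stitch-layer
initialization, and random-path training of the stitching space.

Two pre-trained anchors (a smaller *front* model and a larger *back*
model) are connected by 1x1 linear stitch layers.  A candidate
configuration (n, m) runs the front anchor through block n, maps its
activation into the activation space of the back anchor's block m-1 with
the stitch, and continues through the back anchor from block m to its
classifier.  Candidates are enumerated per stage — a 1x1 stitch cannot
change spatial resolution, so cuts pair only blocks at the same pyramid
level — with the paired (sliding window, k=2, s=1) strategy for stages of
equal depth and the unpaired proportional-bucket strategy when the back
stage is deeper.  Every second candidate can be pruned (odd original
indexes dropped) to halve the search space.

Stitch layers are initialized by the closed-form least-squares map between
front and back activations collected on a mini-batch (default 100
samples), then the whole space is trained by drawing one configuration
uniformly at random per step and updating only the active path.
"""
from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .architecture import MedViT
from .specs import ConfigurationError
from .training import (FocalLossParams, NormalizationParams,
                       NEH_NORMALIZATION, OCTDataset, focal_loss,
                       inverse_frequency_alpha, prepare_batch)


# ---------------------------------------------------------------------------
# Anchors
# ---------------------------------------------------------------------------

@dataclass
class Anchor:
    """A pre-trained network registered as an endpoint of the space."""
    anchor_id: int
    model: MedViT
    name: str = ""

    @property
    def cut_points(self) -> list:
        return self.model.block_infos

    def num_blocks(self, stage: int | None = None) -> int:
        return self.model.num_blocks(stage)

    def clone(self) -> "Anchor":
        model = MedViT(copy.deepcopy(self.model.spec))
        model.load_state_dict(self.model.state_dict())
        return Anchor(self.anchor_id, model, self.name)


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_paired(len_a: int, len_b: int) -> list[tuple[int, int]]:
    """Sliding window (k=2, s=1) over aligned depth positions.

    Yields (n, m) with n the window start in the front anchor and m the
    window end in the back anchor; len_a - 1 candidates in total.
    """
    if len_a != len_b:
        raise ConfigurationError(
            f"paired enumeration requires equal lengths, got "
            f"{len_a} != {len_b}; use the unpaired strategy")
    return [(n, n + 1) for n in range(1, len_a)]


def enumerate_unpaired(len_a: int, len_b: int) -> list[tuple[int, int]]:
    """Proportional-bucket matching for a shallower front anchor.

    Front block n is assigned the back positions
    {j : floor((j-1) * len_a / len_b) = n - 1}; each (n, j) produces the
    candidate (n, m = j + 1), kept while m <= len_b.
    """
    if len_a >= len_b:
        raise ConfigurationError(
            f"unpaired enumeration requires len_a < len_b, got "
            f"{len_a} >= {len_b}")
    out = []
    for j in range(1, len_b + 1):
        n = (j - 1) * len_a // len_b + 1
        m = j + 1
        if m <= len_b:
            out.append((n, m))
    return out


# ---------------------------------------------------------------------------
# Stitch layers and configurations
# ---------------------------------------------------------------------------

class StitchLayer(nn.Module):
    """Per-position linear map (1x1 convolution) between activation spaces."""

    def __init__(self, in_channels: int, out_channels: int):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.conv = nn.Conv2d(in_channels, out_channels, 1, bias=True)
        self.initialized = False

    def set_weights(self, weight: np.ndarray, bias: np.ndarray) -> None:
        self.conv.weight.data = weight.astype(np.float32).reshape(
            self.out_channels, self.in_channels, 1, 1)
        self.conv.bias.data = bias.astype(np.float32)
        self.initialized = True

    def set_identity(self) -> None:
        if self.in_channels != self.out_channels:
            raise ConfigurationError(
                "identity stitch requires equal channel counts")
        self.set_weights(np.eye(self.in_channels, dtype=np.float32),
                         np.zeros(self.in_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


def init_stitch_least_squares(acts_front: np.ndarray,
                              acts_back: np.ndarray) -> StitchLayer:
    """Closed-form least-squares stitch from matched activation matrices.

    Both matrices are (N_tokens, channels) from the same mini-batch.  The
    affine map minimizing ||[A 1] W - B||_F is found with the
    pseudo-inverse (minimum-norm for rank-deficient inputs, with a
    warning).
    """
    A = np.asarray(acts_front, dtype=np.float64)
    B = np.asarray(acts_back, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2:
        raise ValueError("activation matrices must be 2-d (tokens, channels)")
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"token count mismatch: front {A.shape[0]} vs back {B.shape[0]}")
    ones = np.ones((A.shape[0], 1))
    A1 = np.hstack([A, ones])
    sol, _, rank, _ = np.linalg.lstsq(A1, B, rcond=None)
    if rank < A1.shape[1]:
        warnings.warn(
            f"rank-deficient activations (rank {rank} < {A1.shape[1]}); "
            "using the minimum-norm least-squares solution", RuntimeWarning)
    weight = sol[:-1].T            # (d_back, d_front)
    bias = sol[-1]
    layer = StitchLayer(A.shape[1], B.shape[1])
    layer.set_weights(weight, bias)
    return layer


@dataclass
class StitchConfig:
    """One candidate network: cut n in the front anchor, entry m in the back."""
    config_id: int
    raw_index: int
    cut_index: int          # flat block index n in the front anchor
    entry_index: int        # flat block index m in the back anchor
    stage: int
    stitch: StitchLayer


class StitchingSpace(nn.Module):
    """The indexed candidate set between one front and one back anchor."""

    def __init__(self, front: Anchor, back: Anchor,
                 configs: list[StitchConfig], pruned: bool):
        super().__init__()
        self.front = front
        self.back = back
        self.configs = configs
        self.pruned = pruned
        # expose trainable parts to the Module registry
        self.front_model = front.model
        self.back_model = back.model
        self.stitches = [c.stitch for c in configs]

    def __len__(self) -> int:
        return len(self.configs)

    def get_config(self, config_id: int) -> StitchConfig:
        if not 0 <= config_id < len(self.configs):
            raise ConfigurationError(
                f"config_id {config_id} outside 0..{len(self.configs) - 1}")
        return self.configs[config_id]

    # -- initialization ---------------------------------------------------
    def initialize_stitches(self, images: np.ndarray,
                            normalization: NormalizationParams
                            = NEH_NORMALIZATION,
                            batch_size: int = 100) -> None:
        """Least-squares-initialize every stitch from matched activations.

        `images` is a (n, H, W) unit-scaled stack; the first `batch_size`
        samples form the initialization mini-batch.
        """
        xb = prepare_batch(images[:batch_size], normalization)
        self.front_model.eval()
        self.back_model.eval()
        with nn.no_grad():
            for cfg in self.configs:
                a = self.front_model.run_prefix(Tensor(xb), cfg.cut_index)
                b = self.back_model.run_prefix(Tensor(xb),
                                               cfg.entry_index - 1)
                A = a.data.transpose(0, 2, 3, 1).reshape(-1, a.shape[1])
                B = b.data.transpose(0, 2, 3, 1).reshape(-1, b.shape[1])
                layer = init_stitch_least_squares(A, B)
                cfg.stitch.set_weights(
                    layer.conv.weight.data.reshape(layer.out_channels,
                                                   layer.in_channels),
                    layer.conv.bias.data)

    # -- execution --------------------------------------------------------
    def forward(self, x, config_id: int) -> Tensor:
        cfg = self.get_config(config_id)
        if not cfg.stitch.initialized:
            raise ConfigurationError(
                f"stitch for config {config_id} is not initialized; call "
                "initialize_stitches() first")
        if not isinstance(x, Tensor):
            x = Tensor(x)
        a = self.front_model.run_prefix(x, cfg.cut_index)
        return self.back_model.run_suffix(cfg.stitch(a), cfg.entry_index)

    def recalibrate_bn(self, images: np.ndarray, config_id: int,
                       normalization: NormalizationParams = NEH_NORMALIZATION,
                       n_batches: int = 8, batch_size: int = 32) -> None:
        """Re-estimate batch-norm running statistics for one configuration.

        The anchors' norm layers are shared by every candidate, so their
        running statistics reflect a mixture of stitched input
        distributions; before evaluating a candidate they are re-estimated
        on forwards through that candidate's path (norm layers in batch
        mode, everything else — notably stochastic depth — in eval mode).
        """
        from .nn.layers import BatchNorm2d

        bns = [m for m in self.modules() if isinstance(m, BatchNorm2d)]
        self.front_model.eval()
        self.back_model.eval()
        for m in bns:
            m.training = True
            m.running_mean[...] = 0.0
            m.running_var[...] = 1.0
        saved = [m.momentum for m in bns]
        try:
            with nn.no_grad():
                for k in range(n_batches):
                    lo = k * batch_size
                    if lo >= len(images):
                        break
                    for m in bns:
                        m.momentum = 1.0 / (k + 1)   # exact running average
                    xb = prepare_batch(images[lo:lo + batch_size],
                                       normalization)
                    self(xb, config_id)
        finally:
            for m, mom in zip(bns, saved):
                m.momentum = mom
                m.training = False

    def predict_proba(self, images: np.ndarray, config_id: int,
                      normalization: NormalizationParams = NEH_NORMALIZATION,
                      batch_size: int = 64) -> np.ndarray:
        self.front_model.eval()
        self.back_model.eval()
        outs = []
        with nn.no_grad():
            for i in range(0, len(images), batch_size):
                xb = prepare_batch(images[i:i + batch_size], normalization)
                outs.append(nn.softmax(self(xb, config_id)).data)
        return np.concatenate(outs, axis=0)

    # -- reporting --------------------------------------------------------
    def stitched_parameter_count(self, config_id: int) -> int:
        """Exact parameter count of the assembled candidate network."""
        cfg = self.get_config(config_id)
        fm, bm = self.front_model, self.back_model
        total = sum(p.data.size for p in fm.stem.parameters())
        front_stage = fm.block_infos[cfg.cut_index - 1].stage
        for si in range(front_stage):
            total += sum(p.data.size for p in fm.embeds[si].parameters())
        for info in fm.block_infos[:cfg.cut_index]:
            total += sum(p.data.size
                         for p in fm.blocks[info.index - 1].parameters())
        total += sum(p.data.size for p in cfg.stitch.parameters())
        back_stage = bm.block_infos[cfg.entry_index - 1].stage
        for info in bm.block_infos[cfg.entry_index - 1:]:
            total += sum(p.data.size
                         for p in bm.blocks[info.index - 1].parameters())
        for si in range(back_stage, len(bm.embeds)):
            total += sum(p.data.size for p in bm.embeds[si].parameters())
        total += sum(p.data.size for p in bm.head_norm.parameters())
        total += sum(p.data.size for p in bm.head.parameters())
        return total

    def manifest(self) -> pd.DataFrame:
        """Per-config listing: (n, m), stage, stitch dims, parameter count."""
        rows = []
        for cfg in self.configs:
            rows.append({
                "config_id": cfg.config_id,
                "raw_index": cfg.raw_index,
                "stage": cfg.stage,
                "cut_index": cfg.cut_index,
                "entry_index": cfg.entry_index,
                "stitch_in": cfg.stitch.in_channels,
                "stitch_out": cfg.stitch.out_channels,
                "params": self.stitched_parameter_count(cfg.config_id),
                "params_millions": round(
                    self.stitched_parameter_count(cfg.config_id) / 1e6, 2),
            })
        return pd.DataFrame(rows)


def build_space(front: Anchor, back: Anchor, prune: bool = True
                ) -> StitchingSpace:
    """Enumerate all same-stage candidates between two anchors.

    Stages of equal depth use the paired strategy, a deeper back stage the
    unpaired strategy.  With `prune`, candidates at odd original indexes
    are removed and survivors re-indexed from 0.
    """
    fm, bm = front.model, back.model
    if fm.spec.input_channels != bm.spec.input_channels:
        raise ConfigurationError("anchors must share input geometry")
    raw: list[tuple[int, int, int]] = []       # (stage, n_global, m_global)
    f_offset = b_offset = 0
    for stage in range(1, 5):
        la = fm.num_blocks(stage)
        lb = bm.num_blocks(stage)
        pairs = (enumerate_paired(la, lb) if la == lb
                 else enumerate_unpaired(la, lb))
        for n_in, m_in in pairs:
            raw.append((stage, f_offset + n_in, b_offset + m_in))
        f_offset += la
        b_offset += lb
    if not raw:
        raise ConfigurationError(
            "no valid stitching candidates between these anchors")
    kept = [(i, c) for i, c in enumerate(raw)
            if (not prune) or i % 2 == 0]
    configs = []
    for new_id, (raw_idx, (stage, n, m)) in enumerate(kept):
        d_front = fm.block_infos[n - 1].dim
        d_back = bm.block_infos[m - 2].dim
        configs.append(StitchConfig(new_id, raw_idx, n, m, stage,
                                    StitchLayer(d_front, d_back)))
    return StitchingSpace(front, back, configs, prune)


# ---------------------------------------------------------------------------
# Random-path training (the stitching phase)
# ---------------------------------------------------------------------------

def uniform_config_draws(n_configs: int, iterations: int,
                         rng: np.random.Generator) -> np.ndarray:
    """The training loop's uniform per-step configuration selections."""
    if n_configs < 1:
        raise ConfigurationError("need at least one configuration")
    return rng.integers(0, n_configs, size=iterations)

@dataclass
class StitchTrainConfig:
    iterations: int = 1000
    batch_size: int = 32
    lr: float = 5e-5
    reference_batch: int = 32     # lr scales linearly with batch size
    weight_decay: float = 0.01
    gamma: float = 2.0
    freeze_anchors: bool = False
    seed: int = 0
    normalization: NormalizationParams = field(
        default_factory=lambda: NEH_NORMALIZATION)

    @classmethod
    def toy(cls, seed: int = 0, **overrides) -> "StitchTrainConfig":
        """Desk-scale preset matching PretrainConfig.toy()."""
        base = dict(iterations=200, lr=1e-3, seed=seed)
        base.update(overrides)
        return cls(**base)


def train_stitched(space: StitchingSpace, dataset: OCTDataset,
                   config: StitchTrainConfig | None = None
                   ) -> list[dict]:
    """Algorithm: per step draw one config uniformly, train its active path.

    All parameters on the active path (front prefix, stitch, back suffix)
    receive updates unless `freeze_anchors`, in which case only the stitch
    trains.  The learning rate is scaled linearly with batch size and
    cosine-annealed to zero over the iterations.  Returns the step log.
    """
    config = config or StitchTrainConfig()
    if len(space) == 0:
        raise ConfigurationError("cannot train an empty stitching space")
    for cfg in space.configs:
        if not cfg.stitch.initialized:
            raise ConfigurationError(
                f"stitch for config {cfg.config_id} is not initialized; "
                "call initialize_stitches() first")
    rng = np.random.default_rng(config.seed)
    nn.manual_seed(config.seed)     # drives stochastic-depth draws
    if config.freeze_anchors:
        params = [p for s in space.stitches for p in s.parameters()]
    else:
        params = space.parameters()
    lr = config.lr * config.batch_size / config.reference_batch
    opt = nn.AdamW(params, lr=lr, weight_decay=config.weight_decay)
    sched = nn.CosineAnnealingLR(opt, t_max=config.iterations)
    alpha = inverse_frequency_alpha(dataset.labels, dataset.n_classes)
    loss_params = FocalLossParams(gamma=config.gamma, alpha=alpha)

    n = len(dataset)
    draws = uniform_config_draws(len(space), config.iterations, rng)
    order = rng.permutation(n)
    pos = 0
    log = []
    space.front_model.train()
    space.back_model.train()
    for step in range(config.iterations):
        if pos + config.batch_size > n:
            order = rng.permutation(n)
            pos = 0
        sel = order[pos:pos + config.batch_size]
        pos += config.batch_size
        cid = int(draws[step])
        xb = prepare_batch(dataset.images[sel], config.normalization)
        yb = dataset.labels[sel]
        opt.zero_grad()
        loss = focal_loss(space(xb, cid), yb, loss_params)
        loss.backward()
        opt.step()
        log.append({"step": step, "config_id": cid, "loss": loss.item(),
                    "lr": opt.lr})
        sched.step()
    return log
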