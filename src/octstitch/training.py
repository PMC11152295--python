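"""Losses, augmentation, normalization and the anchor pre-training loop.

Pre-training follows a fixed recipe: an 80/20 stratified train/validation
split, focal loss with inverse-frequency class weights under AdamW, a step
learning-rate schedule (x0.1 at epoch 50 by default), and checkpointing of
the model whenever the validation macro one-vs-rest AUC reaches a new best
(ties favour the later epoch).
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from . import nn
from .nn import Tensor
from .architecture import MedViT, build_medvit
from .specs import ModelSpec, get_spec
from .synthetic import CLASS_NAMES


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

@dataclass
class FocalLossParams:
    """gamma: focusing exponent; alpha: per-class weights (None = uniform)."""
    gamma: float = 2.0
    alpha: np.ndarray | None = None
    reduction: str = "mean"

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


def focal_loss(logits: Tensor, labels: np.ndarray,
               params: FocalLossParams | None = None) -> Tensor:
    """Multiclass focal loss -alpha_y (1 - p_y)^gamma log p_y.

    With gamma = 0 and uniform alpha this is exactly cross-entropy.
    """
    params = params or FocalLossParams()
    labels = np.asarray(labels)
    n, k = logits.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(
            f"label index out of range for {k} classes: "
            f"[{labels.min()}, {labels.max()}]")
    logp = nn.log_softmax(logits)
    lp_y = nn.gather_rows(logp, labels)          # (n,)
    p_y = nn.exp(lp_y)
    focal = (1.0 - p_y) ** params.gamma if params.gamma != 0 else 1.0
    loss = -(focal * lp_y)
    if params.alpha is not None:
        alpha = np.asarray(params.alpha, dtype=np.float32)
        if alpha.shape != (k,):
            raise ValueError(f"alpha must have one weight per class ({k})")
        loss = loss * Tensor(alpha[labels])
    return loss.mean() if params.reduction == "mean" else loss.sum()


def inverse_frequency_alpha(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class weights proportional to 1/frequency, normalized to mean 1."""
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    w = 1.0 / counts
    return (w / w.mean()).astype(np.float32)


# ---------------------------------------------------------------------------
# Augmentation and normalization
# ---------------------------------------------------------------------------

@dataclass
class AugmentationParams:
    """Default ranges of the random affine / jitter / flip pipeline."""
    rotation: tuple[float, float] = (-20.0, 20.0)       # degrees
    translate: tuple[float, float] = (0.05, 0.2)        # max |dx|/W, |dy|/H
    shear: tuple[float, float] = (-10.0, 10.0)          # degrees
    scale: tuple[float, float] = (0.8, 1.2)
    brightness: tuple[float, float] = (0.8, 1.2)
    contrast: tuple[float, float] = (0.8, 1.2)
    saturation: tuple[float, float] = (0.8, 1.2)
    hflip_prob: float = 0.5


@dataclass
class NormalizationParams:
    mean: float
    std: float

    def __post_init__(self):
        if self.std <= 0:
            raise ValueError("normalization std must be > 0")


NEH_NORMALIZATION = NormalizationParams(0.13, 0.194)
UCSD_NORMALIZATION = NormalizationParams(0.19, 0.215)


def normalize(image: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """(pixel - mean) / std, identically per channel."""
    return ((np.asarray(image, dtype=np.float32) - params.mean)
            / params.std).astype(np.float32)


def denormalize(image: np.ndarray, params: NormalizationParams) -> np.ndarray:
    return (np.asarray(image, dtype=np.float32) * params.std
            + params.mean).astype(np.float32)


def _affine_matrix(angle_deg: float, tx: float, ty: float, shear_deg: float,
                   scale: float, center: tuple[float, float]) -> np.ndarray:
    """Forward 3x3 affine (rotation/shear/scale about center + translation)."""
    a = np.deg2rad(angle_deg)
    sh = np.deg2rad(shear_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    shear = np.array([[1.0, -np.tan(sh)], [0.0, 1.0]])
    lin = scale * rot @ shear
    cy, cx = center
    m = np.eye(3)
    m[:2, :2] = lin
    m[:2, 2] = [cy - lin[0, 0] * cy - lin[0, 1] * cx + ty,
                cx - lin[1, 0] * cy - lin[1, 1] * cx + tx]
    return m


def sample_affine_params(params: AugmentationParams,
                         rng: np.random.Generator,
                         width: int, height: int
                         ) -> tuple[float, float, float, float, float]:
    """Draw (angle, tx, ty, shear, scale) for one random-affine call."""
    angle = rng.uniform(*params.rotation)
    max_dx, max_dy = params.translate[0] * width, params.translate[1] * height
    tx = rng.uniform(-max_dx, max_dx)
    ty = rng.uniform(-max_dy, max_dy)
    shear = rng.uniform(*params.shear)
    scale = rng.uniform(*params.scale)
    return angle, tx, ty, shear, scale


def augment(image: np.ndarray,
            params: AugmentationParams | None = None,
            rng: np.random.Generator | int | None = None,
            normalization: NormalizationParams = NEH_NORMALIZATION,
            channels: int = 3) -> np.ndarray:
    """Random affine -> jitter -> horizontal flip -> normalize.

    Input: unit-scaled grayscale (H, W).  Output: (channels, H, W) float32
    with the grayscale plane replicated across channels after
    normalization.  Saturation jitter is sampled for stream stability but
    is the identity on replicated-grayscale images.
    """
    params = params or AugmentationParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    img = np.asarray(image, dtype=np.float32)
    h, w = img.shape

    angle, tx, ty, shear, scale = sample_affine_params(params, rng, w, h)
    identity = (angle == 0 and tx == 0 and ty == 0 and shear == 0
                and scale == 1)
    if not identity:
        m = _affine_matrix(angle, tx, ty, shear, scale,
                           ((h - 1) / 2.0, (w - 1) / 2.0))
        inv = np.linalg.inv(m)
        img = ndimage.affine_transform(img, inv[:2, :2], inv[:2, 2],
                                       order=1, mode="constant", cval=0.0)

    b = rng.uniform(*params.brightness)
    c = rng.uniform(*params.contrast)
    _s = rng.uniform(*params.saturation)   # identity on grayscale
    if b != 1:
        img = np.clip(img * b, 0.0, 1.0)
    if c != 1:
        mean = img.mean()
        img = np.clip((img - mean) * c + mean, 0.0, 1.0)
    if rng.random() < params.hflip_prob:
        img = img[:, ::-1]

    img = normalize(img, normalization)
    return np.broadcast_to(img, (channels, h, w)).copy()


def prepare_batch(images: np.ndarray,
                  normalization: NormalizationParams = NEH_NORMALIZATION,
                  channels: int = 3) -> np.ndarray:
    """Normalize + replicate a (n, H, W) stack to (n, channels, H, W)."""
    imgs = normalize(images, normalization)
    return np.repeat(imgs[:, None, :, :], channels, axis=1)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class OCTDataset:
    """In-memory labelled image stack (unit-scaled grayscale)."""
    images: np.ndarray                       # (n, H, W) in [0, 1]
    labels: np.ndarray                       # (n,) int
    patient_ids: np.ndarray | None = None
    class_names: tuple[str, ...] = CLASS_NAMES
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx: np.ndarray, name: str | None = None
               ) -> "OCTDataset":
        return OCTDataset(self.images[idx], self.labels[idx],
                          None if self.patient_ids is None
                          else self.patient_ids[idx],
                          self.class_names, name or self.name)

    @classmethod
    def from_synthetic(cls, n: int, side: int = 224, seed: int = 0,
                       proportions=None, name: str = "synthetic"
                       ) -> "OCTDataset":
        from .synthetic import (DEFAULT_PROPORTIONS, SyntheticOCTParams,
                                generate_samples, to_arrays)
        X, y, groups = to_arrays(generate_samples(
            n, proportions or DEFAULT_PROPORTIONS,
            SyntheticOCTParams(side=side), seed=seed))
        return cls(X, y, groups, CLASS_NAMES, name)

    @classmethod
    def from_folder(cls, root: str | os.PathLike, side: int = 224,
                    name: str | None = None) -> "OCTDataset":
        """Read a class-per-subdirectory image folder, grayscale-resized."""
        root = os.fspath(root)
        subdirs = sorted(d for d in os.listdir(root)
                         if os.path.isdir(os.path.join(root, d)))
        if not subdirs:
            raise FileNotFoundError(f"no class subdirectories under {root}")
        if set(subdirs) == set(CLASS_NAMES):
            classes = list(CLASS_NAMES)
        else:
            classes = subdirs
        manifest_path = os.path.join(root, "manifest.csv")
        patients = {}
        if os.path.exists(manifest_path):
            mf = pd.read_csv(manifest_path)
            patients = {os.path.basename(p): pid for p, pid in
                        zip(mf["path"], mf["patient_id"])}
        images, labels, pids = [], [], []
        for li, cname in enumerate(classes):
            cdir = os.path.join(root, cname)
            for fname in sorted(os.listdir(cdir)):
                if not fname.lower().endswith((".png", ".jpg", ".jpeg",
                                               ".tif", ".tiff")):
                    continue
                with Image.open(os.path.join(cdir, fname)) as im:
                    im = im.convert("L").resize((side, side),
                                                Image.BILINEAR)
                    images.append(np.asarray(im, dtype=np.float32) / 255.0)
                labels.append(li)
                pids.append(patients.get(fname, f"unknown_{len(pids)}"))
        return cls(np.stack(images), np.asarray(labels, dtype=np.int64),
                   np.asarray(pids), tuple(classes),
                   name or os.path.basename(root))


# ---------------------------------------------------------------------------
# Pre-training (anchor training with best-AUC checkpointing)
# ---------------------------------------------------------------------------

@dataclass
class PretrainConfig:
    epochs: int = 75
    batch_size: int = 32
    lr: float = 5e-5
    decay_factor: float = 0.1
    milestones: tuple[int, ...] = (50,)
    weight_decay: float = 0.01
    gamma: float = 2.0                      # focal-loss exponent
    val_fraction: float = 0.2
    seed: int = 0
    augment: bool = True
    augmentation: AugmentationParams = field(default_factory=AugmentationParams)
    normalization: NormalizationParams = field(
        default_factory=lambda: NEH_NORMALIZATION)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def toy(cls, seed: int = 0, **overrides) -> "PretrainConfig":
        """Desk-scale preset for reduced specs on small synthetic images.

        Five epochs at a rate a freshly initialized reduced network can
        actually learn at; augmentation off (the affine/jitter stack is
        tuned for 224-px clinical scans, not 32-px toys).
        """
        base = dict(epochs=5, lr=7e-3, augment=False, seed=seed)
        base.update(overrides)
        return cls(**base)


@dataclass
class Checkpoint:
    model: MedViT
    spec: ModelSpec
    epoch: int
    val_auc: float
    log: list[dict]

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "weights.npz"),
                 **self.model.state_dict())
        self.spec.to_json(os.path.join(directory, "spec.json"))
        with open(os.path.join(directory, "state.json"), "w") as fh:
            json.dump({"epoch": self.epoch, "best_val_auc": self.val_auc},
                      fh, indent=2)
        pd.DataFrame(self.log).to_csv(
            os.path.join(directory, "log.csv"), index=False)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "Checkpoint":
        spec = ModelSpec.from_json(os.path.join(directory, "spec.json"))
        model = MedViT(spec)
        with np.load(os.path.join(directory, "weights.npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        with open(os.path.join(directory, "state.json")) as fh:
            state = json.load(fh)
        log_path = os.path.join(directory, "log.csv")
        log = (pd.read_csv(log_path).to_dict("records")
               if os.path.exists(log_path) else [])
        return cls(model, spec, state["epoch"], state["best_val_auc"], log)


def predict_proba(model: MedViT, images: np.ndarray,
                  normalization: NormalizationParams = NEH_NORMALIZATION,
                  batch_size: int = 64) -> np.ndarray:
    """Softmax class probabilities in eval mode (no weight updates)."""
    model.eval()
    outs = []
    with nn.no_grad():
        for i in range(0, len(images), batch_size):
            xb = prepare_batch(images[i:i + batch_size], normalization)
            logits = model(xb)
            outs.append(nn.softmax(logits).data)
    return np.concatenate(outs, axis=0)


def macro_auc(y_true: np.ndarray, proba: np.ndarray) -> float:
    """Macro one-vs-rest area under the ROC curve."""
    return float(roc_auc_score(y_true, proba, multi_class="ovr",
                               average="macro"))


def stratified_split(dataset: OCTDataset, val_fraction: float, seed: int
                     ) -> tuple[OCTDataset, OCTDataset]:
    idx = np.arange(len(dataset))
    tr, va = train_test_split(idx, test_size=val_fraction,
                              random_state=seed,
                              stratify=dataset.labels)
    return dataset.subset(tr, "train"), dataset.subset(va, "val")


def pretrain(model_kind: str | ModelSpec | MedViT, dataset: OCTDataset,
             config: PretrainConfig | None = None,
             log_path: str | os.PathLike | None = None) -> Checkpoint:
    """Anchor pre-training with best-validation-AUC checkpointing.

    Splits `dataset` 80/20 (stratified), trains with focal loss and a step
    schedule, evaluates macro OVR AUC on the validation part each epoch and
    keeps the checkpoint whenever the AUC ties or beats the best so far.
    """
    config = config or PretrainConfig()
    nn.manual_seed(config.seed)
    if isinstance(model_kind, MedViT):
        model = model_kind
    else:
        spec = (model_kind if isinstance(model_kind, ModelSpec)
                else get_spec(model_kind,
                              num_classes=dataset.n_classes))
        model = build_medvit(spec)
    train_ds, val_ds = stratified_split(dataset, config.val_fraction,
                                        config.seed)
    present = set(np.unique(val_ds.labels))
    for ci, cname in enumerate(dataset.class_names):
        if ci not in present:
            raise ValueError(
                f"class {cname!r} absent from the validation split")

    alpha = inverse_frequency_alpha(train_ds.labels, dataset.n_classes)
    loss_params = FocalLossParams(gamma=config.gamma, alpha=alpha)
    opt = nn.AdamW(model.parameters(), lr=config.lr,
                   weight_decay=config.weight_decay)
    sched = nn.StepLR(opt, list(config.milestones), config.decay_factor)
    rng = np.random.default_rng(config.seed)

    best_state = None
    best_auc = -np.inf
    best_epoch = 0
    log: list[dict] = []
    n_train = len(train_ds)
    for epoch in range(1, config.epochs + 1):
        model.train()
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, config.batch_size):
            sel = order[start:start + config.batch_size]
            if config.augment:
                xb = np.stack([
                    augment(train_ds.images[i], config.augmentation, rng,
                            config.normalization) for i in sel])
            else:
                xb = prepare_batch(train_ds.images[sel],
                                   config.normalization)
            yb = train_ds.labels[sel]
            opt.zero_grad()
            loss = focal_loss(model(xb), yb, loss_params)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        proba = predict_proba(model, val_ds.images, config.normalization)
        auc = macro_auc(val_ds.labels, proba)
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_auc": auc, "lr": opt.lr})
        if auc >= best_auc:            # ties favour the later epoch
            best_auc = auc
            best_epoch = epoch
            best_state = model.state_dict()
        sched.step()

    model.load_state_dict(best_state)
    if log_path is not None:
        pd.DataFrame(log).to_csv(log_path, index=False)
    return Checkpoint(model, model.spec, best_epoch, float(best_auc), log)
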