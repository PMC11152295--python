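"""scikit-learn style estimators wrapping the backbone and the stitching
search, so they compose with sklearn pipelines and model selection.

`X` is a stack of unit-scaled grayscale images with shape (n, H, W) (a
flattened (n, H*W) matrix is also accepted if square); `y` are integer or
string class labels.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import LabelEncoder
from sklearn.utils.validation import check_is_fitted

from .evaluation import evaluate_proba
from .specs import get_spec
from .stitching import Anchor, StitchTrainConfig, build_space, train_stitched
from .training import (NEH_NORMALIZATION, UCSD_NORMALIZATION,
                       NormalizationParams, OCTDataset, PretrainConfig,
                       predict_proba, pretrain)

_NORMS = {"neh": NEH_NORMALIZATION, "ucsd": UCSD_NORMALIZATION}


def _as_images(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        side = int(round(np.sqrt(X.shape[1])))
        if side * side != X.shape[1]:
            raise ValueError(
                f"flattened input with {X.shape[1]} features is not square")
        X = X.reshape(len(X), side, side)
    if X.ndim != 3:
        raise ValueError(f"expected (n, H, W) images, got shape {X.shape}")
    return X


def _resolve_norm(norm) -> NormalizationParams:
    if isinstance(norm, NormalizationParams):
        return norm
    try:
        return _NORMS[norm]
    except KeyError:
        raise ValueError(f"unknown normalization preset {norm!r}; "
                         f"use one of {sorted(_NORMS)}")


class MedViTClassifier(BaseEstimator, ClassifierMixin):
    """Hybrid CNN-transformer image classifier with focal-loss training.

    Wraps anchor pre-training (stratified 80/20 split, best-validation-AUC
    checkpointing) behind the sklearn estimator API.
    """

    def __init__(self, spec: str = "micro", epochs: int = 75,
                 batch_size: int = 32, lr: float = 5e-5,
                 gamma: float = 2.0, weight_decay: float = 0.01,
                 augment: bool = True, normalization: str = "neh",
                 seed: int = 0):
        self.spec = spec
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.gamma = gamma
        self.weight_decay = weight_decay
        self.augment = augment
        self.normalization = normalization
        self.seed = seed

    def _pretrain_config(self) -> PretrainConfig:
        return PretrainConfig(
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            gamma=self.gamma, weight_decay=self.weight_decay,
            augment=self.augment, seed=self.seed,
            normalization=_resolve_norm(self.normalization))

    def fit(self, X, y) -> "MedViTClassifier":
        X = _as_images(X)
        self._label_encoder_ = LabelEncoder().fit(y)
        labels = self._label_encoder_.transform(y).astype(np.int64)
        self.classes_ = self._label_encoder_.classes_
        names = tuple(str(c) for c in self.classes_)
        dataset = OCTDataset(X, labels, class_names=names)
        ckpt = pretrain(get_spec(self.spec, num_classes=len(names)),
                        dataset, self._pretrain_config())
        self.model_ = ckpt.model
        self.best_val_auc_ = ckpt.val_auc
        self.best_epoch_ = ckpt.epoch
        self.history_ = ckpt.log
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return predict_proba(self.model_, _as_images(X),
                             _resolve_norm(self.normalization))

    def predict(self, X) -> np.ndarray:
        idx = self.predict_proba(X).argmax(axis=1)
        return self.classes_[idx]


class StitchedOCTClassifier(BaseEstimator, ClassifierMixin):
    """Stitching-based architecture search as a single sklearn estimator.

    `fit` pre-trains a front and a back anchor on the training data,
    enumerates the (optionally pruned) stitching space, initializes every
    stitch by least squares on a mini-batch and trains the space by
    random-configuration sampling.  `predict` uses the configuration that
    scored best on the held-out split (or a `config_id` chosen at call
    time).
    """

    def __init__(self, front: str = "reduced-micro",
                 back: str = "reduced-tiny", epochs: int = 5,
                 batch_size: int = 32, lr: float = 7e-3,
                 iterations: int = 200, stitch_lr: float = 1e-3,
                 prune: bool = True, init_batch: int = 100,
                 gamma: float = 2.0, augment: bool = False,
                 normalization: str = "neh", val_fraction: float = 0.2,
                 seed: int = 0):
        self.front = front
        self.back = back
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.iterations = iterations
        self.stitch_lr = stitch_lr
        self.prune = prune
        self.init_batch = init_batch
        self.gamma = gamma
        self.augment = augment
        self.normalization = normalization
        self.val_fraction = val_fraction
        self.seed = seed

    def fit(self, X, y) -> "StitchedOCTClassifier":
        from sklearn.model_selection import train_test_split

        X = _as_images(X)
        self._label_encoder_ = LabelEncoder().fit(y)
        labels = self._label_encoder_.transform(y).astype(np.int64)
        self.classes_ = self._label_encoder_.classes_
        names = tuple(str(c) for c in self.classes_)
        norm = _resolve_norm(self.normalization)
        idx = np.arange(len(X))
        tr, va = train_test_split(idx, test_size=self.val_fraction,
                                  random_state=self.seed, stratify=labels)
        train_ds = OCTDataset(X[tr], labels[tr], class_names=names)
        pcfg = PretrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                              lr=self.lr, gamma=self.gamma,
                              augment=self.augment, seed=self.seed,
                              normalization=norm)
        front_ck = pretrain(get_spec(self.front, num_classes=len(names)),
                            train_ds, pcfg)
        back_ck = pretrain(get_spec(self.back, num_classes=len(names)),
                           train_ds, pcfg)
        space = build_space(Anchor(0, front_ck.model, self.front),
                            Anchor(1, back_ck.model, self.back),
                            prune=self.prune)
        rng = np.random.default_rng(self.seed)
        sel = rng.permutation(len(train_ds))[:self.init_batch]
        space.initialize_stitches(train_ds.images[sel], norm,
                                  batch_size=self.init_batch)
        scfg = StitchTrainConfig(iterations=self.iterations,
                                 batch_size=self.batch_size,
                                 lr=self.stitch_lr, gamma=self.gamma,
                                 seed=self.seed, normalization=norm)
        self.train_log_ = train_stitched(space, train_ds, scfg)
        self.space_ = space
        self.manifest_ = space.manifest()
        recal = train_ds.images[rng.permutation(len(train_ds))]
        scores = []
        for cid in range(len(space)):
            space.recalibrate_bn(recal, cid, norm)
            proba = space.predict_proba(X[va], cid, norm)
            rec = evaluate_proba(proba, labels[va], len(names))
            scores.append(rec.accuracy)
        self.config_scores_ = np.asarray(scores)
        self.best_config_id_ = int(np.argmax(scores))
        # leave the shared norm statistics matched to the chosen candidate
        space.recalibrate_bn(recal, self.best_config_id_, norm)
        return self

    def predict_proba(self, X, config_id: int | None = None) -> np.ndarray:
        check_is_fitted(self, "space_")
        cid = self.best_config_id_ if config_id is None else config_id
        return self.space_.predict_proba(
            _as_images(X), cid, _resolve_norm(self.normalization))

    def predict(self, X, config_id: int | None = None) -> np.ndarray:
        idx = self.predict_proba(X, config_id).argmax(axis=1)
        return self.classes_[idx]
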