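"""Evaluation protocol: macro metrics, 95% intervals, five-fold driver.

Metrics follow the multi-class conventions that keep specificity well
defined for three classes: sensitivity and specificity are macro
(unweighted per-class one-vs-rest) averages, AUC is the macro one-vs-rest
area.  Cross-validated results are summarized as mean +- 1.96 * SD / sqrt(k)
over the k fold values (normal approximation; a t-quantile alternative is
available).
"""
from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GroupKFold, KFold

from .specs import ConfigurationError
from .stitching import (Anchor, StitchTrainConfig, build_space,
                        train_stitched)
from .training import (Checkpoint, NEH_NORMALIZATION, NormalizationParams,
                       OCTDataset, PretrainConfig, macro_auc, predict_proba,
                       pretrain)


@dataclass
class MetricsRecord:
    accuracy: float
    sensitivity: float          # macro recall
    specificity: float          # macro true-negative rate
    auc: float                  # macro one-vs-rest
    n: int

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc,
                "n": self.n}


def confusion(y_true: np.ndarray, y_pred: np.ndarray,
              n_classes: int) -> np.ndarray:
    """K x K confusion matrix, rows = true class, columns = predicted."""
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def compute_metrics(cm: np.ndarray, scores: np.ndarray | None = None,
                    labels: np.ndarray | None = None) -> MetricsRecord:
    """Accuracy + macro sensitivity/specificity from a confusion matrix,
    macro OVR AUC from per-class scores.

    Classes with zero true samples are excluded from the macro means with
    a warning.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = cm.shape[0]
    tp = np.diag(cm).astype(float)
    support = cm.sum(axis=1).astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    present = support > 0
    if not present.all():
        missing = np.where(~present)[0].tolist()
        warnings.warn(f"classes {missing} have no true samples; excluded "
                      "from macro averages", RuntimeWarning)
    sens = tp[present] / support[present]
    tn = total - support - pred_tot + tp
    fp = pred_tot - tp
    spec = tn[present] / (tn[present] + fp[present])
    auc = np.nan
    if scores is not None and labels is not None:
        auc = macro_auc(np.asarray(labels), np.asarray(scores))
    return MetricsRecord(accuracy=float(tp.sum() / total),
                         sensitivity=float(sens.mean()),
                         specificity=float(spec.mean()),
                         auc=float(auc), n=int(total))


def ci95(values, use_t: bool = False) -> tuple[float, float]:
    """Mean and 95% half-width over fold values.

    half_width = q * SD / sqrt(n) with q = 1.96 (normal approximation) or
    the two-sided t quantile when `use_t`.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("ci95 requires at least 2 values")
    n = values.size
    sd = values.std(ddof=1)
    q = stats.t.ppf(0.975, n - 1) if use_t else 1.96
    return float(values.mean()), float(q * sd / np.sqrt(n))


def format_ci(mean: float, half_width: float) -> str:
    return f"{mean:.3f} ±{half_width:.3f}"


# ---------------------------------------------------------------------------
# Fold splitting
# ---------------------------------------------------------------------------

def fold_split(n: int, k: int = 5, seed: int = 0,
               groups: np.ndarray | None = None) -> np.ndarray:
    """Assign each sample to one of k folds.

    Random at image level by default; pass patient `groups` for
    patient-grouped splitting.  Fold sizes differ by at most 1 in the
    ungrouped case.
    """
    assign = np.empty(n, dtype=int)
    if groups is None:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (_, test) in enumerate(splitter.split(np.arange(n))):
            assign[test] = f
    else:
        splitter = GroupKFold(n_splits=k)
        for f, (_, test) in enumerate(
                splitter.split(np.arange(n), groups=groups)):
            assign[test] = f
    return assign


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def evaluate_proba(proba: np.ndarray, labels: np.ndarray,
                   n_classes: int) -> MetricsRecord:
    cm = confusion(labels, proba.argmax(axis=1), n_classes)
    return compute_metrics(cm, scores=proba, labels=labels)


def zero_shot_evaluate(checkpoint: Checkpoint, target: OCTDataset,
                       normalization: NormalizationParams = NEH_NORMALIZATION
                       ) -> MetricsRecord:
    """Evaluate a trained checkpoint on a whole target dataset, no updates."""
    model = checkpoint.model
    if model.spec.num_classes != target.n_classes:
        raise ConfigurationError(
            f"checkpoint has {model.spec.num_classes}-class head but the "
            f"target dataset has {target.n_classes} classes")
    proba = predict_proba(model, target.images, normalization)
    return evaluate_proba(proba, target.labels, target.n_classes)


# ---------------------------------------------------------------------------
# Five-fold stitching driver
# ---------------------------------------------------------------------------

@dataclass
class FiveFoldConfig:
    folds: int = 5
    seed: int = 0
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    stitch: StitchTrainConfig = field(default_factory=StitchTrainConfig)
    front_kind: str = "micro"
    back_kind: str = "tiny"
    prune: bool = True
    init_batch: int = 100
    bn_recalibration: bool = True      # per-candidate BN re-estimation
    recal_batches: int = 8
    normalization: NormalizationParams = field(
        default_factory=lambda: NEH_NORMALIZATION)
    group_by_patient: bool = False


@dataclass
class FiveFoldResult:
    per_fold: pd.DataFrame          # one row per (fold, config)
    aggregate: pd.DataFrame         # mean +- half-width per config
    fold_assignments: np.ndarray
    n_pretrains: int

    def metrics_records(self) -> list[MetricsRecord]:
        return [MetricsRecord(r.accuracy, r.sensitivity, r.specificity,
                              r.auc, int(r.n))
                for r in self.per_fold.itertuples()]


def five_fold_run(source: OCTDataset, target: OCTDataset,
                  config: FiveFoldConfig | None = None,
                  in_distribution: bool | None = None) -> FiveFoldResult:
    """Five-fold cross-validated stitching.

    Out-of-distribution mode (source is not target): anchors are
    pre-trained once on the source dataset, then per fold the stitching
    space is trained on the remaining 4/5 of the target and tested on the
    held-out fold.  In-distribution mode: anchors are re-pre-trained per
    fold on the remainder.
    """
    config = config or FiveFoldConfig()
    if source.class_names != target.class_names:
        raise ConfigurationError(
            f"label sets differ: {source.class_names} vs "
            f"{target.class_names}")
    if in_distribution is None:
        in_distribution = source is target
    assign = fold_split(len(target), config.folds, config.seed,
                        target.patient_ids if config.group_by_patient
                        else None)
    n_pretrains = 0
    anchors = None
    if not in_distribution:
        front_ck = pretrain(config.front_kind, source, config.pretrain)
        back_ck = pretrain(config.back_kind, source, config.pretrain)
        n_pretrains = 2
        anchors = (Anchor(0, front_ck.model, config.front_kind),
                   Anchor(1, back_ck.model, config.back_kind))

    rows = []
    for fold in range(config.folds):
        test_idx = np.where(assign == fold)[0]
        rem_idx = np.where(assign != fold)[0]
        test_ds = target.subset(test_idx, f"fold{fold}-test")
        rem_ds = target.subset(rem_idx, f"fold{fold}-remainder")
        if in_distribution:
            fcfg = copy.deepcopy(config.pretrain)
            fcfg.seed = config.pretrain.seed + fold
            front_ck = pretrain(config.front_kind, rem_ds, fcfg)
            back_ck = pretrain(config.back_kind, rem_ds, fcfg)
            n_pretrains += 2
            front = Anchor(0, front_ck.model, config.front_kind)
            back = Anchor(1, back_ck.model, config.back_kind)
        else:
            front, back = anchors[0].clone(), anchors[1].clone()
        space = build_space(front, back, prune=config.prune)
        rng = np.random.default_rng(config.seed + fold)
        init_sel = rng.permutation(len(rem_ds))[:config.init_batch]
        space.initialize_stitches(rem_ds.images[init_sel],
                                  config.normalization,
                                  batch_size=config.init_batch)
        scfg = copy.deepcopy(config.stitch)
        scfg.seed = config.stitch.seed + fold
        train_stitched(space, rem_ds, scfg)
        recal_sel = rng.permutation(len(rem_ds))
        for cfg in space.configs:
            if config.bn_recalibration:
                space.recalibrate_bn(rem_ds.images[recal_sel],
                                     cfg.config_id, config.normalization,
                                     n_batches=config.recal_batches)
            proba = space.predict_proba(test_ds.images, cfg.config_id,
                                        config.normalization)
            rec = evaluate_proba(proba, test_ds.labels, target.n_classes)
            rows.append({
                "model": f"stitch[{cfg.cut_index}->{cfg.entry_index}]",
                "config_id": cfg.config_id, "fold": fold,
                **rec.as_dict(),
                "params_millions": round(
                    space.stitched_parameter_count(cfg.config_id) / 1e6, 2),
            })
    per_fold = pd.DataFrame(rows)
    agg_rows = []
    for cid, grp in per_fold.groupby("config_id"):
        row = {"model": grp["model"].iloc[0], "config_id": cid,
               "n": int(grp["n"].sum()),
               "params_millions": grp["params_millions"].iloc[0]}
        for metric in ("accuracy", "sensitivity", "specificity", "auc"):
            mean, hw = ci95(grp[metric].to_numpy())
            row[metric] = mean
            row[f"{metric}_hw"] = hw
        agg_rows.append(row)
    return FiveFoldResult(per_fold, pd.DataFrame(agg_rows), assign,
                          n_pretrains)
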