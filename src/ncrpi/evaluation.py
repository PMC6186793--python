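"""Cross-validated evaluation: confusion metrics, ROC/AUC, k-fold CV.

Predictions are thresholded at 0.5 by default and tallied into TP/FP/TN/FN,
from which the five standard binary-classification criteria follow:

    accuracy    = (TP+TN) / (TP+TN+FP+FN)
    sensitivity = TP / (TP+FN)
    specificity = TN / (TN+FP)
    precision   = TP / (TP+FP)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Any ratio whose denominator is 0 is defined as 0 so fold averages stay
total. The ROC curve sweeps all distinct score thresholds (TPR vs FPR) and
AUC is the trapezoidal area, which equals the Mann-Whitney pairwise-ranking
statistic.

Cross-validation uses stratified folds by default (fold sizes differ by at
most one; per-fold class ratios within one sample of the global ratio)
because the small benchmark corpora in this field occasionally yield
single-class folds under plain random splitting. Feature extraction is
fit-free — no statistic is learned from the training portion — so features
are computed once for the whole dataset without leakage.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .classifier import (
    ClassifierConfig,
    FeatureConfig,
    featurize_dataset,
    predict_scores,
    train,
)
from .data_io import Dataset, synthesize_pssms


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    mcc: float


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class CvReport:
    """Everything one 10-fold run produces, serializable to JSON."""

    fold_metrics: list[MetricSet]
    fold_confusions: list[ConfusionCounts]
    fold_assignments: np.ndarray
    fold_aucs: list[float]
    mean_metrics: MetricSet
    mean_fold_auc: float
    pooled_roc: RocCurve
    seed: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "fold_assignments": self.fold_assignments.tolist(),
            "fold_metrics": [asdict(m) for m in self.fold_metrics],
            "fold_confusions": [asdict(c) for c in self.fold_confusions],
            "fold_aucs": list(self.fold_aucs),
            "mean_metrics": asdict(self.mean_metrics),
            "mean_fold_auc": self.mean_fold_auc,
            "pooled_auc": self.pooled_roc.auc,
            "pooled_roc": {
                "fpr": self.pooled_roc.fpr.tolist(),
                "tpr": self.pooled_roc.tpr.tolist(),
            },
            "leakage_note": "feature extraction is fit-free; no per-fold refit needed",
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Tally predictions (score >= threshold -> positive) against labels."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != scores.shape:
        raise ValueError(
            f"length mismatch: {labels.size} labels vs {scores.size} scores"
        )
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def metrics(c: ConfusionCounts) -> MetricSet:
    """The five standard criteria; zero-denominator ratios are defined as 0."""
    if c.total == 0:
        raise ValueError("no samples tallied")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return MetricSet(
        accuracy=_ratio(tp + tn, c.total),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        mcc=_ratio(tp * tn - fp * fn, mcc_den),
    )


def roc_auc(labels, scores) -> RocCurve:
    """ROC curve over all distinct thresholds; AUC by the trapezoidal rule."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def kfold_split(
    n: int, folds: int = 10, stratify_labels=None, seed: int = 0
) -> np.ndarray:
    """Random fold assignment vector of length n (sizes differ by <= 1)."""
    if n < folds:
        raise ValueError(f"cannot split {n} samples into {folds} folds")
    assignment = np.empty(n, dtype=int)
    if stratify_labels is not None:
        y = np.asarray(stratify_labels, dtype=int)
        if y.size != n:
            raise ValueError("stratify_labels length must equal n")
        counts = np.bincount(y)
        if np.any(counts[counts > 0] < folds):
            raise ValueError("each class needs at least `folds` members")
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        iterator = splitter.split(np.zeros(n), y)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        iterator = splitter.split(np.zeros(n))
    for fold, (_, test_idx) in enumerate(iterator):
        assignment[test_idx] = fold
    return assignment


def _mean_metrics(per_fold: list[MetricSet]) -> MetricSet:
    return MetricSet(
        **{
            name: float(np.mean([getattr(m, name) for m in per_fold]))
            for name in ("accuracy", "sensitivity", "specificity", "precision", "mcc")
        }
    )


def cross_validate(
    dataset: Dataset,
    feature_config: FeatureConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    pssms: dict | None = None,
    threshold: float = 0.5,
    stratify: bool = True,
) -> CvReport:
    """Full pipeline: features -> fuse -> k-fold train/score -> metrics.

    Each fold trains on the other folds and scores its own held-out pairs;
    per-fold metrics use ``threshold``, the pooled ROC concatenates all
    held-out scores, and mean metrics are the arithmetic mean over folds.
    If ``pssms`` is omitted, synthetic profile matrices are generated
    deterministically from the run seed.
    """
    fc = feature_config or FeatureConfig()
    cc = classifier_config or ClassifierConfig()
    if pssms is None:
        pssms = synthesize_pssms(
            dataset.proteins, noise_sd=fc.pssm_noise_sd,
            seed=(seed * 1000003 + 7919) % (2**31 - 1),
        )
    X, y, _ = featurize_dataset(dataset, pssms, fc)
    if np.unique(y).size < 2:
        raise ValueError("dataset must contain both classes")
    assignment = kfold_split(y.size, folds, y if stratify else None, seed)

    held_out_scores = np.empty(y.size)
    fold_metrics, fold_confusions, fold_aucs = [], [], []
    for fold in range(folds):
        test_mask = assignment == fold
        handle = train(
            X[~test_mask], y[~test_mask],
            backend=cc.backend, hyperparameters=cc.hyperparameters,
            seed=(seed * 10007 + fold) % (2**31 - 1),
        )
        scores = predict_scores(handle, X[test_mask])
        held_out_scores[test_mask] = scores
        counts = confusion(y[test_mask], scores, threshold)
        fold_confusions.append(counts)
        fold_metrics.append(metrics(counts))
        fold_aucs.append(roc_auc(y[test_mask], scores).auc)

    pooled = roc_auc(y, held_out_scores)
    return CvReport(
        fold_metrics=fold_metrics,
        fold_confusions=fold_confusions,
        fold_assignments=assignment,
        fold_aucs=fold_aucs,
        mean_metrics=_mean_metrics(fold_metrics),
        mean_fold_auc=float(np.mean(fold_aucs)),
        pooled_roc=pooled,
        seed=seed,
        config={
            "feature": asdict(fc),
            "classifier": {"backend": cc.backend, "hyperparameters": cc.hyperparameters},
            "folds": folds,
            "threshold": threshold,
            "stratify": stratify,
        },
    )
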