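"""Leave-one-subject-out (LOSO) cross-validation.

Subjects are partitioned into k similarly sized clusters (default 5); for
each split one cluster is the blind test set and the remainder supply
class-balanced training and validation data.  Every architecture is trained
on identical splits and scored with the standard confusion-matrix metric
suite plus AUROC of the positive class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .models import ModelHandle
from .preprocess import AugmentPolicy, Datastore, LOSO_POLICY, balanced_sample
from .stage1 import TrainConfig, train_with_early_stopping
from .training import ImageDataset, evaluate_accuracy

logger = logging.getLogger(__name__)

__all__ = [
    "LOSOPlan",
    "ConfusionCounts",
    "MetricSet",
    "assign_clusters",
    "build_split",
    "confusion",
    "compute_metrics",
    "compute_auroc",
    "run_loso",
    "DEFAULT_BUDGETS",
]

# per-split sample budgets (n per class): train, val, test
DEFAULT_BUDGETS = {
    "B": {"train": 8000, "val": 1000, "test": 1000},   # 16000/2000/2000 total
    "M": {"train": 2000, "val": 250, "test": 250},     # 4000/500/500 total
}


@dataclass
class LOSOPlan:
    """subject_id -> cluster index in 1..k; cluster sizes differ by <= 1."""

    assignment: dict[str, int]
    k: int

    def cluster(self, index: int) -> list[str]:
        return sorted(s for s, c in self.assignment.items() if c == index)

    def sizes(self) -> list[int]:
        return [len(self.cluster(i)) for i in range(1, self.k + 1)]

    def to_dict(self) -> dict:
        return {"k": self.k, "assignment": dict(self.assignment)}


def assign_clusters(subject_ids: Sequence[str], k: int = 5,
                    rng: np.random.Generator | None = None) -> LOSOPlan:
    """Random balanced partition of subjects into k clusters."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(subject_ids) < k:
        raise ValueError(f"need at least {k} subjects, got {len(subject_ids)}")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("subject_ids must be unique")
    rng = rng or np.random.default_rng(0)
    order = list(rng.permutation(list(subject_ids)))
    assignment = {s: (i % k) + 1 for i, s in enumerate(order)}
    return LOSOPlan(assignment, k)


def build_split(plan: LOSOPlan, holdout: int, store: Datastore, site: str,
                budgets: dict[str, int], rng: np.random.Generator,
                ) -> tuple[ImageDataset, ImageDataset, ImageDataset]:
    """Class-balanced train/val/test datasets for one LOSO split.

    Train and validation draw only from non-holdout clusters (disjoint
    frames); test draws only from the holdout cluster.  ``budgets`` maps
    role -> n per class.
    """
    if not 1 <= holdout <= plan.k:
        raise ValueError(f"holdout must be in 1..{plan.k}")
    test_subjects = plan.cluster(holdout)
    pool_subjects = sorted(set(plan.assignment) - set(test_subjects))
    n_train, n_val = budgets["train"], budgets["val"]
    # draw train+val jointly, then partition, so the two never share a frame
    joint = balanced_sample(store, site, pool_subjects, n_train + n_val, rng)
    pos = [f for f in joint if f.label == "positive"]
    neg = [f for f in joint if f.label == "negative"]
    train_frames = pos[:n_train] + neg[:n_train]
    val_frames = pos[n_train:] + neg[n_train:]
    test_frames = balanced_sample(store, site, test_subjects, budgets["test"], rng)
    return (ImageDataset.from_frames(train_frames),
            ImageDataset.from_frames(val_frames),
            ImageDataset.from_frames(test_frames))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(predictions: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """2x2 counts with label 1 ('positive') as the positive class."""
    p = np.asarray(predictions)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("predictions and truth must have equal length")
    return ConfusionCounts(
        tp=int(((p == 1) & (t == 1)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
    )


@dataclass
class MetricSet:
    """accuracy, precision, recall, specificity, F1, AUROC — fractions in
    [0, 1]; NaN marks a metric whose denominator was zero (undefined)."""

    accuracy: float = math.nan
    precision: float = math.nan
    recall: float = math.nan
    specificity: float = math.nan
    f1: float = math.nan
    auroc: float = math.nan

    def to_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "specificity": self.specificity,
                "f1": self.f1, "auroc": self.auroc}


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Standard confusion-derived metrics.

    accuracy    = (TN + TP) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * recall * precision / (recall + precision)

    Zero denominators yield NaN (undefined), never an exception.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated frames")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2 * recall * precision / (recall + precision)
    return MetricSet(
        accuracy=(c.tn + c.tp) / c.total,
        precision=precision,
        recall=recall,
        specificity=_ratio(c.tn, c.tn + c.fp),
        f1=f1,
    )


def compute_auroc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Area under the ROC curve for the positive class (trapezoidal;
    equal to the tie-corrected Mann-Whitney ordering probability)."""
    t = np.asarray(truth)
    if len(set(t.tolist())) < 2:
        raise ValueError("AUROC requires both classes present in truth")
    return float(roc_auc_score(t, np.asarray(scores, dtype=float)))


@dataclass
class LOSOResult:
    architecture: str
    site: str
    per_split: list[MetricSet] = field(default_factory=list)
    split_val_accuracy: list[float] = field(default_factory=list)
    failed_splits: list[int] = field(default_factory=list)

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """Mean and sample (n-1) standard deviation over completed splits."""
        out = {}
        for name in ("accuracy", "precision", "recall", "specificity",
                     "f1", "auroc"):
            vals = [getattr(m, name) for m in self.per_split
                    if not math.isnan(getattr(m, name))]
            if not vals:
                out[name] = (math.nan, math.nan)
            else:
                mean = float(np.mean(vals))
                sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                out[name] = (mean, sd)
        return out


def evaluate_split(handle: ModelHandle, test: ImageDataset) -> MetricSet:
    """Blind-test MetricSet for a trained model on one split."""
    pred = handle.predict_labels(test.X)
    proba = handle.predict_proba(test.X)[:, 1]
    metrics = compute_metrics(confusion(pred, test.y))
    try:
        metrics.auroc = compute_auroc(proba, test.y)
    except ValueError:
        metrics.auroc = math.nan
    return metrics


def run_loso(architectures: dict[str, Callable], plan: LOSOPlan,
             store: Datastore, site: str, config: TrainConfig,
             budgets: dict[str, int], base_seed: int = 0,
             augment: AugmentPolicy = LOSO_POLICY,
             ) -> tuple[list[LOSOResult], pd.DataFrame]:
    """Train and evaluate every architecture on every LOSO split.

    ``architectures`` maps name -> builder(activator, rng) -> ModelHandle.
    Splits are built once per holdout (identical data for all
    architectures).  A failed split is recorded and aggregation proceeds
    over completed splits with a warning.
    """
    splits = []
    for holdout in range(1, plan.k + 1):
        rng = np.random.default_rng([base_seed, 31, holdout])
        splits.append(build_split(plan, holdout, store, site, budgets, rng))
    results = []
    rows = []
    for name, builder in architectures.items():
        res = LOSOResult(name, site)
        for holdout, (train, val, test) in enumerate(splits, start=1):
            rng = np.random.default_rng([base_seed, 127, holdout])
            handle = builder(config.activator, rng)
            run = train_with_early_stopping(handle, config, train, val,
                                            augment, rng)
            if run.failed:
                logger.warning("LOSO split %d failed for %s", holdout, name)
                res.failed_splits.append(holdout)
                continue
            metrics = evaluate_split(handle, test)
            res.per_split.append(metrics)
            res.split_val_accuracy.append(evaluate_accuracy(handle, val))
            rows.append(dict(site=site, architecture=name, split=holdout,
                             split_val_accuracy=res.split_val_accuracy[-1],
                             **metrics.to_dict()))
        results.append(res)
    return results, pd.DataFrame(rows)
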