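"""Stage 1: exhaustive optimization of training hyperparameters.

All 54 combinations of batch size x optimizer x learning rate x final
activator are trained with early stopping, scored on blind-test accuracy,
and aggregated per parameter value: each run with accuracy >= 0.5
contributes (accuracy - 0.5) to the running score of *every one* of its
four parameter values; runs below 0.5 contribute 0.  The highest-scoring
value of each parameter is selected.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelHandle
from .preprocess import AugmentPolicy, STAGE_POLICY
from .training import ImageDataset, TrainingHistory, train_model, evaluate_accuracy

logger = logging.getLogger(__name__)

__all__ = [
    "BATCH_SIZES",
    "OPTIMIZERS",
    "LEARNING_RATES",
    "ACTIVATORS",
    "TrainConfig",
    "RunResult",
    "ScoreTable",
    "enumerate_grid",
    "train_with_early_stopping",
    "score_model",
    "aggregate_scores",
    "select_parameters",
    "run_stage1",
]

BATCH_SIZES = (16, 64, 128)
OPTIMIZERS = ("RMSprop", "ADAM", "SGDM")
LEARNING_RATES = (0.001, 0.0005, 0.0001)
ACTIVATORS = ("softmax", "softplus")

PARAMETERS = ("batch_size", "optimizer", "learning_rate", "activator")
_CHOICES = {
    "batch_size": BATCH_SIZES,
    "optimizer": OPTIMIZERS,
    "learning_rate": LEARNING_RATES,
    "activator": ACTIVATORS,
}


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    optimizer: str = "RMSprop"
    learning_rate: float = 0.001
    activator: str = "softmax"
    max_epochs: int = 100
    patience: int = 5

    def __post_init__(self):
        errs = [f"{name}={getattr(self, name)!r} not in {_CHOICES[name]}"
                for name in PARAMETERS
                if getattr(self, name) not in _CHOICES[name]]
        if errs:
            raise ValueError("; ".join(errs))

    def values(self) -> dict[str, object]:
        return {name: getattr(self, name) for name in PARAMETERS}


@dataclass
class RunResult:
    config: TrainConfig
    blind_accuracy: float = float("nan")
    epochs_run: int = 0
    best_val_loss: float = float("inf")
    failed: bool = False
    history: TrainingHistory | None = None


class ScoreTable:
    """Accumulated score per parameter value; one bucket per parameter."""

    def __init__(self):
        self.scores: dict[str, dict[object, float]] = {
            name: {v: 0.0 for v in _CHOICES[name]} for name in PARAMETERS}

    def add(self, config: TrainConfig, score: float) -> None:
        for name, value in config.values().items():
            self.scores[name][value] += score

    def totals(self) -> dict[str, float]:
        return {name: sum(bucket.values()) for name, bucket in self.scores.items()}

    def to_dict(self) -> dict:
        return {name: {str(k): v for k, v in bucket.items()}
                for name, bucket in self.scores.items()}


def enumerate_grid(max_epochs: int = 100, patience: int = 5) -> list[TrainConfig]:
    """The full 3 x 3 x 3 x 2 = 54-configuration grid, in lexicographic order
    of (batch size, optimizer, learning rate, activator) as listed above."""
    return [TrainConfig(b, o, lr, a, max_epochs, patience)
            for b, o, lr, a in itertools.product(
                BATCH_SIZES, OPTIMIZERS, LEARNING_RATES, ACTIVATORS)]


def train_with_early_stopping(handle: ModelHandle, config: TrainConfig,
                              train: ImageDataset, val: ImageDataset,
                              augment: AugmentPolicy | None,
                              rng: np.random.Generator) -> RunResult:
    """Train one configuration; blind accuracy is filled in downstream."""
    hist = train_model(handle, train, val, config.optimizer,
                       config.learning_rate, config.batch_size, rng,
                       max_epochs=config.max_epochs, patience=config.patience,
                       augment=augment)
    return RunResult(config, epochs_run=hist.epochs_run,
                     best_val_loss=hist.best_val_loss, failed=hist.failed,
                     history=hist)


def score_model(blind_accuracy: float) -> float:
    """Score one run: accuracy - 0.5 when accuracy >= 0.5, else 0."""
    if not 0.0 <= blind_accuracy <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {blind_accuracy}")
    return blind_accuracy - 0.5 if blind_accuracy >= 0.5 else 0.0


def aggregate_scores(results: list[RunResult]) -> ScoreTable:
    """Sum each run's score into every one of its four parameter values."""
    table = ScoreTable()
    for res in results:
        acc = 0.0 if res.failed else res.blind_accuracy
        table.add(res.config, score_model(acc))
    return table


def select_parameters(table: ScoreTable, max_epochs: int = 100,
                      patience: int = 5) -> TrainConfig:
    """Per-parameter argmax of accumulated score; ties go to the first value
    in the declared enumeration order (and are logged)."""
    chosen = {}
    for name in PARAMETERS:
        bucket = table.scores[name]
        best = max(bucket.values())
        winners = [v for v in _CHOICES[name] if bucket[v] == best]
        if len(winners) > 1:
            logger.info("tie for %s among %s; choosing %s", name, winners,
                        winners[0])
        chosen[name] = winners[0]
    return TrainConfig(**chosen, max_epochs=max_epochs, patience=patience)


def run_seed(base_seed: int, run_index: int) -> int:
    """Stable per-run seed derived from (base_seed, run index)."""
    h = hashlib.sha256(f"{base_seed}:{run_index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_stage1(model_builder, train: ImageDataset, val: ImageDataset,
               test: ImageDataset, base_seed: int = 0,
               grid: list[TrainConfig] | None = None,
               augment: AugmentPolicy = STAGE_POLICY,
               ) -> tuple[list[RunResult], ScoreTable, TrainConfig, pd.DataFrame]:
    """Run the grid: train each config on a fresh model, score on the blind
    test set, aggregate, select.  ``model_builder(activator, rng) ->
    ModelHandle`` supplies a fresh network per run.

    Returns (results, score table, selected config, per-run table).
    """
    grid = grid if grid is not None else enumerate_grid()
    results: list[RunResult] = []
    for i, cfg in enumerate(grid):
        rng = np.random.default_rng(run_seed(base_seed, i))
        handle = model_builder(cfg.activator, rng)
        res = train_with_early_stopping(handle, cfg, train, val, augment, rng)
        if not res.failed:
            res.blind_accuracy = evaluate_accuracy(handle, test)
        else:
            res.blind_accuracy = 0.0
            logger.warning("run %d (%s) diverged; recorded as failed", i, cfg)
        results.append(res)
    table = aggregate_scores(results)
    selected = select_parameters(
        table, max_epochs=grid[0].max_epochs, patience=grid[0].patience)
    rows = []
    for res in results:
        row = res.config.values()
        row.update(epochs_run=res.epochs_run, best_val_loss=res.best_val_loss,
                   blind_accuracy=res.blind_accuracy,
                   score=score_model(0.0 if res.failed else res.blind_accuracy),
                   failed=res.failed)
        rows.append(row)
    return results, table, selected, pd.DataFrame(rows)
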