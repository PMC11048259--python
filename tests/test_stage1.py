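"""Exhaustive grid, score aggregation, parameter selection, early stopping."""

import itertools

import numpy as np
import pytest

from efastnet import stage1
from efastnet.models import build_simple_cnn
from efastnet.stage1 import (RunResult, TrainConfig, aggregate_scores,
                             enumerate_grid, score_model, select_parameters)
from efastnet.training import EarlyStopping, train_model
from .conftest import make_dataset


class TestGrid:
    def test_cardinality_54(self):
        assert len(enumerate_grid()) == 54

    def test_matches_brute_force_product(self):
        brute = set(itertools.product(stage1.BATCH_SIZES, stage1.OPTIMIZERS,
                                      stage1.LEARNING_RATES, stage1.ACTIVATORS))
        grid = enumerate_grid()
        assert {(c.batch_size, c.optimizer, c.learning_rate, c.activator)
                for c in grid} == brute
        assert len(brute) == 3 * 3 * 3 * 2

    def test_no_duplicates_and_stable_order(self):
        a, b = enumerate_grid(), enumerate_grid()
        assert a == b
        assert len(set(a)) == len(a)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=32)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="Adagrad")


class TestScoring:
    @pytest.mark.parametrize("acc,expected", [(0.74, 0.24), (0.5, 0.0),
                                              (0.3, 0.0), (1.0, 0.5)])
    def test_score_rule(self, acc, expected):
        assert score_model(acc) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_model(1.2)

    def test_score_monotone_and_zero_below_half(self):
        accs = np.linspace(0, 1, 101)
        scores = [score_model(a) for a in accs]
        assert all(s == 0 for a, s in zip(accs, scores) if a <= 0.5)
        assert all(s2 >= s1 for s1, s2 in zip(scores, scores[1:]))

    def test_empty_results_all_zero(self):
        table = aggregate_scores([])
        assert all(v == 0.0 for bucket in table.scores.values()
                   for v in bucket.values())

    def test_hand_summed_aggregation(self):
        runs = [RunResult(TrainConfig(16, "ADAM", 0.001, "softmax"), 0.6),
                RunResult(TrainConfig(16, "SGDM", 0.0005, "softplus"), 0.7)]
        table = aggregate_scores(runs)
        assert table.scores["batch_size"][16] == pytest.approx(0.3)
        assert table.scores["optimizer"]["ADAM"] == pytest.approx(0.1)
        assert table.scores["optimizer"]["SGDM"] == pytest.approx(0.2)

    def test_score_conservation_across_parameters(self):
        rng = np.random.default_rng(3)
        runs = [RunResult(cfg, float(rng.uniform(0, 1)))
                for cfg in enumerate_grid()]
        table = aggregate_scores(runs)
        totals = list(table.totals().values())
        expected = sum(score_model(r.blind_accuracy) for r in runs)
        for t in totals:
            assert t == pytest.approx(expected)


class TestSelection:
    def test_dominant_value_selected_per_parameter(self):
        # one value of each parameter gets uniformly higher accuracy;
        # oracle: exhaustive per-parameter argmax over summed scores
        favored = dict(batch_size=64, optimizer="ADAM", learning_rate=0.0005,
                       activator="softplus")
        runs = []
        for cfg in enumerate_grid():
            acc = 0.55 + 0.05 * sum(
                getattr(cfg, k) == v for k, v in favored.items())
            runs.append(RunResult(cfg, acc))
        table = aggregate_scores(runs)
        # independent argmax oracle
        for name, value in favored.items():
            bucket = table.scores[name]
            assert max(bucket, key=bucket.get) == value
        selected = select_parameters(table)
        assert selected.values() == favored

    def test_tie_broken_by_enumeration_order(self):
        table = aggregate_scores([])  # all zeros: every parameter tied
        selected = select_parameters(table)
        assert selected.values() == dict(
            batch_size=16, optimizer="RMSprop", learning_rate=0.001,
            activator="softmax")

    def test_selection_has_one_value_per_parameter(self):
        rng = np.random.default_rng(0)
        runs = [RunResult(cfg, float(rng.uniform(0.4, 0.9)))
                for cfg in enumerate_grid()]
        selected = select_parameters(aggregate_scores(runs))
        assert set(selected.values()) == set(stage1.PARAMETERS)


def _reference_stopper(losses, patience):
    """Independent simulator of the validation-patience rule."""
    best, best_epoch, since = float("inf"), 0, 0
    for epoch, loss in enumerate(losses, start=1):
        if loss < best:
            best, best_epoch, since = loss, epoch, 0
        else:
            since += 1
        if since >= patience:
            return epoch, best_epoch
    return len(losses), best_epoch


class TestEarlyStopping:
    def test_scripted_sequence_stops_after_seven(self):
        losses = [1.0, 0.9, 0.95, 0.96, 0.97, 0.98, 0.99]
        stopper = EarlyStopping(patience=5)
        stopped_at = None
        for loss in losses:
            if stopper.update(loss):
                stopped_at = stopper.epoch
                break
        assert stopped_at == 7
        assert stopper.best_epoch == 2

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopping(patience=5)
        assert not any(stopper.update(1.0 / (e + 1)) for e in range(100))

    def test_default_max_epochs_and_patience(self):
        cfg = TrainConfig()
        assert cfg.max_epochs == 100 and cfg.patience == 5

    def test_matches_reference_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            losses = rng.uniform(0, 1, size=n).round(2)
            patience = int(rng.integers(1, 8))
            ref_stop, ref_best = _reference_stopper(losses, patience)
            stopper = EarlyStopping(patience)
            for loss in losses:
                if stopper.update(loss):
                    break
            assert stopper.epoch == ref_stop
            assert stopper.best_epoch == ref_best
            assert stopper.epoch <= ref_best + patience


class TestTraining:
    def test_epochs_bounded_and_weights_restored(self, desk_params, effects):
        train = make_dataset("HTX_B", 20, desk_params, effects, seed=1)
        val = make_dataset("HTX_B", 8, desk_params, effects, seed=2)
        h = build_simple_cnn("softmax", 64, np.random.default_rng(0))
        hist = train_model(h, train, val, "ADAM", 0.001, 16,
                           np.random.default_rng(1), max_epochs=4, patience=2)
        assert 1 <= hist.epochs_run <= 4
        assert hist.epochs_run <= hist.best_epoch + 2
        assert hist.best_val_loss == pytest.approx(min(hist.val_losses))

    def test_non_finite_weights_abort_as_failed(self, desk_params, effects):
        train = make_dataset("HTX_B", 4, desk_params, effects, seed=1)
        val = make_dataset("HTX_B", 2, desk_params, effects, seed=2)
        h = build_simple_cnn("softmax", 64, np.random.default_rng(0))
        for p, _ in h.net.parameters():
            p[...] = np.nan
        hist = train_model(h, train, val, "ADAM", 0.001, 4,
                           np.random.default_rng(1), max_epochs=3, patience=2)
        assert hist.failed

    def test_empty_dataset_rejected(self, desk_params, effects):
        val = make_dataset("HTX_B", 2, desk_params, effects, seed=2)
        h = build_simple_cnn("softmax", 64, np.random.default_rng(0))
        from efastnet.training import ImageDataset
        with pytest.raises(ValueError):
            train_model(h, ImageDataset(np.zeros((0, 64, 64)), np.zeros(0)),
                        val, "ADAM", 0.001, 4, np.random.default_rng(1))
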