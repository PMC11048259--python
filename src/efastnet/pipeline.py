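"""End-to-end orchestration: phantom -> preprocess -> stage 1 -> stage 2 ->
LOSO -> Grad-CAM, with every artifact written under one run directory."""

from __future__ import annotations

import itertools
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import explain, loso, models, phantom, preprocess, stage1, stage2
from .config import ExperimentConfig
from .training import ImageDataset, evaluate_accuracy

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "stage1_budgets", "loso_budgets"]

# stage-1/2 sample totals (train/val/test), halved per class when balanced
STAGE_TOTALS = {"B": (2500, 500, 500), "M": (1250, 250, 250)}


def _per_class(total: int, scale: float) -> int:
    return max(1, int(round(total * scale / 2)))


def stage1_budgets(mode: str, scale: float) -> dict[str, int]:
    tr, va, te = STAGE_TOTALS[mode]
    return {"train": _per_class(tr, scale), "val": _per_class(va, scale),
            "test": _per_class(te, scale)}


def loso_budgets(mode: str, scale: float) -> dict[str, int]:
    base = loso.DEFAULT_BUDGETS[mode]
    return {k: max(1, int(round(v * scale))) for k, v in base.items()}


def _subgrid(cfg: ExperimentConfig) -> list[stage1.TrainConfig]:
    if cfg.stage1_values is None:
        return stage1.enumerate_grid(cfg.max_epochs, cfg.patience)
    choices = {name: tuple(cfg.stage1_values.get(name, default))
               for name, default in (
                   ("batch_size", stage1.BATCH_SIZES),
                   ("optimizer", stage1.OPTIMIZERS),
                   ("learning_rate", stage1.LEARNING_RATES),
                   ("activator", stage1.ACTIVATORS))}
    return [stage1.TrainConfig(b, o, lr, a, cfg.max_epochs, cfg.patience)
            for b, o, lr, a in itertools.product(
                choices["batch_size"], choices["optimizer"],
                choices["learning_rate"], choices["activator"])]


def _generate_store(cfg: ExperimentConfig, seed: int) -> preprocess.Datastore:
    params = phantom.PhantomParams(severity=cfg.severity, size=cfg.image_size,
                                   base_seed=seed)
    counts = {}
    for site in cfg.sites:
        if phantom.site_mode(site) == "B":
            counts[site] = cfg.frames_per_subject
        else:
            counts[site] = max(1, round(cfg.frames_per_subject / cfg.mmode_sections))
    cohort = phantom.generate_cohort(params, cfg.n_subjects, counts)
    cohort = preprocess.expand_mmode(cohort, n_sections=cfg.mmode_sections,
                                     target=cfg.image_size)
    return preprocess.build_datastore(cohort)


def _stage_splits(store: preprocess.Datastore, site: str, scale: float,
                  seed: int) -> tuple[ImageDataset, ImageDataset, ImageDataset]:
    """Two subject-disjoint pools: train+val, and blind test (stages 1-2)."""
    subjects = store.subjects(site)
    rng = np.random.default_rng([seed, 11])
    order = list(rng.permutation(subjects))
    n_test = max(1, len(order) // 3)
    test_subjects, pool = order[:n_test], order[n_test:]
    b = stage1_budgets(phantom.site_mode(site), scale)
    joint = preprocess.balanced_sample(store, site, pool,
                                      b["train"] + b["val"], rng)
    pos = [f for f in joint if f.label == "positive"]
    neg = [f for f in joint if f.label == "negative"]
    train = pos[:b["train"]] + neg[:b["train"]]
    val = pos[b["train"]:] + neg[b["train"]:]
    test = preprocess.balanced_sample(store, site, test_subjects, b["test"], rng)
    return (ImageDataset.from_frames(train), ImageDataset.from_frames(val),
            ImageDataset.from_frames(test))


def _builders(cfg: ExperimentConfig, top_spec: models.ArchSpec | None,
              activator_for_optimized: str):
    size = cfg.image_size
    out = {}
    for name in cfg.architectures:
        if name == "simple_cnn":
            out[name] = lambda act, rng: models.build_simple_cnn(act, size, rng)
        elif name == "optimized":
            if top_spec is None:
                logger.warning("no optimized spec available; skipping")
                continue
            out[name] = (lambda act, rng, _s=top_spec:
                         models.build_custom_cnn(_s, activator_for_optimized,
                                                 size, rng))
        else:
            out[name] = (lambda act, rng, _n=name:
                         models.reference_model(_n, False, act, size, rng))
    return out


def run_pipeline(cfg: ExperimentConfig, seed: int | None = None,
                 run_dir: str | Path | None = None) -> Path:
    """Execute the enabled stages for every configured site.

    Returns the run directory; raises on stage failure after retaining
    partial outputs.
    """
    cfg.validate()
    seed = cfg.base_seed if seed is None else seed
    if run_dir is None:
        run_dir = Path(cfg.output_root) / time.strftime("run_%Y%m%d_%H%M%S")
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.dump(run_dir / "config.yaml")
    logger.info("run directory: %s", run_dir)

    store = _generate_store(cfg, seed)
    pd.DataFrame([{"site": k[0], "subject": k[1], "label": k[2], "count": v}
                  for k, v in store.counts().items()]
                 ).to_csv(run_dir / "datastore_counts.csv", index=False)

    summary: dict[str, dict] = {}
    for site in cfg.sites:
        site_dir = run_dir / site
        site_dir.mkdir(exist_ok=True)
        mode = phantom.site_mode(site)
        train, val, test = _stage_splits(store, site, cfg.scale, seed)
        size = cfg.image_size
        selected = stage1.TrainConfig(max_epochs=cfg.max_epochs,
                                      patience=cfg.patience)
        if cfg.train_config:
            selected = stage1.TrainConfig(**cfg.train_config,
                                          max_epochs=cfg.max_epochs,
                                          patience=cfg.patience)
        top_spec = None

        if cfg.stage1:
            grid = _subgrid(cfg)
            _, table, selected, runs = stage1.run_stage1(
                lambda act, rng: models.build_simple_cnn(act, size, rng),
                train, val, test, base_seed=seed, grid=grid)
            runs.to_csv(site_dir / "stage1_runs.csv", index=False)
            (site_dir / "stage1_scores.json").write_text(
                json.dumps(table.to_dict(), indent=1))
            logger.info("%s stage1 selected: %s", site, selected.values())

        if cfg.stage2:
            def objective(spec: models.ArchSpec) -> float:
                rng = np.random.default_rng([seed, 53, len(history_holder)])
                history_holder.append(1)
                handle = models.build_custom_cnn(spec, selected.activator,
                                                 size, rng)
                stage1.train_with_early_stopping(
                    handle, selected, train, val, preprocess.STAGE_POLICY, rng)
                return evaluate_accuracy(handle, test)

            history_holder: list[int] = []
            hist = stage2.run_optimization(
                objective, stage2.default_space(), budget=cfg.stage2_budget,
                rng=np.random.default_rng([seed, 59]))
            hist.to_frame().to_csv(site_dir / "stage2_trials.csv", index=False)
            top3 = stage2.select_top_k(hist, 3)
            (site_dir / "stage2_top3.json").write_text(
                json.dumps([s.to_dict() for s in top3], indent=1))
            top_spec = top3[0]

        loso_rows = None
        if cfg.loso:
            plan = loso.assign_clusters(store.subjects(site), cfg.loso_k,
                                        np.random.default_rng([seed, 61]))
            (site_dir / "loso_plan.json").write_text(
                json.dumps(plan.to_dict(), indent=1))
            builders = _builders(cfg, top_spec, selected.activator)
            results, loso_rows = loso.run_loso(
                builders, plan, store, site, selected,
                loso_budgets(mode, cfg.scale), base_seed=seed)
            loso_rows.to_csv(site_dir / "loso_metrics.csv", index=False)
            agg = {r.architecture: {k: {"mean": m, "sd": s}
                                    for k, (m, s) in r.aggregate().items()}
                   for r in results}
            (site_dir / "loso_aggregate.json").write_text(
                json.dumps(agg, indent=1))
            summary[site] = agg

        if cfg.explain and cfg.loso and loso_rows is not None and len(loso_rows):
            arch = loso_rows.iloc[-1]["architecture"]
            builders = _builders(cfg, top_spec, selected.activator)
            rng = np.random.default_rng([seed, 67])
            handle = builders[arch](selected.activator, rng)
            run = stage1.train_with_early_stopping(
                handle, selected, train, val, preprocess.LOSO_POLICY, rng)
            if not run.failed:
                pred = handle.predict_labels(test.X)
                frames = [phantom.Frame(x, site, "?", "positive" if t else
                                        "negative", str(i))
                          for i, (x, t) in enumerate(zip(test.X, test.y))]
                groups = explain.sample_outcomes(frames, pred, test.y, 5, rng)
                for cat, items in groups.items():
                    for i, fr in enumerate(items):
                        heat = explain.gradcam(handle, fr, target=1)
                        explain.save_overlay(
                            fr.pixels, heat,
                            site_dir / "gradcam" / arch / cat / f"{i}.png")

    (run_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return run_dir
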