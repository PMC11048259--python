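"""Stage 2: Bayesian optimization over the custom-CNN architecture space.

A Gaussian-process surrogate (Matern 5/2) with an expected-improvement
acquisition proposes architecture points; integers are handled by
continuous relaxation and rounding, dropout by snapping to its 0.1 grid.
The first ``n_initial`` trials are uniform random.  Objective per protocol:
blind-test accuracy of the trained candidate (a validation-accuracy switch
is provided as the methodologically conservative alternative).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .models import (ArchSpec, BASE_FILTERS_RANGE, DROPOUT_LEVELS,
                     FILTER_SIZE_RANGE, MULTIPLIER_RANGE, N_LAYERS_RANGE)

logger = logging.getLogger(__name__)

__all__ = [
    "SearchSpace",
    "TrialHistory",
    "default_space",
    "suggest",
    "run_optimization",
    "select_top_k",
]

N_INITIAL = 8  # uniform-random warmup proposals before the surrogate engages


@dataclass(frozen=True)
class SearchSpace:
    filter_size: tuple[int, int] = FILTER_SIZE_RANGE
    n_layers: tuple[int, int] = N_LAYERS_RANGE
    base_filters: tuple[int, int] = BASE_FILTERS_RANGE
    multiplier: tuple[float, float] = MULTIPLIER_RANGE
    dropout_levels: tuple[float, ...] = DROPOUT_LEVELS

    def sample(self, rng: np.random.Generator) -> ArchSpec:
        return ArchSpec(
            filter_size=int(rng.integers(self.filter_size[0], self.filter_size[1] + 1)),
            n_layers=int(rng.integers(self.n_layers[0], self.n_layers[1] + 1)),
            base_filters=int(rng.integers(self.base_filters[0], self.base_filters[1] + 1)),
            multiplier=float(rng.uniform(*self.multiplier)),
            dropout=float(rng.choice(self.dropout_levels)),
        )

    def to_vector(self, spec: ArchSpec) -> np.ndarray:
        return np.array([spec.filter_size, spec.n_layers, spec.base_filters,
                         spec.multiplier, spec.dropout], dtype=float)

    def from_vector(self, v: np.ndarray) -> ArchSpec:
        clip = lambda x, lo, hi: int(np.clip(round(x), lo, hi))
        drop = self.dropout_levels[
            int(np.argmin(np.abs(np.asarray(self.dropout_levels) - v[4])))]
        return ArchSpec(
            filter_size=clip(v[0], *self.filter_size),
            n_layers=clip(v[1], *self.n_layers),
            base_filters=clip(v[2], *self.base_filters),
            multiplier=float(np.clip(v[3], *self.multiplier)),
            dropout=float(drop),
        )


@dataclass
class TrialHistory:
    """Evaluated (spec, objective) pairs with best-so-far tracking."""

    specs: list[ArchSpec] = field(default_factory=list)
    objectives: list[float] = field(default_factory=list)

    def append(self, spec: ArchSpec, objective: float) -> None:
        self.specs.append(spec)
        self.objectives.append(float(objective))

    def __len__(self) -> int:
        return len(self.specs)

    def incumbents(self) -> list[float]:
        """Best objective after each trial — non-decreasing by construction."""
        return list(np.maximum.accumulate(self.objectives)) if self.objectives else []

    def best(self) -> tuple[ArchSpec, float]:
        i = int(np.argmax(self.objectives))
        return self.specs[i], self.objectives[i]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(s.to_dict(), objective=o, incumbent=(o == inc))
                for s, o, inc in zip(self.specs, self.objectives,
                                     self.incumbents())]
        return pd.DataFrame(rows)


def default_space() -> SearchSpace:
    """The architecture search space: filter size 2-7, layers 2-6, base
    filters 2-16 (integers), multiplier 1-2 (real), dropout {0.1..0.9}."""
    return SearchSpace()


def _key(spec: ArchSpec) -> tuple:
    return (spec.filter_size, spec.n_layers, spec.base_filters,
            round(spec.multiplier, 6), round(spec.dropout, 1))


def _expected_improvement(mu: np.ndarray, sd: np.ndarray,
                          best: float, xi: float = 0.01) -> np.ndarray:
    sd = np.maximum(sd, 1e-12)
    z = (mu - best - xi) / sd
    return (mu - best - xi) * norm.cdf(z) + sd * norm.pdf(z)


def suggest(history: TrialHistory, space: SearchSpace,
            rng: np.random.Generator, n_candidates: int = 512) -> ArchSpec:
    """Propose the next architecture.

    The first N_INITIAL proposals are uniform random; afterwards a GP fit to
    the history scores random candidates by expected improvement and the
    best is returned.  A proposal colliding with an evaluated point is
    perturbed to a fresh one.
    """
    seen = {_key(s) for s in history.specs}

    def dedupe(spec: ArchSpec) -> ArchSpec:
        tries = 0
        while _key(spec) in seen:
            spec = space.sample(rng)
            tries += 1
            if tries > 1000:
                raise RuntimeError("search space exhausted")
        return spec

    if len(history) < N_INITIAL:
        return dedupe(space.sample(rng))

    X = np.stack([space.to_vector(s) for s in history.specs])
    y = np.asarray(history.objectives)
    scale = X.max(axis=0) - X.min(axis=0)
    scale[scale == 0] = 1.0
    kernel = (ConstantKernel(1.0) * Matern(length_scale=np.ones(5), nu=2.5)
              + WhiteKernel(1e-4))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                  n_restarts_optimizer=1,
                                  random_state=int(rng.integers(2 ** 31)))
    with warnings.catch_warnings():
        # hyperparameters pinned at bounds are routine on small histories
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X / scale, y)
    cands = [space.sample(rng) for _ in range(n_candidates)]
    Xc = np.stack([space.to_vector(c) for c in cands])
    mu, sd = gp.predict(Xc / scale, return_std=True)
    ei = _expected_improvement(mu, sd, best=y.max())
    order = np.argsort(ei)[::-1]
    for i in order:
        if _key(cands[i]) not in seen:
            return cands[i]
    return dedupe(space.sample(rng))


def run_optimization(objective: Callable[[ArchSpec], float],
                     space: SearchSpace | None = None, budget: int = 100,
                     rng: np.random.Generator | None = None) -> TrialHistory:
    """Evaluate ``budget`` unique architectures, Bayesian-guided.

    An objective that raises is recorded as 0 for that trial and the search
    continues.  Default budget 100 unique combinations.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    space = space or default_space()
    rng = rng or np.random.default_rng(0)
    history = TrialHistory()
    for _ in range(budget):
        spec = suggest(history, space, rng)
        try:
            value = float(objective(spec))
        except Exception:
            logger.warning("objective failed for %s; recording 0", spec,
                           exc_info=True)
            value = 0.0
        history.append(spec, value)
    return history


def select_top_k(history: TrialHistory, k: int = 3) -> list[ArchSpec]:
    """The k highest-objective specs; ties broken by earlier trial index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(range(len(history)),
                   key=lambda i: (-history.objectives[i], i))
    return [history.specs[i] for i in order[:k]]
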