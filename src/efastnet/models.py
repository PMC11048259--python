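"""CNN construction: the simple baseline, the parametric custom family
searched in Stage 2, and a registry of reference architectures.

Every model is a :class:`ModelHandle` exposing raw 2-class scores, final
activation ('softmax' or 'softplus'), parameter count, and a reference to
the last convolutional layer's feature maps for Grad-CAM.

The MobileNetV2 / DarkNet53 / ShrapML registry entries are synthetic,
scaled-down stand-in renditions built from the same layer vocabulary: they
preserve the comparison role (lighter vs. much deeper networks) rather than
the exact published topologies, and no pretrained weights are shipped —
requesting them falls back to random initialization with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np

from . import nn

logger = logging.getLogger(__name__)

__all__ = [
    "ArchSpec",
    "ModelHandle",
    "final_activation",
    "layer_filter_counts",
    "build_simple_cnn",
    "build_custom_cnn",
    "reference_model",
    "register_model",
    "REFERENCE_MODELS",
]

ACTIVATORS = ("softmax", "softplus")

FILTER_SIZE_RANGE = (2, 7)
N_LAYERS_RANGE = (2, 6)
BASE_FILTERS_RANGE = (2, 16)
MULTIPLIER_RANGE = (1.0, 2.0)
DROPOUT_LEVELS = tuple(round(i / 10, 1) for i in range(1, 10))


@dataclass(frozen=True)
class ArchSpec:
    """Architecture point for the Bayesian search.

    filter_size   conv kernel edge, integer in [2, 7]
    n_layers      number of conv blocks, integer in [2, 6]
    base_filters  feature maps in layer 1, integer in [2, 16]
    multiplier    per-layer filter growth factor, real in [1, 2]
    dropout       rate of the dropout layer before the final activation,
                  one of {0.1, ..., 0.9}
    """

    filter_size: int
    n_layers: int
    base_filters: int
    multiplier: float
    dropout: float

    def validate(self) -> None:
        errs = []
        if not FILTER_SIZE_RANGE[0] <= self.filter_size <= FILTER_SIZE_RANGE[1]:
            errs.append(f"filter_size {self.filter_size} not in {FILTER_SIZE_RANGE}")
        if not N_LAYERS_RANGE[0] <= self.n_layers <= N_LAYERS_RANGE[1]:
            errs.append(f"n_layers {self.n_layers} not in {N_LAYERS_RANGE}")
        if not BASE_FILTERS_RANGE[0] <= self.base_filters <= BASE_FILTERS_RANGE[1]:
            errs.append(f"base_filters {self.base_filters} not in {BASE_FILTERS_RANGE}")
        if not MULTIPLIER_RANGE[0] <= self.multiplier <= MULTIPLIER_RANGE[1]:
            errs.append(f"multiplier {self.multiplier} not in {MULTIPLIER_RANGE}")
        if min(abs(self.dropout - lvl) for lvl in DROPOUT_LEVELS) > 1e-9:
            errs.append(f"dropout {self.dropout} not in {DROPOUT_LEVELS}")
        if errs:
            raise ValueError("; ".join(errs))

    def to_dict(self) -> dict:
        return asdict(self)


def final_activation(scores: np.ndarray, kind: str) -> np.ndarray:
    """Final-layer activation over 2-class raw scores.

    softmax:  y_r = exp(a_r) / sum_j exp(a_j), log-sum-exp stabilized.
    softplus: Y = log(1 + e^X) element-wise — positive but not normalized.
    """
    a = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("final_activation requires finite scores")
    if kind == "softmax":
        m = a.max(axis=-1, keepdims=True)
        e = np.exp(a - m)
        return e / e.sum(axis=-1, keepdims=True)
    if kind == "softplus":
        return np.logaddexp(0.0, a)
    raise ValueError(f"unknown activator {kind!r}; choose from {ACTIVATORS}")


def class_probabilities(scores: np.ndarray, kind: str) -> np.ndarray:
    """Per-class probabilities: softmax directly; softplus L1-normalized."""
    act = final_activation(scores, kind)
    if kind == "softplus":
        tot = act.sum(axis=-1, keepdims=True)
        act = np.where(tot > 0, act / np.where(tot == 0, 1.0, tot),
                       np.full_like(act, 0.5))
    return act


def layer_filter_counts(base: int, multiplier: float, n_layers: int) -> list[int]:
    """Filter count per conv layer: round-half-up(base * multiplier**(l-1))."""
    counts = []
    for layer in range(n_layers):
        raw = base * multiplier ** layer
        counts.append(max(1, int(np.floor(raw + 0.5))))
    return counts


@dataclass
class ModelHandle:
    """A built network plus the metadata the pipeline needs."""

    name: str
    net: nn.Sequential
    activator: str
    input_size: int
    spec: ArchSpec | None = None

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        """Raw 2-class scores for a batch (N, H, W) or (N, 1, H, W)."""
        if x.ndim == 3:
            x = x[:, None, :, :]
        return self.net.forward(x.astype(np.float32), train=False)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return class_probabilities(self.predict_scores(x), self.activator)

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        """0 = negative, 1 = positive; exact score ties predict negative."""
        act = final_activation(self.predict_scores(x), self.activator)
        return (act[:, 1] > act[:, 0]).astype(int)

    @property
    def param_count(self) -> int:
        return self.net.param_count()

    @property
    def last_conv_index(self) -> int:
        return self.net.last_conv_index()

    def summary(self) -> dict:
        return {
            "name": self.name,
            "activator": self.activator,
            "input_size": self.input_size,
            "param_count": self.param_count,
            "layers": [type(l).__name__ for l in self.net.layers],
            "spec": self.spec.to_dict() if self.spec else None,
        }


def _conv_ladder(counts: list[int], k: int, input_size: int,
                 rng: np.random.Generator,
                 dropout: float | None = None) -> nn.Sequential:
    layers: list[nn.Layer] = []
    in_ch, size = 1, input_size
    for c in counts:
        layers += [nn.Conv2D(in_ch, c, k, rng), nn.ReLU(), nn.MaxPool2()]
        in_ch, size = c, size // 2
        if size < 1:
            raise ValueError(
                f"input size {input_size} too small for {len(counts)} pooled blocks")
    layers.append(nn.Flatten())
    layers.append(nn.Dense(in_ch * size * size, 2, rng))
    if dropout is not None:
        layers.append(nn.Dropout(dropout, rng))
    return nn.Sequential(layers)


def build_simple_cnn(activator: str = "softmax", input_size: int = 512,
                     rng: np.random.Generator | None = None) -> ModelHandle:
    """The unoptimized baseline: three conv blocks of 16/32/64 3x3 filters,
    each ReLU + 2x2 max-pooled, then a fully connected 2-class head."""
    if activator not in ACTIVATORS:
        raise ValueError(f"activator must be one of {ACTIVATORS}")
    rng = rng or np.random.default_rng(0)
    net = _conv_ladder([16, 32, 64], 3, input_size, rng)
    return ModelHandle("simple_cnn", net, activator, input_size)


def build_custom_cnn(spec: ArchSpec, activator: str = "softmax",
                     input_size: int = 512,
                     rng: np.random.Generator | None = None) -> ModelHandle:
    """A member of the searched family: ``n_layers`` conv blocks whose filter
    counts follow :func:`layer_filter_counts`, a 2-class dense head, then
    dropout before the final activation (inference-time identity)."""
    if activator not in ACTIVATORS:
        raise ValueError(f"activator must be one of {ACTIVATORS}")
    spec.validate()
    rng = rng or np.random.default_rng(0)
    counts = layer_filter_counts(spec.base_filters, spec.multiplier, spec.n_layers)
    net = _conv_ladder(counts, spec.filter_size, input_size, rng,
                       dropout=spec.dropout)
    return ModelHandle("custom_cnn", net, activator, input_size, spec=spec)


def _mobilenet_standin(activator: str, input_size: int,
                       rng: np.random.Generator) -> ModelHandle:
    """Synthetic stand-in for MobileNetV2: a light, moderately deep ladder."""
    net = _conv_ladder([8, 16, 24, 32, 48], 3, input_size, rng)
    return ModelHandle("MobileNetV2", net, activator, input_size)


def _darknet_standin(activator: str, input_size: int,
                     rng: np.random.Generator) -> ModelHandle:
    """Synthetic stand-in for DarkNet53: the deepest, widest ladder here."""
    net = _conv_ladder([16, 32, 64, 96, 128, 160], 3, input_size, rng)
    return ModelHandle("DarkNet53", net, activator, input_size)


def _shrapml_standin(activator: str, input_size: int,
                     rng: np.random.Generator) -> ModelHandle:
    """Synthetic stand-in for ShrapML (a mid-depth CNN previously tuned for
    ultrasound); the published topology is external, so this is a documented,
    non-canonical plug-in."""
    net = _conv_ladder([12, 24, 48, 64], 5, input_size, rng)
    return ModelHandle("ShrapML", net, activator, input_size)


REFERENCE_MODELS: dict[str, Callable] = {
    "MobileNetV2": _mobilenet_standin,
    "DarkNet53": _darknet_standin,
    "ShrapML": _shrapml_standin,
}


def register_model(name: str, builder: Callable) -> None:
    """Register a reference architecture builder
    (signature: (activator, input_size, rng) -> ModelHandle)."""
    REFERENCE_MODELS[name] = builder


def reference_model(name: str, pretrained: bool = False,
                    activator: str = "softmax", input_size: int = 512,
                    rng: np.random.Generator | None = None) -> ModelHandle:
    """Build a registered reference architecture with a 2-class head.

    ``pretrained=True`` is accepted for interface parity but no weights are
    shipped; a warning is logged and random initialization is used.
    """
    if name not in REFERENCE_MODELS:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(REFERENCE_MODELS)}")
    if pretrained:
        logger.warning(
            "pretrained weights for %s are not available; using random init", name)
    rng = rng or np.random.default_rng(0)
    return REFERENCE_MODELS[name](activator, input_size, rng)
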