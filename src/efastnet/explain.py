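"""Model auditing: Grad-CAM heat maps and confusion-category sampling.

Grad-CAM weights each final-conv feature map by the spatial mean of the
gradient of the target-class raw score with respect to that map, rectifies
the weighted sum, min-max normalizes to [0, 1], and upsamples to frame
size.  Sampled TP/TN/FP/FN frames are rendered as red-yellow overlays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from . import nn
from .models import ModelHandle
from .phantom import Frame

__all__ = ["HeatMap", "gradcam", "sample_outcomes", "save_overlay"]


@dataclass
class HeatMap:
    values: np.ndarray          # relevance in [0, 1], frame-sized
    target: int                 # class index the map explains
    model_name: str


def gradcam(handle: ModelHandle, frame: Frame | np.ndarray,
            target: int = 1) -> HeatMap:
    """Grad-CAM relevance map for one frame and target class."""
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    try:
        conv_idx = handle.last_conv_index
    except ValueError as exc:
        raise TypeError("gradcam requires a model with a conv layer") from exc
    x = px.astype(np.float32)[None, None]
    scores = handle.net.forward(x, train=False)
    dscores = np.zeros_like(scores)
    dscores[0, target] = 1.0
    # gradient flowing into the layer *after* the last conv's ReLU output:
    # backprop through everything downstream of the conv block
    dfeat = handle.net.backward(dscores, upto=conv_idx + 1)
    feat = _conv_output(handle, x, conv_idx)
    weights = dfeat.mean(axis=(2, 3))[0]            # (channels,)
    cam = np.maximum((weights[:, None, None] * feat[0]).sum(axis=0), 0.0)
    if cam.max() > cam.min():
        cam = (cam - cam.min()) / (cam.max() - cam.min())
    else:
        cam = np.zeros_like(cam)
    cam = resize(cam, px.shape, order=1, preserve_range=True)
    return HeatMap(np.clip(cam, 0.0, 1.0).astype(np.float32), target,
                   handle.name)


def _conv_output(handle: ModelHandle, x: np.ndarray, conv_idx: int) -> np.ndarray:
    out = x
    for layer in handle.net.layers[: conv_idx + 1]:
        out = layer.forward(out, train=False)
    return out


def sample_outcomes(frames: list[Frame], predictions: np.ndarray,
                    truth: np.ndarray, n_per_category: int = 5,
                    rng: np.random.Generator | None = None,
                    ) -> dict[str, list[Frame]]:
    """Sample up to n frames per confusion category, without replacement."""
    rng = rng or np.random.default_rng(0)
    p = np.asarray(predictions)
    t = np.asarray(truth)
    cats = {
        "TP": np.flatnonzero((p == 1) & (t == 1)),
        "TN": np.flatnonzero((p == 0) & (t == 0)),
        "FP": np.flatnonzero((p == 1) & (t == 0)),
        "FN": np.flatnonzero((p == 0) & (t == 1)),
    }
    out: dict[str, list[Frame]] = {}
    for cat, idx in cats.items():
        take = min(n_per_category, len(idx))
        chosen = rng.choice(idx, size=take, replace=False) if take else []
        out[cat] = [frames[i] for i in chosen]
    return out


def save_overlay(frame_pixels: np.ndarray, heat: HeatMap, path: str | Path,
                 alpha: float = 0.4) -> None:
    """Write an 8-bit PNG of the frame with a red-yellow heat overlay."""
    gray = np.clip(frame_pixels, 0, 1)
    h = heat.values
    # red..yellow ramp: red fixed, green follows relevance
    overlay = np.stack([np.ones_like(h), h, np.zeros_like(h)], axis=-1)
    base = np.repeat(gray[..., None], 3, axis=-1)
    blend = (1 - alpha * h[..., None]) * base + alpha * h[..., None] * overlay
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.clip(blend, 0, 1) * 255).astype(np.uint8))
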