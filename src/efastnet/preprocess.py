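"""Frame preparation: cropping, resizing, M-mode windowing, datastores,
class-balanced sampling, and random augmentation.

The datastore mirrors how a clinical image pool is organized — indexed by
(scan site, subject, injury label) — so that subject-disjoint splits can be
drawn without leakage, and minority-class counts can be matched exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage.transform import resize, rotate, rescale

from .phantom import Frame, MModeCapture, SubjectDataset, site_mode

__all__ = [
    "AugmentPolicy",
    "Datastore",
    "InsufficientDataError",
    "crop_ui",
    "resize_frame",
    "split_mmode_windows",
    "expand_mmode",
    "build_datastore",
    "balanced_sample",
    "apply_augment",
    "STAGE_POLICY",
    "LOSO_POLICY",
]


@dataclass(frozen=True)
class AugmentPolicy:
    """Random augmentation: y-reflection, rotation, multiplicative rescale."""

    reflect_y: bool = True
    max_rotation: float = 36.0           # degrees, either direction
    scale_range: tuple[float, float] = (0.90, 1.10)

    def __post_init__(self):
        if self.max_rotation < 0:
            raise ValueError("max_rotation must be non-negative")
        lo, hi = self.scale_range
        if not 0 < lo <= hi:
            raise ValueError("scale_range must satisfy 0 < low <= high")

    @property
    def is_identity(self) -> bool:
        return (not self.reflect_y and self.max_rotation == 0
                and self.scale_range == (1.0, 1.0))


# optimization stages: 36 deg rotation, 0.90-1.10 rescale
STAGE_POLICY = AugmentPolicy(True, 36.0, (0.90, 1.10))
# LOSO runs: 10% rotation (read as +/-10 degrees) and +/-10% rescale
LOSO_POLICY = AugmentPolicy(True, 10.0, (0.90, 1.10))


class InsufficientDataError(RuntimeError):
    """Raised when a balanced sample cannot be filled; carries deficits."""

    def __init__(self, deficits: dict[str, int]):
        self.deficits = deficits
        super().__init__(f"insufficient frames per class: {deficits}")


def crop_ui(frame: Frame, top: int = 0, bottom: int = 0,
            left: int = 0, right: int = 0) -> Frame:
    """Crop fixed margins (scanner UI chrome) off a frame."""
    h, w = frame.pixels.shape
    if min(top, bottom, left, right) < 0:
        raise ValueError("margins must be non-negative")
    if top + bottom >= h or left + right >= w:
        raise ValueError(
            f"margins ({top},{bottom},{left},{right}) consume the {h}x{w} frame")
    px = frame.pixels[top:h - bottom, left:w - right]
    mask = frame.mask[top:h - bottom, left:w - right] if frame.mask is not None else None
    return Frame(px, frame.site, frame.subject_id, frame.label,
                 frame.provenance, mask=mask)


def resize_frame(frame: Frame, target: int = 512) -> Frame:
    """Bilinear resize to target x target, clamped to [0, 1]."""
    if target < 1:
        raise ValueError("target must be >= 1")
    if frame.pixels.shape == (target, target):
        return frame
    px = resize(frame.pixels, (target, target), order=1, mode="reflect",
                anti_aliasing=False, preserve_range=True)
    px = np.clip(px, 0.0, 1.0).astype(np.float32)
    mask = None
    if frame.mask is not None:
        mask = resize(frame.mask, (target, target), order=0,
                      preserve_range=True).astype(np.float32)
    return Frame(px, frame.site, frame.subject_id, frame.label,
                 frame.provenance, mask=mask)


def split_mmode_windows(capture: MModeCapture, window: float = 1.0,
                        n_sections: int = 25,
                        target: int | None = None) -> list[Frame]:
    """Rolling-window split of an M-mode capture into fixed-length sections.

    Start times are evenly spaced with stride (duration - window) /
    (n_sections - 1) — the unique even tiling that yields 25 overlapping
    one-second sections from a 5 s capture.  Each section becomes a Frame
    (optionally resized to ``target`` square) with its index in provenance.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if window > capture.duration:
        raise ValueError(
            f"window {window}s exceeds capture duration {capture.duration}s")
    cps = capture.columns_per_second
    win_cols = max(1, round(window * cps))
    total_cols = capture.matrix.shape[1]
    if window == capture.duration or n_sections == 1:
        starts = [0.0]
    else:
        stride = (capture.duration - window) / (n_sections - 1)
        starts = [i * stride for i in range(n_sections)]
    out = []
    for i, t0 in enumerate(starts):
        c0 = min(round(t0 * cps), total_cols - win_cols)
        sect = capture.matrix[:, c0:c0 + win_cols]
        msk = capture.mask[:, c0:c0 + win_cols] if capture.mask is not None else None
        fr = Frame(sect, capture.site, capture.subject_id, capture.label,
                   f"{capture.provenance}/w{i}", mask=msk)
        if target is not None:
            fr = resize_frame(fr, target)
        out.append(fr)
    return out


def expand_mmode(cohort: Sequence[SubjectDataset], window: float = 1.0,
                 n_sections: int = 25,
                 target: int | None = None) -> list[SubjectDataset]:
    """Replace every M-mode capture in a cohort by its windowed sections."""
    out = []
    for ds in cohort:
        new = SubjectDataset(ds.subject_id, ds.protocol_tag)
        for code, items in ds.frames.items():
            if site_mode(code) == "M":
                frames: list[Frame] = []
                for cap in items:
                    frames.extend(split_mmode_windows(cap, window, n_sections, target))
                new.frames[code] = frames
            else:
                new.frames[code] = list(items)
        out.append(new)
    return out


@dataclass
class Datastore:
    """Index of frames keyed by (site, subject, label)."""

    index: dict[tuple[str, str, str], list[Frame]] = field(default_factory=dict)

    def add(self, frame: Frame) -> None:
        key = (frame.site, frame.subject_id, frame.label)
        self.index.setdefault(key, []).append(frame)

    def counts(self) -> dict[tuple[str, str, str], int]:
        return {k: len(v) for k, v in self.index.items()}

    def total(self) -> int:
        return sum(len(v) for v in self.index.values())

    def subjects(self, site: str | None = None) -> list[str]:
        subs = {k[1] for k in self.index
                if site is None or k[0] == site}
        return sorted(subs)

    def frames_for(self, site: str, subjects: Iterable[str],
                   label: str) -> list[Frame]:
        out = []
        for sub in subjects:
            out.extend(self.index.get((site, sub, label), []))
        return out


def build_datastore(cohort: Sequence[SubjectDataset]) -> Datastore:
    """Index a cohort; duplicate provenance within a subject is corrupt input."""
    store = Datastore()
    for ds in cohort:
        seen: set[tuple[str, str]] = set()
        for item in ds.items():
            if not isinstance(item, Frame):
                raise TypeError(
                    "datastore holds frames; expand M-mode captures first "
                    "(preprocess.expand_mmode)")
            if item.subject_id != ds.subject_id:
                raise ValueError(
                    f"frame subject {item.subject_id!r} does not match "
                    f"container {ds.subject_id!r}")
            key = (item.site, item.provenance)
            tag = (key[0], f"{item.label}:{key[1]}")
            if tag in seen:
                raise ValueError(
                    f"duplicate provenance {item.provenance!r} for subject "
                    f"{ds.subject_id}, site {item.site}")
            seen.add(tag)
            store.add(item)
    return store


def balanced_sample(store: Datastore, site: str, subjects: Sequence[str],
                    n_per_class: int, rng: np.random.Generator) -> list[Frame]:
    """Sample exactly n_per_class positives and negatives without replacement,
    restricted to the given subjects (class balancing by matching counts)."""
    if n_per_class < 0:
        raise ValueError("n_per_class must be non-negative")
    pools = {lab: store.frames_for(site, subjects, lab)
             for lab in ("positive", "negative")}
    deficits = {lab: n_per_class - len(pool)
                for lab, pool in pools.items() if len(pool) < n_per_class}
    if deficits:
        raise InsufficientDataError(deficits)
    out: list[Frame] = []
    for lab in ("positive", "negative"):
        pool = pools[lab]
        idx = rng.choice(len(pool), size=n_per_class, replace=False)
        out.extend(pool[i] for i in idx)
    return out


def augment_pixels(px: np.ndarray, policy: AugmentPolicy,
                   rng: np.random.Generator) -> np.ndarray:
    """Array-level augmentation: reflect -> rotate -> rescale, 0-filled."""
    if policy.is_identity:
        return px
    if policy.reflect_y and rng.random() < 0.5:
        px = px[:, ::-1]
    angle = rng.uniform(-policy.max_rotation, policy.max_rotation)
    if angle != 0.0:
        px = rotate(px, angle, resize=False, order=1, mode="constant",
                    cval=0.0, preserve_range=True)
    lo, hi = policy.scale_range
    factor = rng.uniform(lo, hi)
    if factor != 1.0:
        px = _rescale_keep_extent(px, factor)
    return np.clip(px, 0.0, 1.0).astype(np.float32)


def apply_augment(frame: Frame, policy: AugmentPolicy,
                  rng: np.random.Generator) -> Frame:
    """Random reflect -> rotate -> rescale; extents preserved, borders 0-filled."""
    px = augment_pixels(frame.pixels, policy, rng)
    return Frame(px, frame.site, frame.subject_id, frame.label,
                 frame.provenance, mask=None)


def _rescale_keep_extent(px: np.ndarray, factor: float) -> np.ndarray:
    h, w = px.shape
    scaled = rescale(px, factor, order=1, mode="constant", cval=0.0,
                     preserve_range=True, anti_aliasing=False)
    sh, sw = scaled.shape
    out = np.zeros((h, w), dtype=scaled.dtype)
    if factor >= 1.0:  # center crop
        r0, c0 = (sh - h) // 2, (sw - w) // 2
        out[...] = scaled[r0:r0 + h, c0:c0 + w]
    else:  # center pad
        r0, c0 = (h - sh) // 2, (w - sw) // 2
        out[r0:r0 + sh, c0:c0 + sw] = scaled
    return out
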