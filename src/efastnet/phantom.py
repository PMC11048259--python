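"""Synthetic eFAST ultrasound phantom generator.

Emulates the statistical structure of a swine eFAST image cohort: Rayleigh
speckle B-mode frames and depth-vs-time M-mode captures at six scan sites,
binary injury labels realised as anechoic free-fluid signals whose strength
is a tunable effect size (``severity``), and per-subject random effects so
leave-one-subject-out evaluation is a meaningful generalization test.

Scan sites
----------
RUQ    hepatorenal recess (B-mode); positive = fluid along the liver/kidney
       interface.
BLD    pelvic/bladder view (B-mode); the anechoic bladder itself varies in
       size frame to frame, and positive adds a second anechoic pocket
       beside it — two varying factors by design.
PTX_B  pneumothorax, B-mode; positive only *suppresses* sub-pleural texture
       (a deliberately weak cue: air gives no bright geometric target).
HTX_B  hemothorax, B-mode; positive = anechoic band under the pleural line.
PTX_M  pneumothorax, M-mode; positive = static "barcode" striation replacing
       the granular "seashore" texture below the pleural line.
HTX_M  hemothorax, M-mode; positive = anechoic widening of the pleural space.

At ``severity = 0`` the injury signal vanishes exactly: a positive and a
negative render from the same generator state are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SITE_CODES",
    "B_MODE_SITES",
    "M_MODE_SITES",
    "ScanSite",
    "InjuryLabel",
    "Frame",
    "MModeCapture",
    "SubjectEffects",
    "PhantomParams",
    "SubjectDataset",
    "site_mode",
    "sample_subject_effects",
    "speckle_field",
    "render_bmode",
    "render_mmode",
    "generate_cohort",
    "canonical_fluid_region",
    "save_cohort",
]

B_MODE_SITES = ("RUQ", "BLD", "PTX_B", "HTX_B")
M_MODE_SITES = ("PTX_M", "HTX_M")
SITE_CODES = B_MODE_SITES + M_MODE_SITES

POSITIVE = "positive"
NEGATIVE = "negative"
LABELS = (POSITIVE, NEGATIVE)


def site_mode(code: str) -> str:
    """Imaging mode for a scan-site code: 'B' (frame) or 'M' (depth-time)."""
    if code in B_MODE_SITES:
        return "B"
    if code in M_MODE_SITES:
        return "M"
    raise ValueError(f"unknown scan site {code!r}; expected one of {SITE_CODES}")


@dataclass(frozen=True)
class ScanSite:
    code: str

    def __post_init__(self):
        site_mode(self.code)  # validates

    @property
    def mode(self) -> str:
        return site_mode(self.code)


@dataclass(frozen=True)
class InjuryLabel:
    value: str

    def __post_init__(self):
        if self.value not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.value!r}")

    @property
    def is_positive(self) -> bool:
        return self.value == POSITIVE


@dataclass
class Frame:
    """One grayscale image with provenance; pixels in [0, 1], float32."""

    pixels: np.ndarray
    site: str
    subject_id: str
    label: str
    provenance: str
    mask: np.ndarray | None = None  # truth fluid mask; never shown to models

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("Frame.pixels must be a non-empty 2-D grid")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class MModeCapture:
    """Depth x time intensity matrix over a fixed acquisition window."""

    matrix: np.ndarray
    site: str
    subject_id: str
    label: str
    provenance: str
    duration: float = 5.0
    columns_per_second: float = 100.0
    tick_spacing: float = 0.2  # seconds between display tick marks
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.duration <= 0 or self.tick_spacing <= 0:
            raise ValueError("duration and tick_spacing must be positive")
        want = round(self.duration * self.columns_per_second)
        if self.matrix.shape[1] != want:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns; "
                f"duration x rate requires {want}")


@dataclass(frozen=True)
class SubjectEffects:
    """Per-subject random effects, a deterministic draw from PhantomParams."""

    gain_offset: float
    grain_scale: float
    depth_jitter: float
    geometry_jitter: tuple[float, ...]


@dataclass(frozen=True)
class PhantomParams:
    severity: float = 1.0          # injury effect size in [0, 1]
    speckle_sigma: float = 0.18    # Rayleigh scale of the speckle amplitude
    grain: float = 1.5             # speckle correlation length, pixels
    size: int = 512                # rendered frame edge, pixels
    mmode_columns_per_second: float = 100.0
    mmode_duration: float = 5.0
    gain_sd: float = 0.04          # SD of per-subject brightness offset
    grain_sd: float = 0.25         # SD of per-subject grain perturbation
    depth_jitter_sd: float = 0.02  # SD of anatomy depth shift, frac. of height
    geometry_jitter_sd: float = 0.03
    base_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")
        if self.size < 8:
            raise ValueError("size must be at least 8 pixels")


@dataclass
class SubjectDataset:
    subject_id: str
    protocol_tag: str
    frames: dict[str, list] = field(default_factory=dict)  # site -> Frame/MModeCapture

    def items(self) -> Iterable:
        for site in self.frames:
            yield from self.frames[site]


def sample_subject_effects(params: PhantomParams, subject_seed: int) -> SubjectEffects:
    """Draw one subject's random effects; pure function of (params, seed)."""
    if subject_seed < 0:
        raise ValueError("subject_seed must be non-negative")
    rng = np.random.default_rng([params.base_seed, 7919, subject_seed])
    gain = float(rng.normal(0.0, params.gain_sd)) if params.gain_sd > 0 else 0.0
    grain = params.grain + (float(rng.normal(0.0, params.grain_sd))
                            if params.grain_sd > 0 else 0.0)
    depth = (float(rng.normal(0.0, params.depth_jitter_sd))
             if params.depth_jitter_sd > 0 else 0.0)
    geom = tuple(
        float(g) for g in (rng.normal(0.0, params.geometry_jitter_sd, size=4)
                           if params.geometry_jitter_sd > 0 else np.zeros(4)))
    # bound so a clamp to [0,1] stays meaningful
    gain = float(np.clip(gain, -0.2, 0.2))
    grain = float(np.clip(grain, 0.0, 8.0))
    depth = float(np.clip(depth, -0.1, 0.1))
    return SubjectEffects(gain, grain, depth, geom)


def speckle_field(height: int, width: int, sigma: float, grain: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Fully developed speckle: |smoothed complex Gaussian field|, clamped.

    The in-phase and quadrature components are i.i.d. N(0, sigma^2); their
    magnitude is Rayleigh(sigma) with mean sigma*sqrt(pi/2).  ``grain``
    (Gaussian smoothing width in pixels) sets the correlation length; the
    smoothed field is rescaled so the marginal scale stays sigma.
    """
    if height < 1 or width < 1:
        raise ValueError("speckle_field dimensions must be positive")
    if sigma < 0 or grain < 0:
        raise ValueError("sigma and grain must be non-negative")
    if sigma == 0:
        return np.zeros((height, width), dtype=np.float32)
    re = rng.normal(0.0, sigma, size=(height, width))
    im = rng.normal(0.0, sigma, size=(height, width))
    if grain > 0:
        re = gaussian_filter(re, grain, mode="reflect")
        im = gaussian_filter(im, grain, mode="reflect")
        # restore the marginal scale removed by averaging
        gain = max(np.std(re), 1e-12)
        re = re * (sigma / gain)
        im = im * (sigma / max(np.std(im), 1e-12))
    amp = np.hypot(re, im)
    return np.clip(amp, 0.0, 1.0).astype(np.float32)


def _norm_grid(size: int):
    y = np.linspace(0.0, 1.0, size)[:, None]
    x = np.linspace(0.0, 1.0, size)[None, :]
    return y, x


def render_bmode(site: ScanSite | str, label: InjuryLabel | str,
                 params: PhantomParams, effects: SubjectEffects,
                 rng: np.random.Generator) -> Frame:
    """Render one B-mode frame for a scan site, subject, and injury label.

    All random draws are made identically for both labels; the injury signal
    is applied last, only for positives, with magnitude scaled by
    ``params.severity`` — so at severity 0 matched-state renders coincide.
    """
    code = site.code if isinstance(site, ScanSite) else site
    lab = label.value if isinstance(label, InjuryLabel) else label
    if site_mode(code) != "B":
        raise ValueError(f"render_bmode requires a B-mode site, got {code}")
    if lab not in LABELS:
        raise ValueError(f"bad label {lab!r}")
    n = params.size
    img = speckle_field(n, n, params.speckle_sigma, effects.grain_scale, rng)
    y, x = _norm_grid(n)
    gj = effects.geometry_jitter
    sev = params.severity
    mask = np.zeros((n, n), dtype=np.float32)

    if code == "RUQ":
        # bright curved hepatorenal interface
        yc = 0.45 + effects.depth_jitter + gj[0]
        curve = yc + 0.25 * (x - 0.5 + gj[1]) ** 2
        band = np.exp(-((y - curve) / 0.02) ** 2)
        img = np.clip(img + 0.55 * band, 0.0, 1.0)
        # fluid pocket hugging the interface from below, area ~ severity
        half_w = 0.22 * np.sqrt(sev)
        depth_ext = 0.06 * sev
        lens = ((np.abs(x - 0.5 - gj[2]) < half_w)
                & (y > curve + 0.015) & (y < curve + 0.015 + depth_ext))
        mask[lens] = 1.0
    elif code == "BLD":
        # anechoic bladder with per-frame randomized size + posterior enhancement
        rx = rng.uniform(0.10, 0.22)
        ry = rx * rng.uniform(0.7, 0.95)
        cx = 0.5 + gj[0]
        cy = 0.42 + effects.depth_jitter + gj[1]
        bladder = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 < 1.0
        img[bladder] *= 0.06
        post = ((np.abs(x - cx) < rx) & (y > cy + ry) & (y < cy + ry + 0.12))
        img = np.clip(img + 0.25 * post, 0.0, 1.0)
        # hemorrhage pocket adjacent to the bladder, area ~ severity
        prx = 0.13 * np.sqrt(sev)
        pry = 0.09 * np.sqrt(sev)
        pcx = cx + rx + prx + 0.02
        pcy = cy + 0.05 + gj[2]
        pocket = ((x - pcx) / max(prx, 1e-9)) ** 2 + \
                 ((y - pcy) / max(pry, 1e-9)) ** 2 < 1.0
        if sev > 0:
            mask[pocket] = 1.0
    elif code in ("PTX_B", "HTX_B"):
        yp = 0.32 + effects.depth_jitter + gj[0]  # pleural line depth
        # vertical rib shadows
        for cx_ in (0.18 + gj[1], 0.82 + gj[2]):
            shadow = (np.abs(x - cx_) < 0.07) & (y > yp - 0.08)
            img[shadow] *= 0.3
        pleural = np.exp(-((y - yp) / 0.012) ** 2)
        img = np.clip(img + 0.6 * pleural, 0.0, 1.0)
        if code == "HTX_B":
            # anechoic blood band below the pleural line
            thick = 0.16 * sev
            band = ((y > yp + 0.02) & (y < yp + 0.02 + thick)
                    & (np.abs(x - 0.5) < 0.28))
            mask[band] = 1.0
        else:  # PTX_B: texture suppression only — deliberately weak signal
            sub = (y > yp + 0.02) & (np.abs(x - 0.5) < 0.28)
            mask[sub & (y < yp + 0.22)] = 1.0
            if lab == POSITIVE and sev > 0:
                region = img[sub]
                img[sub] = region.mean() + (region - region.mean()) * (1 - 0.7 * sev)
    if lab == POSITIVE and sev > 0 and code != "PTX_B":
        m = mask.astype(bool)
        img[m] = img[m] * 0.05  # anechoic: near-zero echo
    img = np.clip(img + effects.gain_offset, 0.0, 1.0).astype(np.float32)
    return Frame(img, code, "", lab, "",
                 mask=mask if (lab == POSITIVE and sev > 0) else None)


def render_mmode(site: ScanSite | str, label: InjuryLabel | str,
                 params: PhantomParams, effects: SubjectEffects,
                 rng: np.random.Generator) -> MModeCapture:
    """Render one M-mode capture (depth rows x time columns).

    Negative: granular, column-varying "seashore" texture below a bright
    pleural line.  PTX_M positive blends in a temporally static "barcode"
    striation; HTX_M positive inserts an anechoic band that widens the
    pleural space.  Injury magnitude scales with ``params.severity``.
    """
    code = site.code if isinstance(site, ScanSite) else site
    lab = label.value if isinstance(label, InjuryLabel) else label
    if site_mode(code) != "M":
        raise ValueError(f"render_mmode requires an M-mode site, got {code}")
    if lab not in LABELS:
        raise ValueError(f"bad label {lab!r}")
    rows = params.size
    cols = round(params.mmode_duration * params.mmode_columns_per_second)
    sev = params.severity
    depth = np.linspace(0.0, 1.0, rows)[:, None]
    yp = 0.3 + effects.depth_jitter + effects.geometry_jitter[0]
    ip = int(round(yp * rows))

    # chest wall above the pleural line: smooth horizontal layers, static in time
    wall_profile = 0.25 + 0.2 * np.sin(depth * 40.0 + 10 * effects.geometry_jitter[1]) ** 2
    wall_noise = speckle_field(rows, cols, 0.05, effects.grain_scale, rng)
    img = np.clip(wall_profile + wall_noise, 0.0, 1.0)

    # seashore: granular speckle below the line, varying along time
    sea = speckle_field(rows, cols, params.speckle_sigma, 0.8, rng)
    below = depth > yp
    img = np.where(below, sea, img)

    # barcode: static striation, drawn for every render (rng parity across labels)
    stripe = 0.15 + 0.45 * np.sin(depth * 120.0 + 10 * effects.geometry_jitter[2]) ** 2
    bar_noise = rng.normal(0.0, 0.02, size=(rows, 1))
    barcode = np.clip(stripe + bar_noise, 0.0, 1.0) * np.ones((1, cols))

    mask = np.zeros((rows, cols), dtype=np.float32)
    if code == "PTX_M":
        mask[below.repeat(cols, axis=1)] = 1.0
        if lab == POSITIVE and sev > 0:
            img = np.where(below, (1 - sev) * img + sev * barcode, img)
    else:  # HTX_M: anechoic pleural-space widening
        width_frac = 0.22 * sev
        band = (depth > yp + 0.015) & (depth < yp + 0.015 + width_frac)
        band2d = band.repeat(cols, axis=1)
        mask[band2d] = 1.0
        if lab == POSITIVE and sev > 0:
            shift = int(round(width_frac * rows))
            if shift > 0:
                lung = img[ip:rows - shift, :]
                img = img.copy()
                img[ip + shift:, :] = lung
            img[band2d] *= 0.05
    # bright pleural line drawn last so it stays visible
    pleural = np.exp(-((depth - yp) / 0.012) ** 2)
    img = np.clip(img + 0.6 * pleural + effects.gain_offset, 0.0, 1.0)
    return MModeCapture(img.astype(np.float32), code, "", lab, "",
                        duration=params.mmode_duration,
                        columns_per_second=params.mmode_columns_per_second,
                        mask=mask if (lab == POSITIVE and sev > 0) else None)


def canonical_fluid_region(site: str, size: int) -> np.ndarray:
    """Boolean mask of the default-geometry fluid location for a B site.

    A fixed, generator-independent discriminant region used for effect-size
    monotonicity checks: mean intensity inside it separates positives from
    negatives increasingly well as severity grows.
    """
    y, x = _norm_grid(size)
    if site == "RUQ":
        curve = 0.45 + 0.25 * (x - 0.5) ** 2
        return (np.abs(x - 0.5) < 0.18) & (y > curve + 0.015) & (y < curve + 0.07)
    if site == "BLD":
        return ((x - 0.78) / 0.10) ** 2 + ((y - 0.47) / 0.07) ** 2 < 1.0
    if site in ("PTX_B", "HTX_B"):
        return (y > 0.34) & (y < 0.46) & (np.abs(x - 0.5) < 0.25)
    raise ValueError(f"no canonical B-mode fluid region for site {site!r}")


def generate_cohort(params: PhantomParams, n_subjects: int,
                    per_subject_counts: Mapping[str, int]) -> list[SubjectDataset]:
    """Generate a reproducible multi-subject cohort.

    ``per_subject_counts`` maps site code -> number of items *per label*
    (B-mode frames, or M-mode captures).  Every stream is derived from
    ``params.base_seed``; regenerating with the same params gives identical
    pixels.
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be non-negative")
    for code, cnt in per_subject_counts.items():
        site_mode(code)
        if cnt < 0:
            raise ValueError(f"negative count for site {code}")
    cohort: list[SubjectDataset] = []
    for s in range(n_subjects):
        sid = f"S{s:03d}"
        effects = sample_subject_effects(params, s)
        ds = SubjectDataset(subject_id=sid, protocol_tag="synthetic")
        for code, cnt in per_subject_counts.items():
            items = []
            for li, lab in enumerate(LABELS):
                for i in range(cnt):
                    rng = np.random.default_rng(
                        [params.base_seed, 104729, s, _site_index(code), li, i])
                    if site_mode(code) == "B":
                        fr = render_bmode(code, lab, params, effects, rng)
                        fr.subject_id = sid
                        fr.provenance = f"clip{li}_{i}"
                        items.append(fr)
                    else:
                        cap = render_mmode(code, lab, params, effects, rng)
                        cap.subject_id = sid
                        cap.provenance = f"cap{li}_{i}"
                        items.append(cap)
            ds.frames[code] = items
        cohort.append(ds)
    return cohort


def _site_index(code: str) -> int:
    return SITE_CODES.index(code)


def save_cohort(cohort: list[SubjectDataset], root: str | Path,
                severity: float | None = None) -> pd.DataFrame:
    """Export frames as 8-bit PNGs plus CSV and JSON manifests.

    Layout: ``<root>/<site>/<subject_id>/<label>/<index>.png``.  M-mode
    captures are saved as full depth-time images.  Returns the manifest.
    """
    root = Path(root)
    records = []
    for ds in cohort:
        for code, items in ds.frames.items():
            counters: dict[str, int] = {}
            for item in items:
                idx = counters.get(item.label, 0)
                counters[item.label] = idx + 1
                out = root / code / ds.subject_id / item.label / f"{idx:04d}.png"
                out.parent.mkdir(parents=True, exist_ok=True)
                arr = item.pixels if isinstance(item, Frame) else item.matrix
                iio.imwrite(out, (np.clip(arr, 0, 1) * 255).astype(np.uint8))
                records.append({
                    "path": str(out.relative_to(root)),
                    "site": code,
                    "mode": site_mode(code),
                    "subject": ds.subject_id,
                    "label": item.label,
                    "severity": severity if severity is not None else float("nan"),
                })
    manifest = pd.DataFrame.from_records(
        records, columns=["path", "site", "mode", "subject", "label", "severity"])
    root.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(root / "manifest.csv", index=False)
    manifest.to_json(root / "manifest.json", orient="records", indent=1)
    return manifest
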