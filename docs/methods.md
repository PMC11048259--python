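# Methods

## What the phantom emulates — and what it does not

Real eFAST clips are coherent ultrasound images: granular speckle texture,
site-specific anatomy, and, in injured subjects, anechoic (near-black)
pockets of free fluid or, for pneumothorax, the loss of lung-sliding
motion. The generator reproduces the *statistical* structure a classifier
pipeline interacts with, not the acoustics:

- **Speckle.** Fully developed speckle is modelled as the magnitude of a
  complex Gaussian field — in-phase and quadrature components i.i.d.
  N(0, σ²) — giving Rayleigh-distributed amplitudes with mean σ√(π/2).
  A correlation length ("grain", Gaussian smoothing of the complex field
  before taking the magnitude, rescaled to preserve the marginal σ)
  controls texture coarseness. Defaults: σ = 0.18, grain 1.5 px.
- **Site templates.** RUQ: a bright curved hepatorenal interface; BLD: an
  anechoic bladder ellipse whose radius is re-drawn per frame (0.10–0.22 of
  width) plus posterior enhancement; PTX_B/HTX_B: vertical rib shadows and
  a bright pleural line. M-mode negatives show a static layered chest wall
  above the pleural line and granular, column-varying "seashore" texture
  below it.
- **Injury signal and effect size.** `severity` ∈ [0, 1] scales the injury:
  RUQ/BLD/HTX_B positives insert an anechoic region (area ∝ severity,
  intensity ×0.05); PTX_B positives only *suppress* sub-pleural texture
  contrast (a deliberately weak cue — B-mode pneumothorax offers no bright
  geometric target, and the corresponding classifiers are expected to be
  the hardest); PTX_M positives blend in a temporally static "barcode"
  striation; HTX_M positives insert an anechoic band that widens the
  pleural space. All random draws are made identically for both labels and
  the injury is applied last, so at severity 0 a positive and a negative
  render from the same generator state are **bit-identical** — an exact
  null for power-style tests.
- **Subject effects.** Each subject draws a brightness offset
  (N(0, 0.04)), a grain perturbation (N(0, 0.25)), an anatomy depth shift
  (N(0, 0.02) of height) and four geometry jitters (N(0, 0.03)),
  deterministically from (params, subject seed). These create the
  between-subject covariate shift that makes LOSO evaluation informative.

Not modelled: wave propagation, transducer point-spread functions, probe
pressure and angle variation, motion artefacts, live-animal vs post-mortem
acquisition differences, and operator variability. Passing tests therefore
demonstrate that the *pipeline* (optimization, selection, cross-validation,
metrics) behaves correctly on data with the assumed statistical structure;
they say nothing about classifier accuracy on clinical images.

Truth masks of the inserted fluid are stored next to each positive frame
for generator-level checks (effect-size monotonicity, Grad-CAM
localization) and are never exposed to classifiers.

## Model family and training

The baseline CNN is three conv blocks of 16/32/64 3×3 filters, each
ReLU + 2×2 max-pool, flattened into a two-output dense head. The searched
family generalizes this: `n_layers` blocks whose filter counts follow
round-half-up(base · multiplier^(l−1)), a dense head, then dropout before
the final activation. Pooling after every conv block is applied uniformly
across the family (the baseline defines the pattern; without it, deep
members at 512 px would be impractically large). Conv stride is 1 with
"same" padding; weights are He-normal.

Final activations: softmax y_r = exp(a_r)/Σ_j exp(a_j) (log-sum-exp
stabilized) or element-wise softplus log(1 + eˣ). The softplus head is not
normalized; probabilities for loss and AUROC are its L1-normalized outputs,
and hard labels are the argmax of the activation, with exact ties resolved
to negative. Optimizers use conventional defaults (SGDM momentum 0.9, ADAM
β = 0.9/0.999, RMSprop ρ = 0.9).

Early stopping ("validation patience"): the best validation loss so far is
tracked with zero minimum delta; training halts after `patience = 5`
consecutive epochs without a new best and the best epoch's weights are
restored. A non-finite training or validation loss aborts the run, which
is recorded as a zero-accuracy failure rather than raised.

The CNN engine is pure numpy (im2col convolutions, index-tracked pooling,
explicit backward passes). This keeps the package self-contained, exactly
seedable, and lets Grad-CAM reuse the training backward pass. The
MobileNetV2/DarkNet53/ShrapML registry entries are synthetic stand-in
ladders of matching character (light-and-deep, heavy-and-deepest,
mid-depth) built from the same layers; they preserve the role of
"reference architecture" in comparisons without claiming the published
topologies, and no pretrained weights exist (requesting them logs a
warning and falls back to random initialization).

## Stage 1 — grid and score aggregation

54 configurations (3 batch sizes × 3 optimizers × 3 learning rates × 2
activators) are trained independently with per-run seeds derived by
hashing (base seed, run index). Each run's blind-test accuracy a maps to a
score max(a − 0.5, 0), which is added to the accumulated score of each of
the run's four parameter values; per-parameter argmax wins, ties resolved
to the first value in enumeration order and logged. Score totals are
conserved across parameters (every run contributes once per parameter),
which the tests assert.

## Stage 2 — Bayesian architecture search

Surrogate: sklearn Gaussian process with a Matérn-5/2 kernel plus white
noise on inputs scaled to unit range, refit each trial. Acquisition:
expected improvement (ξ = 0.01) maximized over 512 random candidates —
adequate for a 5-dimensional, mostly discrete space. The first 8 trials
are uniform random; integers are handled by rounding, dropout snaps to its
0.1 grid, and proposals colliding with evaluated points are re-drawn, so
all trials are unique. The objective is blind-test accuracy, as the
protocol specifies; note this leaks the test set into model selection —
the behaviour is implemented as specified and documented rather than
silently corrected (validation accuracy can be substituted by passing a
different objective callable).

## LOSO protocol

Subjects are randomly partitioned (seeded) into k clusters whose sizes
differ by at most one; the plan is persisted and shared by all
architectures so comparisons see identical splits. For each holdout,
train and validation are drawn jointly from the remaining clusters by one
balanced without-replacement sample and then partitioned, so they can
never share a frame; the test set comes only from the holdout cluster.
Subject-set disjointness is hard-asserted in tests. Metrics: accuracy,
precision, recall, specificity, F1 from the 2×2 confusion table (zero
denominators yield NaN, never an exception), AUROC of positive-class
probability via the trapezoidal/Mann-Whitney identity. Aggregation is
mean ± sample SD (n − 1) over completed splits; failed splits are recorded
and skipped with a warning.

Because the M-mode injury signal is temporal (static barcode vs varying
seashore) while B-mode pneumothorax is texture-only, M-mode thoracic
classifiers are by construction easier than their B-mode counterparts at
matched budgets. This ordering is a design property of the generator,
stated here rather than asserted as a test: demonstrating it requires
several full LOSO trainings per modality, which would dominate the default
suite's runtime.

## Numerical and interface choices

- Rolling window: 25 one-second sections from a 5 s capture require
  overlap; the stride is the unique even tiling
  (duration − window)/(n_sections − 1) = 1/6 s. Window = duration yields
  one section.
- Augmentation order reflect → rotate → rescale, bilinear interpolation,
  exposed borders zero-filled, extents preserved (rescale crops or pads
  about the centre). Optimization stages use ±36° rotation and 0.90–1.10
  rescale; LOSO uses ±10° and ±10%. The "10% rotation" phrasing is
  unit-ambiguous; it is read as ±10 degrees and exposed as a config
  default, not hard-coded.
- M-mode time axis: 100 columns/s (500 columns per capture), display ticks
  every 0.2 s; depth resolution equals the configured frame size.
- Filter-count rounding is half-up (counts must be integers; floor(x+0.5)
  avoids banker's rounding surprises).
- All randomness flows from integer seed sequences; cohorts, training
  runs, search trajectories, and the whole pipeline are bit-reproducible
  from (config, seed).

## Problem sizes used by the test suite

The default suite exercises the full protocol at desk scale, chosen once:
64×64 frames (the generator's native default is 512), cohorts of 4–27
subjects, ~200 training frames per class for end-to-end runs, a 2×2×1×1
Stage-1 sub-grid, Stage-2 budget 5, LOSO k = 3, and ≤ 5 epochs. At full
severity these sizes are sufficient for the baseline CNN to exceed 0.8
blind accuracy, which the end-to-end test asserts. Full-scale runs (512
px, 54-run grid, budget 100, k = 5, paper-scale budgets) use the same code
paths via `efast all` with the default configuration.

## Known limitations

- Phantom realism is calibrated only to qualitative descriptions of eFAST
  appearances; no quantitative appearance statistics were available to fit.
- The numpy engine is CPU-bound and single-threaded beyond BLAS; it is
  meant for protocol-scale experiments, not production training.
- Reference-architecture results characterize depth/width classes, not the
  published networks.
- The BLD site carries two varying factors (bladder size and hemorrhage
  severity) by design, making it the hardest B-mode site — mirroring its
  role as the weakest scan point in the motivating application.
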