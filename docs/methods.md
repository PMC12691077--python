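# Methods

`thermoroi` implements an illumination-adaptive pipeline for locating two
body-surface regions of interest (ROIs) on dairy cows — the lower udder
(LU) and the perianal area (AA) — in RGB frames and reading radiometric
surface temperatures out of the co-registered thermal frame. The two
sites are the standard "thermal windows" whose surface temperature tracks
rectal temperature (RT) most closely, which is why the package also ships
the Spearman-based site-selection analysis that justifies them.

## Illumination gate

Frames are routed by mean luminance of the ITU-R 601 grayscale
conversion, `I_gray = 0.299 R + 0.587 G + 0.114 B` (kept real-valued; no
intermediate rounding):

* `mu < T_low` (default 60) — low light, Retinex enhancement;
* `mu >= T_high` (default 150) — overexposed, CLAHE;
* otherwise — passed through unchanged.

Both thresholds are 8-bit luminance values, configurable under the
`enhancement:` config section. The boundary semantics are exact: 60 is
already normal light, 150 is already overexposed.

## Retinex low-light path

The normalised image `I` in [0,1]^3 is decomposed as `I = R * L` with
reflectance `R` (per channel) and a single illumination map `L`. The
decomposition minimises

    eps(P, Q, R, L) = ||I - P R||_F^2 + alpha phi(R) + beta psi(L)
                      + gamma ||P - Q||_F^2 + lambda ||Q - L||_F^2

where `P`, `Q` are auxiliary illumination variables that split the data
term from the smoothness term on `L`, and `phi`, `psi` are quadratic
finite-difference (total-variation-style) smoothness penalties. This is a
classical alternating scheme rather than a trained unfolding network: the
published version of this decomposition learns its proximal operators
and its illumination-adjustment network from data; here the stated
energy itself is optimised so that the physical model and its testable
properties (energy descent, reconstruction, brightening) hold without any
pretrained weights.

Per stage, `P` and `Q` have closed-form minimisers; `R` and `L` take
projected gradient steps with backtracking (step accepted only if the
energy does not increase), so the energy sequence is monotonically
non-increasing by construction — the property the tests assert at 1e-8
relative tolerance. Initialisation is the closed form `L0 = max_c I_c`
(floored at 1e-4), `R0 = I / L0`, which reconstructs the input exactly
wherever `L0` is above the floor.

Defaults: `mu_init = 0.05`, `alpha = 0.001`, `beta = 0.01`,
`gamma = lambda = 0.1`, `T = 3` stages — small regularisation and a
shallow unfolding depth; all configurable. Illumination is brightened as
`L^omega` with `omega = 0.5`; since `omega <= 1` this is monotone, fixes
`L = 1`, and strictly raises the mean luminance of genuinely dim frames.
The gamma law is a deliberate closed-form stand-in for a learned
adjustment operator (no architecture is published for it). The enhanced
image is `clip(R * L^omega * 255)`, rounded to 8 bit only at the end.

## CLAHE overexposure path

Contrast-limited adaptive histogram equalisation of the luminance channel
in Lab space (D65; L rescaled to 0–255 as in the common 8-bit
convention). The image is tiled into `grid_rows x grid_cols` cells
(default 8x8; the last row/column absorbs any remainder). Each tile's
256-bin histogram is clipped at `clip_count =
ceil(clip_limit * tile_pixels / bins)` with `clip_limit = 3.0`, and the
clipped excess is redistributed uniformly across bins with headroom
(integer shares; the remainder goes one count each to the lowest-index
bins). Redistribution conserves total mass exactly; if the cap is
infeasible (`mass > clip_count * bins`, impossible for `clip_limit >= 1`
in normal operation) conservation wins and the residue spreads uniformly.
Tile mappings are the normalised CDFs scaled to 0–255; each output pixel
bilinearly blends the mappings of its four neighbouring tile centres
(weights non-negative, summing to 1; border pixels fall back to one or
two tiles). The a/b chroma channels pass through bit-exactly. With a 1x1
grid and an unbounded clip limit the procedure reduces to global
histogram equalisation, which is the oracle equivalence the tests check.

## Text-conditioned detection core

Categories are text, not one-hot labels. The default bank holds five
anatomical entries — LU, AA, RU (rear udder), hind legs, hind quarters —
whose descriptions chain the two ROIs into one spatial structure
(LU -> hind legs -> hind quarters enclosing RU and AA). Only LU and AA
are measurement ROIs; the other three are auxiliary linking categories.
The bank is data (JSON); restricting it to `{LU, AA}` yields the
two-text configuration. No pretrained language encoder is bundled: text
features come from a seeded hashing bag-of-words embedder (deterministic,
L2-normalised mean pooling over token vectors, default dimension 64), and
any encoder with the same signature can be injected.

The EDC block modulates visual features with text:

1. attention refinement `X' = X * A_S * A_C`, with `A_S` the sigmoid of
   the channel-mean map (spatial weights) and `A_C` the sigmoid of the
   spatial mean (channel weights) — the simplest reading of a two-factor
   mean-pool/sigmoid attention;
2. text-conditioned modulation `X^ = X' * gs * cs + gb + cb`, the four
   parameter groups (global/channel-wise scale and shift) produced by a
   one-hidden-layer GELU MLP over the pooled text vector, with the
   convention that the shifts are added, not multiplied;
3. residual recombination `Y = X + GELU(LayerNorm(X^))` (channel-axis
   LayerNorm, no affine).

With the MLP fully zero-initialised the block is exactly the identity —
the anchor property used in tests. For *training* the output bias is
instead initialised at the identity modulation (gs = cs = 1, gb = cb =
0), because at the all-zeros point the product `gs * cs` has zero
gradient in both factors and the block would never move.

Cross-scale fusion uses fast-normalised learnable weights,
`O = sum_i w_i I_i / (eps + sum_j w_j)` with `w_i = max(raw_i, 0)` and
`eps = 1e-4` — a convex combination up to `eps`.

### Miniature detector

The full open-vocabulary YOLO architecture is out of scope; the package
ships a deliberately small CPU-trainable head that exercises EDC, the
weighted fusion node, the assigner and the hybrid loss end to end:

* input resized to 192x144; a fixed statistics backbone computes 24
  channels per cell at two scales (8 px and 16 px cells): cell mean
  RGB, colour-opponent differences, grayscale std, mean gradient
  magnitudes, directional neighbour-cell mean RGB (above/below/left/
  right), normalised cell-centre coordinates and a bias channel. The
  directional context is what lets a shallow head separate regions whose
  local appearance coincides;
* EDC conditioning is applied per scale (conditioning vector = mean of
  the bank's pooled text embeddings), then the coarse scale is upsampled
  and fused with the fine scale by the learnable fusion node;
* per anchor (one per fine cell) a linear head regresses the box —
  centre offset `tanh`-bounded to two cells, width/height as
  `base_size * exp(t)` — and a linear embedding head produces a visual
  vector whose scaled dot products with the category text embeddings give
  per-class sigmoid scores. Swapping the text bank therefore changes
  scores but never box geometry;
* inference keeps detections with confidence >= 0.25 and applies
  class-wise greedy NMS at IoU 0.5 (YOLO-family conventions).

Training is plain NumPy with hand-derived gradients: analytic backprop
for the heads, the EDC MLP (through LayerNorm and GELU) and the fusion
weights, and central finite differences only for the IoU-family box loss
with respect to the four decoded box parameters (step 0.01 px). A unit
test checks every analytic gradient against finite differences of the
whole loss with frozen assignment targets. The optimiser is Adam
(lr 0.02, cosine-decayed, batch 8).

## Training strategy

* **Task-alignment score** `A_ij = p_cls^alpha * IoU_ij^beta` (defaults
  `alpha = 1`, `beta = 6`, the task-aligned-assignment convention; the
  exponents are not pinned by the published description).
* **Gaussian soft centre prior** `w_ij = exp(-d_ij^2 / sigma^2)` with
  `d_ij` the anchor-to-centre distance normalised by half the
  ground-truth diagonal and `sigma = 0.5`. The exponent is `d^2/sigma^2`
  exactly as stated (not `d^2/(2 sigma^2)`).
* **Assigner**: combined metric `m_ij = A_ij * w_ij` (the combination
  rule is this package's choice; the two mechanisms are published
  separately). Per ground truth the top-k anchors by `m` (default k = 5
  in the detector, 10 in the standalone default) become positives; an
  anchor claimed by several targets goes to the larger metric (ties:
  larger IoU, then lower index). Classification targets are the soft
  task-aligned labels `m_ij / max_i m_ij`, so confidence tracks
  localisation quality. When no predicted boxes exist yet the centre
  prior stands in for the IoU term.
* **Hybrid regression loss** `1 - (lambda * CIoU + (1 - lambda) * GIoU)`
  with `lambda = 0.5`. The published expression defines the *fused
  similarity*; since a similarity is maximised, the minimised loss is its
  complement. At `lambda` 1 or 0 the loss reduces to its pure CIoU/GIoU
  forms; it is zero iff the boxes coincide. CIoU uses the standard
  published form (centre distance over enclosing diagonal plus
  aspect-ratio term with its self-normalising weight).

## Evaluation

Greedy confidence-ordered matching at IoU >= 0.5 per class; P and R in
percent (P defined as 0 with no detections); AP by all-point
interpolation (monotone precision envelope integrated over recall);
mAP50 the mean over evaluated classes — by default only the two ROI
classes, matching the two-class inference accounting. Unmatched ground
truth counts as FN whether missed or confused.

## Temperature extraction

Pixels belong to a detection box if their centres fall in the half-open
rectangle `[x1, x2) x [y1, y2)`; TMax/TMin/Tavg are taken over those
pixels with no finer mask (segmentation within boxes is future work).
TMax is the temperature characteristic used for comparisons, because the
animal is the warmest surface in the scene. Error statistics against
reference values are absolute (max/min/mean); the signed mean is kept as
a secondary field because detection errors tend to produce slight
underestimates, never overestimates.

## Synthetic scenes

The generator emulates what matters for the pipeline, not photorealism:

* a body ellipse textured with thresholded Gaussian-smoothed noise
  (irregular black/white patches, the stated confound of Holstein coats);
* five-category layouts in rear view (hind quarters framing two flanking
  legs, RU between them, AA above RU, LU at the lowest point) and side
  view (LU adjacent to a hind leg; RU not visible), mixed 50/50 by
  default; ROI areas carry distinct skin colours (pale pink udder,
  darker perianal skin), which is what makes the scenes separable for a
  miniature head;
* a radiometric frame tied to a per-scene core temperature
  `RT ~ N(38.7, 0.3)` degC with `AA = RT - N(1.3, 0.15)` and
  `LU = RT - N(2.3, 0.25)`, clipped to the observed ranges
  (LU 35.2–37.5, AA 36.9–38.5), plus per-pixel noise (sd 0.1 degC,
  instrument-range clipped to [-20, 250]); the physiological gradient
  RT > AA > LU holds by construction and survives default noise in well
  over 95% of scenes;
* global luminance gain bisected so the mean grey lands in the requested
  illumination band; scenes are bit-reproducible from their seed, and
  dataset manifests record every per-scene seed (6:2:2
  train/val/test split by default).

What passing tests on these scenes does *not* show: robustness to real
coat patterns, occlusion, pose deformation beyond box jitter, camera
noise, or real radiometric calibration error. The generator's role is to
make every stage testable end to end without any downloaded data.

## Problem sizes and defaults used in checks

The smoke-training check uses 200 training scenes and 50 held-out scenes
generated at 320x240 in the normal-light band, 100 epochs — the scale at
which the miniature head reliably clears mAP50 0.8 on held-out scenes
while remaining a few minutes of single-core work. Scene generation
defaults to 640x480 (the camera's RGB resolution) for external use. The
acceptance script additionally derives all its RNG streams from a single
`--seed`.

## Known limitations

* The Retinex solver optimises the stated energy but is not the trained
  unfolding network; enhancement quality on real low-light photographs
  will differ from the published system.
* The hashing text encoder carries no semantics — two descriptions are
  similar only through shared tokens. The spatial prior therefore acts
  through shared anatomical vocabulary, not through language
  understanding.
* The miniature detector is a testbed for the training machinery, not a
  production detector; its fixed statistics backbone saturates well below
  what a convolutional backbone achieves.
* `P = 0` when there are no detections is a pipeline-stability
  convention, not an information-theoretic choice.
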