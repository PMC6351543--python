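# Methods

## Pipeline model

The package implements two-stage cascade inference over pyramidal
whole-slide images. All geometry is anchored to level 0 (40x): pyramid
level *k* is exactly 2^k-fold downsampled, coordinates are 0-based
(x = column, y = row), and windows are half-open squares `[x, x+size) x
[y, y+size)` in level-0 pixels. These conventions are deliberate: they
make every coordinate mapping a floor division (`map_coords`), keep
stitching arithmetic exact, and let all rasters at scales 1/8, 1/32 and
1/128 index consistently. Reads past the slide boundary return white
(255, 255, 255), modelling bare glass; border patches are therefore
always well defined.

**Tissue preselection.** The 1.25x image (level 5, or the deepest level
pooled down to 1/32) is converted to integer HSV with
`S = round(255 * (max - min) / max)` (0 where max = 0). The integer
channels keep the 256-bin histogram exact, so the Otsu threshold — the
exhaustive maximizer of the between-class variance
`w0 * w1 * (mu0 - mu1)^2`, ties broken toward the smallest index for
determinism — is reproducible bit-for-bit. Foreground is the
high-saturation side (`S > t`): tissue is stained, background near-gray.
H- and V-channel thresholding share the same Otsu core but the pipeline
uses S only, which separates stained tissue best. An all-background
slide produces a degenerate single-bin histogram and is rejected rather
than silently masked.

**Rough pass.** 299 x 299 windows at stride 128 tile the slide extent; a
flush window is appended at each edge when the extent minus the window
size is not a stride multiple, so no tissue pixel escapes coverage.
Windows whose 1/32-scale footprint contains no tissue are dropped. Each
window's classifier probability is written to the single rough-heatmap
cell addressed by its top-left corner (`x/128, y/128`); windows mapping
to the same cell are averaged. The alternative of painting the full
299-px footprint (299 > 128) is implemented nowhere by default because
the one-cell rule reproduces the intended 1/128-side map and keeps the
rough heatmap an injective function of the window grid.

**Candidate selection and dense pass.** Rough cells with probability
strictly above 0.5 become candidates. Ties at exactly 0.5 are excluded;
the strict rule also governs heatmap binarization everywhere else, and
it is the conservative choice: an overlap average of one "tumor" and one
"normal" oracle vote lands exactly on 0.5 and is treated as normal.
Dense tiles (default 2560 px, stride 1280, i.e. half overlap) sit on an
aligned stride grid — origins are stride multiples, hence divisible
by 8 as the stitcher requires — and a tile is kept iff its footprint
contains a candidate cell. Literal per-candidate-pixel centering would
produce one 2560^2 tile per candidate pixel; the aligned grid preserves
the half-overlap and coverage guarantees at a bounded tile count.
Tile predictions (ensemble-averaged across models where several are
given) are stitched by sum/count accumulation; finalization divides
once, leaves never-covered cells at 0, and keeps the count raster as
provenance. Windows are accumulated in sorted row-major order so
floating-point results are bit-reproducible regardless of planning
order.

**Losses.** The classifier trains against the mean binary cross-entropy
of patch labels (a patch is tumor iff it contains at least one
ground-truth tumor pixel — a conservative, testable reading; the rule is
configurable at the labeling call). The segmenter trains against
cross-entropy on the (L/8)^2 output lattice with the mask sampled at
stride-8 lattice points (nearest value, no averaging). Probabilities
are clipped to [1e-7, 1 - 1e-7] before the logarithms. The lattice
index runs 0 .. L/8 - 1, consistent with the (L/8)^2 normalization.

**Evaluation.** Slide AUC uses the per-slide maximum heatmap
probability (midrank tie handling). FROC treats each 8-connected
component of the ground-truth mask at heatmap scale as one lesion,
scored by the maximum probability of detections falling inside it;
detections inside no lesion are false positives; the score is the mean
sensitivity at 0.25, 0.5, 1, 2, 4 and 8 average false positives per
slide, linearly interpolating the sensitivity–FP curve and clamping
outside the achieved range. Heatmap detections are one per connected
component above threshold (at the component argmax), which bounds false
positives the way common Camelyon entries do. For IoU, a class absent
from both prediction and truth scores 1.0, so a normal slide predicted
all-normal has mIoU 1 — matching the convention of averaging mIoU over
tumor *and* normal slides. Bootstrap CIs resample slides with
replacement (B = 2000 by default) and report the 2.5/97.5 percentiles;
replicates where a metric is undefined (single-class resample) are
skipped.

**Polygon export.** Binarized dense-heatmap components are traced by
Moore boundary following through pixel centers — the classic contour
retrieval behavior, implemented here directly — yielding one external
polygon per component (holes are not exported); vertices scale by 8
into level-0 pixels and are written as ASAP annotation XML. Components
under 4 heatmap pixels are dropped by default to suppress single-pixel
noise (configurable).

## Oracle models

Trained networks are out of scope; the contracts are exercised by
ground-truth-backed oracles. The oracle classifier returns 1 iff the
window contains a tumor pixel, plus optional clipped Gaussian noise.
The oracle segmenter returns the ground truth sampled at the window's
stride-8 lattice, each value independently flipped with a set
probability, mapped to probabilities {0.1, 0.9}. Both derive their
random stream from (seed, window.x, window.y), so predictions are pure
functions of the window: reproducible, order-independent, and identical
across repeated tiling of the same region.

## Synthetic slides

The generator emulates exactly the structure the pipeline relies on:
white glass background; tissue as a union of smoothed random ellipses
grown until the target area fraction is hit (verified within +/-0.03,
else the spec is rejected); tumors as smooth elliptical blobs placed
strictly inside tissue (intersection enforces the subset invariant);
eosin-pink tissue and hematoxylin-purple tumor stains with per-pixel
Gaussian color noise, both clearly saturated against the near-gray
background so S-channel Otsu separates them; pyramids by exact 2x mean
pooling down to a 64-px side.

Defaults model a desk-scale stand-in for a 40x scan: 4096^2 level 0
(roughly 1/25 of a full scan side), tissue fraction 0.40, two tumor
blobs with radii 300–700 px — the analogue of macro-metastases several
millimetres across, several rough-heatmap cells wide. Cohorts draw
per-slide seeds from a spawned seed sequence, so slides are mutually
independent and the cohort reproduces bit-for-bit from one seed.

What the generator does *not* emulate: nuclear/glandular texture, stain
gradients and artefacts (folds, pen marks, blur), irregular infiltrative
lesion margins, and isolated-tumor-cell scatter. Tests passing on these
slides therefore demonstrate the correctness of the *pipeline machinery*
(geometry, stitching, selection, metrics) under controlled noise — not
the discriminative power of any real model on real tissue.

## Numerical choices

- Probability clipping 1e-7 in both losses; loss reductions in float64.
- Stitching accumulates float64 sums with integer counts; finalized
  heatmaps are float32 in [0, 1].
- Otsu ties break to the smallest threshold; argmax over a vectorized
  variance curve reproduces an explicit 256-threshold loop exactly.
- Mean pooling pads odd sides by edge replication, so level dimensions
  follow ceil division; stored pyramids tolerate +/-1 px against the
  2^k rule (scanner rounding), anything larger is malformed.
- Empty inputs fail loudly (degenerate histogram, empty batch, 0-sized
  rasters); an empty tissue mask yields an empty tile plan with a
  warning, and an empty candidate mask a zero dense heatmap.

## Known limitations

- At the default 4096^2 desk scale the dense tile grid is only ~1.6
  tiles wide, so a large fraction of the slide has single or double
  (rather than quadruple) stitching coverage. With per-tile noisy
  predictions, points covered twice lose the benefit of averaging
  whenever one of two votes flips (the mean lands on the excluded 0.5
  boundary). Noisy-oracle IoU at this scale is therefore dominated by
  edge-coverage strips in a way it would not be on full-size slides,
  where interior quadruple coverage dominates; the tests record this
  behavior quantitatively.
- The rough heatmap writes each window's probability to its top-left
  cell only, so the last one or two cell columns/rows of a slide are
  never rough-heatmap addresses; their tissue is still segmented because
  dense tiles extend 2560 px past any lit cell.
- Real scanner formats (JPEG2000, vendor TIFF dialects) are not read;
  the multipage-TIFF dialect (page k = level k, exact 2x, RGB 8-bit) is
  the only on-disk pyramid format.
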