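# Methods

## The problem and the pipeline

Cultures of baculovirus-infected insect cells can grow protein crystals
inside the cells ("*in cellulo*" crystallization). Screening cultures for
crystal growth from bright-field micrographs is an instance-segmentation
task: per-object pixel masks for crystals (and, separately, cell bodies).
`cellcryst` implements the complete desk-scale loop for such a pipeline —
data synthesis with exact ground truth, annotation I/O, a trainable
segmentation stage with transfer/incremental protocols, an evaluation-metric
suite, and a harness that runs the full 19-strategy training matrix.

## Evaluation metrics

Pixel metrics compare the **union** of predicted foreground *A* against the
union of ground-truth foreground *B* per image (overlapping instances, e.g.
crystal clusters, are unioned before counting):

- P = tp/(tp+fp), R = tp/(tp+fn), F = 2PR/(P+R), J = tp/(tp+fp+fn).
- The algebraic identity J = F/(2−F) holds whenever tp+fp+fn > 0 and is
  enforced by tests.
- 0/0 conventions (which the formulas leave open): if both sides are empty
  P = R = F = J = 1 (a correct negative); if exactly one side is empty all
  four are 0 (a miss or a hallucination). These conventions reward correct
  rejection of crystal-free images and punish spurious detections.

Object-count metrics use per-image ground-truth count Nᵢ and predicted count
Mᵢ:

- ΔO = (1/n) Σᵢ |Nᵢ − Mᵢ|. A miss and a spurious detection on the same
  image cancel; the indicator is blind to compensating errors by design.
- ΔO*N* = (1/n) Σᵢ min(1, |Nᵢ − Mᵢ|/Nᵢ). Normalizing by Nᵢ **per image**
  and capping each term at 1 is the only reading under which the average is
  bounded in [0, 1] and images of different object density weigh equally;
  both choices are declared here rather than inherited. An image with
  Nᵢ = 0 contributes 0 if Mᵢ = 0 and 1 otherwise.

Averaging is macro (per image, then arithmetic mean), matching the
per-image reporting convention of screening studies; micro-averaged pixel
metrics (pooled counts) are exposed on the report but are not the default.

The mixed-crystal analysis reports mean prediction box scores instead of
per-type pixel metrics, because on scenes where both crystal types co-occur
in one cell the per-type annotation is ambiguous. A prediction is assigned
to the first cell whose mask contains its mask centroid; cells with exactly
one accepted prediction define the *isolated* context, cells with more than
one the *coexisting* context; predictions outside every cell join neither.

## Synthetic scene generator

The generator emulates the acquisition geometry of an automated bright-field
screening microscope: a 300 × 300 µm field of view rasterized at
2136 × 2136 px (pixel pitch ≈ 0.1404 µm) and downscaled to 512 × 512 8-bit
PNG. All intensity and texture parameters are synthetic inventions exposed
on `GeneratorConfig`; the contract is that a detector can learn the scenes
and the metric suite can score them — not photorealism.

Per scene: 10–40 elliptical cells (axes 15–25 µm, a typical High Five cell
scale) are placed with rejection of >60% mutual overlap. Each cell then
independently bears, per enabled crystal class:

- **Target G** (probability `efficiency_G`, default 0.95): one rod-like
  crystal, length 40–140 µm (hard morphology cap at 140 µm), width
  5–12 µm, free to protrude beyond the cell rim.
- **Target H** (probability `efficiency_H`, default 0.85): 1–6 crystals
  with an elongated-hexagon outline (long axis 3–15 µm, aspect 1–2),
  random orientations, sharing a cluster anchor and a cluster id whenever
  two or more co-occur. The per-cell count and cluster-size distributions
  are declared defaults, not measured values.

Rendering: bright Gaussian background (mean 200, σ 6), translucent cell
interiors (×0.90) with darker rims (×0.75), crystals filled at a
class-specific gray level (G: 70, H: 125) with a darker edge band, global
Gaussian blur (σ 0.5 µm). The two classes deliberately occupy different
intensity bands so that class-selective segmentation is learnable and the
cross-target degradation studied by the experiment harness is observable.
What the generator does **not** model: focus gradients, debris and optical
artifacts, cell texture, Z-structure (no confocal stacks), crystal
birefringence, or annotation noise. Passing desk-scale tests therefore
demonstrates that the pipeline's machinery is correct and its trends are
reproducible — not that any particular accuracy carries over to real
micrographs.

Masks are rasterized from polygons with a scanline implementation of the
pixel-center even-odd rule (a pixel is foreground iff its center at
(c+0.5, r+0.5) lies inside the polygon), verified pixel-exactly against a
brute-force point-in-polygon oracle. Images are resized with an
anti-aliased area-like filter, masks with nearest-neighbor (any
interpolation would require a re-threshold decision), polygons by pure
scaling. Determinism: every dataset derives per-image child seeds from a
root seed via hashed seed sequences, so image *i* is independent of how
many images are requested.

## Segmentation stage

The region-proposal detector used at production scale (Mask R-CNN,
ResNet-50, COCO-pretrained) is wrapped as an optional backend, not
re-implemented. The repository's testable core is the **reference
backend**, chosen to train on one CPU in seconds while honoring every
protocol contract:

- Fixed encoder: 9 per-pixel features — centered intensity, its square,
  Gaussian-smoothed intensities (σ = 1, 2, 4 px), squared smoothed
  intensity, gradient magnitudes (σ = 1, 2), local standard deviation.
  The quadratic terms let the linear decoder carve an intensity *band*,
  which is what makes the model class-selective rather than a monotone
  darkness detector.
- Learned decoder: logistic regression over the features, trained with
  momentum SGD (µ = 0.9, no schedule, no weight decay) on class-balanced
  binary cross entropy (foreground and background weigh equally; plain BCE
  otherwise, e.g. on crystal-free crops). One optimization step per image
  (batch size 1), `epochs × n_images` steps per stage.
- The protocol learning rate is multiplied by the backend's feature-scale
  constant (`lr_scale = 100`), mapping the nominal 1e-3 / 1e-4 protocol
  values onto the classic logistic-regression step-size regime while
  preserving their 10× ratio. The optimizer and this scaling are declared
  package choices; the protocols pin only epochs, batch size, loss and the
  nominal learning rates.
- Instancing: probability map ≥ 0.5 → 8-connected components → components
  < 5 px discarded → per-component objectness score = mean component
  probability; predictions below the score threshold (default 0.7) are
  dropped and the rest sorted by descending score. All values configurable.
- Augmentation: horizontal/vertical flips with probability 0.5 each; random
  crops keep ≥ 50% of the area and are re-drawn (≤ 10 tries, then skipped)
  if they would remove every instance.

Checkpoints are JSON (weights, class set, lineage, schema version); a
save→load round trip reproduces predictions bit-identically. The lineage —
one (dataset fingerprint, protocol) entry per completed stage — records the
warm-start history: a primary>secondary model carries two entries.

## Experiment harness

`build_plan` constructs the 19-strategy matrix: rows 1–3 primary-only on
target G at three training-set sizes, rows 4–9 the largest G model tuned on
H (three secondary sizes × learning rates 1e-3/1e-4), rows 10–18 the mirror
starting from H, row 19 a combined single-stage training on the pooled
largest sets. Smaller training subsets are nested within larger ones (a
declared choice), test sets are disjoint from training pools by seeded
substream construction, and primary models are trained once and reused by
the secondary rows.

Problem sizes: the `paper` scale keeps 10/30/50 training and 150 test
images per target at the full acquisition geometry. The `desk` scale — the
package's default working size, and the size used by the test suite and
`scripts/acceptance.py` — substitutes 4/8/12 training and 20 test images on
a 100 µm field of view rasterized 256→128 px, so H crystals remain several
pixels wide; G rod lengths are clipped to 20–60 µm to fit the smaller
field. A full 19-row desk matrix runs in well under a minute on one CPU.

Absolute indicator values from GPU-trained detectors on real micrographs
are out of reach at this scale, so the harness asserts **ordinal trends**:
on-target training beats off-target evaluation; secondary training lifts
the secondary target's F above the primary-only baseline; the combined row
converges toward the best incremental rows. Predicted-vs-ground-truth
object counts are logged per image (in the reports) so over-segmentation of
large objects by small-object-trained models can be inspected, but no test
asserts that mechanism.

## Numerical and degenerate-input choices

- Coordinates are 0-based (x, y) = (column, row), origin top-left, pixel
  centers at integer + 0.5 — the convention of the Labelme dialect.
- Degenerate (collinear) polygons rasterize to an empty mask with a
  warning; self-intersecting polygons warn and follow the even-odd rule.
- Resizing never changes instance counts; a sub-pixel instance that
  vanishes triggers a warning. Dataset generation drops such instances
  from the written ground truth (an invisible crystal is not annotatable).
- Non-finite training loss aborts with a diagnostic rather than continuing.
- Scores are bounded in [0, 1] by construction; prediction boxes are
  always the tight bounding boxes of their masks.

## Known limitations

- The reference backend has no notion of object shape beyond connected
  components: touching crystals merge into one prediction, which inflates
  ΔO/ΔO*N* even when pixel metrics are high. This mirrors a failure mode
  of real detectors but exaggerates its frequency for clustered targets.
- The torchvision Mask R-CNN wrapper is provided for realism but is not
  exercised by the test suite (it requires the optional torch extras and
  GPU-scale budgets to be meaningful).
- RLE-only annotation files and multi-page TIFF are unsupported; the
  Labelme reader accepts both version-bearing and version-less files.
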