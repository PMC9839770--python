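# Methods

## Problem setting

Binary semantic segmentation of caries-like lesions in grayscale
radiographs. The labelled set `D_L = {(x_i^l, y_i^l)}` is small; a larger
pool `D_U = {x_j^u}` is unlabelled. The defining difficulty is pixel-class
imbalance: lesions of side ~10 px in 300×300 frames put the foreground
prior near 10⁻³, so full-frame training signals are dominated by
background.

## Self-training procedure

A teacher model is fitted supervised on `D_L` by minimising the mean
binary cross-entropy

    L(y, ŷ) = −mean[ y·log ŷ + (1−y)·log(1−ŷ) ],

with predictions clipped to [1e−7, 1−1e−7] for loss evaluation. Teacher
probabilities on the pool are binarised at 0.5 (exposed as
`pseudo_threshold`) to form pseudo pairs. The student is then trained on
the pseudo pairs, plus the real labelled pairs by default
(`include_real=True`); disabling this isolates the pseudo-label signal
for ablations. Pseudo labels are produced only by the teacher; the pool's
hidden ground truth is used solely to report pseudo-label fidelity (mean
foreground IoU of pseudo vs hidden masks), never for training. Held-out
test images with real labels never enter any training stage, which the
pipeline asserts from its split manifests.

Two training regimes are implemented. **Standard** self-training uses
full frames everywhere. **CCS** self-training trains the teacher on the
union of the labelled full frames and their centroid crops (so it sees
both global context and balanced patches), and trains the student on
5-way-augmented centroid crops of the pseudo pairs (plus real crops).
By default the student also keeps the full frames behind those crops
(`student_full_frames=True`): for a per-pixel classifier, crops-only
training omits most of the background distribution, and the student then
misfires on unseen background at full-frame inference (measured ~0.05
foreground-IoU cost on the bundled study). Setting the flag to False
restores a strictly crops-only student for ablation.

## Centroid cropping-based sampling

Foreground components are maximal 8-connected regions (8-connectivity is
the natural choice for blob-like masks and makes the flood-fill oracle in
the tests unambiguous). For each component a square window of side
`crop_size` is centred on the rounded centroid (round-half-up) and
shifted — never shrunk or padded — to lie inside the frame. If a
component's bounding box exceeds the crop size, the side grows to the box
plus a 2 px margin so no lesion pixel is ever lost; this guarantee is
preferred over a strict fixed window area because a crop that truncates
its lesion would corrupt the training target. Components below
`min_area` (default 1, i.e. no filtering) can be dropped. Images whose
pseudo mask is empty contribute no crops and are skipped with a log
entry.

Default `crop_size` is 32: windows of ~10 px would barely contain one
lesion with no surrounding context, while 32 px keeps the tooth-boundary
context that distinguishes lesions from plain dark background yet still
raises the in-crop foreground fraction by well over an order of magnitude
(the measured gain on default synthetic data is ≈40×).

## Augmentation

Each crop pair expands into exactly five pairs in fixed order: identity,
horizontal flip, vertical flip, rotation (+15°), x-shear (factor 0.2).
Angles and shear are deterministic constants rather than random draws so
the expansion factor — and every augmented pixel — is exactly
reproducible; a fixed published training-set size implies a deterministic
scheme, and reproducibility is worth more here than augmentation
diversity. Transforms act about the patch centre with the output shape
preserved; images are interpolated bilinearly, masks by nearest neighbour
and re-binarised at 0.5; out-of-support pixels are filled with 0. Flips
are exact index permutations (involutions, area-preserving); rotation and
shear lose a bounded sliver of border mass.

## Metrics

All metrics derive from pixel confusion counts with lesion = positive:

* `mPA = (1/k) Σ n_jj / t_j` with `t_j` the ground-truth pixel count of
  class `j` (per-class recall). The denominator is deliberately the truth
  count, not the prediction count: with a prediction denominator the
  "fraction correctly classified" reading breaks down (a class predicted
  once, correctly, would score 1.0 regardless of misses). Classes absent
  from the truth are excluded from the mean and flagged.
* `IoU = TP/(TP+FP+FN)` per class. The reported mIoU is the mean of the
  foreground and background IoU, so values are comparable with two-class
  segmentation tables; the foreground IoU is reported alongside because
  the background IoU is always ≈1 in this imbalanced regime.
* `Dice = 2TP/(2TP+FP+FN) = 2·IoU/(1+IoU)` for the foreground.

When prediction and truth are both empty the union is empty and every
metric is defined as 1.0 — a correct empty prediction should not be
penalised by a 0/0 convention. Aggregation is either `micro` (pool counts
over all pixels, then apply the formulas — the default) or `per_image`
(average per-image values); both are recorded in every report because the
two can differ when image difficulty varies.

## Built-in backbone

`FilterBankSegmenter` is a compact per-pixel classifier: a fixed bank of
eight features per pixel — raw intensity, Gaussian means at σ = 1, 2, 4 px,
two centre-surround (difference-of-Gaussian) channels, local standard
deviation at σ = 2, and the gradient magnitude at σ = 1 — feeds a single
32-unit tanh hidden layer with a sigmoid output. The feature scales
bracket the lesion scale: a lesion is a blob-sized negative
centre-surround response sitting on locally bright, low-gradient tooth
structure, which this feature set separates well. Features are
standardised with mean/std fitted on the training pixels and stored in
the checkpoint. The model satisfies the pipeline's backbone contract
(same-shape probability output in [0, 1], deterministic inference,
single-file serialisation), and any dense segmentation network can be
plugged in through the same contract.

Training is minibatch gradient descent on the BCE objective: batches of
8 images (mixed frame/crop shapes are fine — supervision is per pixel),
processed in pixel chunks of 2048 with one Adam step per chunk at a fixed
learning rate 10⁻³. Adam is used because with so few images per epoch,
plain SGD at a fixed small step makes negligible progress within the
epoch budget. A seeded 10 % image holdout provides the early-stopping
signal: training stops after 5 consecutive epochs without a validation
loss improvement of at least 10⁻⁴ (or at 100 epochs), and the
best-validation checkpoint is restored. When the training set is too
small to spare a holdout image the training loss is monitored instead.
Non-finite losses abort with the epoch index. With a fixed seed the whole
fit is bit-reproducible.

## Synthetic data generator

Each frame is: background intensity 0.15; a row of bright (~0.7)
elliptical teeth with per-tooth jitter, blurred (σ = 1.2) so tooth edges
are gradients; 1–3 lesions per image, each an irregular connected blob —
the sub-level set of an anisotropic quadratic form eroded by smooth
noise, restricted to the component containing its centre — with extent
drawn from Normal(10, 2) px (clipped to [2, min(H, W)/4]), centred on a
tooth-boundary pixel, and darkened by a contrast of 0.3; finally i.i.d.
Gaussian noise (sd 0.03) and clipping to [0, 1]. The mask is exactly the
set of darkened pixels, so image/mask alignment is perfect by
construction. Lesions are rejection-sampled (≤100 attempts) to be
mutually non-adjacent, keeping one 8-connected component per lesion.
Every draw is keyed by `SeedSequence([seed, draw_index])`, so items are
reproducible independently of generation order.

The generator reproduces the statistics that matter to the method — frame
size, lesion scale, foreground fraction ~0.1 %, lesions on bright
structures, noise — but not radiographic physics: no beam hardening,
scatter, overlapping anatomy, annotation noise, or caries-grade
variation. Passing results therefore demonstrate that the pipeline's
machinery (sampling, augmentation, self-training dynamics, metrics) works
under realistic imbalance, not that the built-in backbone would reach the
same numbers on clinical radiographs.

## Reduced-scale study

The bundled study (`cariesseg.experiments`) runs at desk scale: 120
synthetic 96×96 frames with ~8 px lesions, split into 20 teacher images,
a 60-image pseudo pool and a ~12-image test set (test size =
round(0.10·N)), three replicate seeds — each replicate re-drawing the
dataset, the split and the optimisation randomness, so the comparison is
over the method rather than one dataset realisation — comparing CCS
self-training,
standard self-training and a supervised baseline trained on the teacher
subset only. These sizes keep a full three-arm, three-seed study within a
few minutes on one CPU while preserving the imbalance regime; at this
scale the CCS student typically reaches foreground IoU ≈ 0.8 on held-out
frames and the full-frame arms trail it, reproducing the direction of
effect that motivates CCS.

## Known limitations and open choices

* The per-pixel backbone has no learned spatial hierarchy; it suffices
  for the synthetic contrast structure but is not a substitute for a deep
  encoder–decoder on clinical images. The contract makes swapping
  backbones trivial.
* Whether rotation/shear should be random per epoch, the pseudo-label
  threshold, and the evaluation protocol for crop-trained students
  (full-frame inference vs crop-centred evaluation) are genuinely open
  choices; the defaults are fixed deterministic parameters, 0.5, and
  full-frame inference respectively, with flags for the alternatives.
* Polygon rasterisation uses pixel-centre containment with the even-odd
  fill rule (boundary inclusive). Union semantics are assumed for
  overlapping polygons.
* `mPA` can be high even for a useless segmenter when the background
  dominates; foreground IoU is the headline number to read.
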