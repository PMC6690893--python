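# Methods

## Problem and model

Lung-nodule segmentation on screening CT is both tedious and subjective:
expert readers of the same nodule routinely disagree, so a purely automatic
segmenter has a practical ceiling at the inter-observer agreement. This
package implements a two-block volumetric segmentation network that first
proposes an automatic 3D segmentation of a nodule-centered cube and then,
optionally, corrects it from the lightest imaginable interaction: the two
endpoints of a diameter stroke drawn by the user.

### The two-point attraction map

The interaction enters the model through a weight map inspired by the field
of two opposite point charges. Anchored at a point `c`, the sphere function
`S(r) = ||r − c||²` has gradient `G(r) = 2 (r − c)`; each charge contributes
a radial field with direction `G/||G||` and magnitude `||G||^(1−p)`, where
`p ≥ 0` sets the radial decay. The source field at the first point and the
sink field at the second are superposed, `W = Q0 + Q1`, and the map is the
normalized magnitude `M = |W| / max |W|`. `W` reinforces along the segment
between the points and cancels far from it, so `M` ridges along the drawn
diameter — exactly where the nodule should be. At the singular voxel of a
charge its own field is defined as zero. With no interaction, `M` is
identically zero.

Two limiting behaviors are worth knowing. At `p = 0` the superposition of
the two linear fields is a constant vector, so the normalized map is flat:
low `p` emphasizes the central region at the price of volume. At large `p`
the map concentrates into small shells around the two points. Intermediate
values (`p ≈ 0.5`) yield an ellipsoidal high-value region connecting the
points, which matches the roughly ellipsoidal shape of most nodules.

The map is used twice: concatenated as a third input channel of the
correction block, and thresholded (`M > γ`, strict) into the region of
interest of the attraction loss. Because the map is normalized, `γ ∈ [0,1]`.

### Losses

- soft IoU loss `L_IoU = 1 − Σ(t∘p) / (Σt + Σp − Σ(t∘p))` between the
  binary annotation `t` and the un-thresholded soft prediction `p`;
  defined as 0 when both grids are empty.
- attraction loss `L_att = 1 − Σ((M>γ)∘p) / Σ(M>γ)`: the fraction of the
  interaction ROI not covered by prediction mass; an empty ROI (no
  interaction) contributes nothing, so the automatic path is unaffected.
- combination `L = λ₁ L_IoU + (1−λ₁) L_att` with `λ₁ ∈ [0,1]`.

Defaults `γ = 0.59`, `p = 0.44`, `λ₁ = 0.68` are the operating point
selected by random search at full scale; `λ₁ > 0.5` keeps the
annotation the primary target and relegates the map to local corrections.
Binarization at 0.5 happens only at evaluation, never inside a loss.

### Architecture

Each block is a compact encoder–decoder operating on `(x, y, z)` intensity
cubes in `[0, 1]`: per resolution level one 3×3×3 convolution +
batch norm + ReLU followed by a stride-2 convolution of the same kind;
two bottleneck convolutions; per decoder level a 2× nearest-neighbour
upsample, a convolution, a skip concatenation with the matching encoder
output and another convolution; finally a biased 3×3×3 convolution with a
sigmoid. "Same" padding keeps encoder and decoder shapes mirrored; inputs
must be divisible by 2³.

The reference stage widths are `(12, 24, 68, 110)`, fixed by requiring
(a) the layer vocabulary above and (b) a trainable-parameter total of
exactly 1,592,093 for the single-channel first block — the reference size
for this architecture. The same constraint settles the bias convention:
convolutions followed by batch normalization carry no bias; only the
sigmoid head does. The second block is identical except for its 3-channel
input `[image, initial prediction, M]` — feeding `M` at the encoder input
(rather than only in the decoder) lets every weight of the correction block
react to the user's points, and the skip connections still deliver `M` to
the final layers.

The sigmoid head bias of both blocks is initialized to `logit(0.01)`, the
standard foreground-prior initialization for sparse-foreground
segmentation. Without it the early soft-IoU gradients — diluted by the
union term once predictions inflate — can lose against the dense attraction
gradients, and stage-2 training can stall on a degenerate solution that
simply paints the ROI.

### Compute engine

No deep-learning framework is used: the layers (3D convolution with
analytic backward, batch normalization, ReLU, sigmoid, nearest upsampling)
and the Adam optimizer are implemented directly on numpy in `iwnet.nn`.
Convolutions evaluate as 27 offset-wise GEMMs, which avoids materializing
im2col buffers; gradients with respect to a block's raw input are skipped
where nothing consumes them. Everything runs in float32 on CPU.

## Training procedure

Training pairs each nodule with **every** annotator's mask — no consensus
merging — so the same image appears with different viable ground truths.
Two stages:

1. the first block trains alone with `L_IoU` until the validation loss
   fails to strictly improve for 3 consecutive epochs (best weights kept);
2. its weights are frozen (it runs in inference mode; its outputs are
   cached), and the correction block trains with `L` on inputs
   `[image, initial prediction, M]`, where `M` comes from simulated user
   input on that pair's mask, until 5 epochs without improvement.

Simulated interaction takes the two most distant boundary pixels
(4-connectivity; exhaustive O(n²) search, lexicographic tie-break) on the
median occupied axial slice during training, and on the slice through the
mask's center of mass (rounded) at evaluation. This is deliberately the
hard scenario: nothing guarantees the diameter endpoints point along the
direction in which the segmentation needs correcting.

Cross-validation partitions at scan level (a scan's nodules never straddle
folds), stratified by texture class, with 20% of the training scans held
out for validation. Hyper-parameters `{λ₁, γ, p}` come from random search
with triples drawn uniformly on `[0,1]³`, scored by validation IoU on the
first split; at desk scale each step uses a shortened training schedule.

## Data handling

Cubes are extracted by cropping 51 mm around the nodule's consensus center
(out-of-scan regions padded with −1000 HU), resampling isotropically to
64³ — trilinear for images, nearest-neighbour for masks, voxel-center
convention — and windowing `[−1000, 400]` HU linearly onto `[0, 1]`.
Augmentation applies one shared spatial transform per draw: rotation about
the axial axis ±15°, translation ±4 voxels per axis, isotropic zoom in
`[0.9, 1.1]`, independent per-axis flips at probability 0.5 — conservative
ranges that keep the 51 mm context valid. Volumes are read and written as
NIfTI or MetaImage through SimpleITK; cohorts are CSV manifests with
semicolon-separated per-annotator mask paths and texture ratings.

## Evaluation protocols

Predictions are binarized at 0.5. Per nodule with agreement level ≥ 2:

- **automatic**: mean IoU of the initial prediction over all annotators;
- **interactive**: one guided prediction per annotator (driven by that
  annotator's simulated endpoints); per annotator the better of corrected
  and initial is kept (`max` of the IoUs), then averaged. By construction
  this corrected score dominates the automatic one; the interesting
  quantity is how often it *strictly* improves.
- **inter-observer agreement**: each annotation scored against all others
  (ordered pairs; 12 comparisons for 4 annotators), the practical ceiling.

ASD (average surface distance, mm) uses boundary voxels under
6-connectivity as surface elements, center-to-center distances scaled by
the spacing, and the mean of the two directed means with weight ½ each;
whether the original definition uses voxel faces or centers is unstated, so
the center convention is fixed here. The corrected ASD follows the same
keep-the-better decision, decided by IoU. `iou(∅,∅) := 1` is documented
but never triggered by valid cohorts. Reports stratify by mean equivalent
spherical radius (1 mm bins over [1, 12] mm) and texture class (mean
rating ≤ 2 non-solid, = 5 solid, otherwise sub-solid).

## Synthetic phantoms

The phantom generator makes the whole stack testable without any dataset.
Each phantom is an isotropic cube (0.8 mm voxels, matching 51 mm / 64) with
a parenchyma-like noisy background (smoothed Gaussian noise), an optional
bright tubular decoy (vessel/pleura stand-in), and one randomly oriented
ellipsoid whose radius is modulated by a smooth random degree-≤2 function
on the sphere (clipped at 2 RMS units, amplitude 0.12) — so supports are
smooth and star-shaped like real contours. Texture classes map to
intensity structure (solid: bright and uniform; sub-solid: bright core in
a faint halo; non-solid: faint and textured) and to ratings that
round-trip through the classification rule.

Annotator variability warps the truth radially around its centroid by
another random sphere function scaled by a strength parameter; strength 0
reproduces the truth exactly, and the mean pairwise IoU decreases
monotonically with strength. `calibrate_annotator_strength` bisects the
strength (common random numbers across evaluations, ≥100 phantoms per
estimate) until the Monte-Carlo mean pairwise IoU hits a target — default
0.6, the order of the mutual agreement typical of expert readers.

What the phantoms do **not** emulate: reconstruction physics and CT noise
spectra, attachment taxonomy beyond the single decoy primitive, the
intensity statistics of real parenchyma, and real inter-reader *bias*
(annotators here are exchangeable warps of one truth). Passing tests
therefore demonstrate that the mechanisms work — fields, losses, training
dynamics, protocols — not that full-scale clinical accuracy is reproduced.

## Scaled-down problem sizes

The self-contained end-to-end check trains on 160 and evaluates on 40
phantoms at 32³ with stage widths `(4, 8, 16, 24)`, two annotators at warp
strength 0.25, batch 8, Adam at 0.001, and epoch caps of 6 (stage 1) and 8
(stage 2) under the standard patiences. At this scale the guided
correction raises the held-out keep-the-better mean IoU above the
automatic one and strictly improves the large majority of phantoms, with
the corrected score approaching the phantom inter-observer agreement —
exactly the behavior the interactive design is meant to produce. Calibration checks
run on a 48³ configuration. Full-scale results on clinical multi-annotator cohorts
require the original data and GPU-scale training and are out of scope; the
manifest adapter and protocols shipped here are the interface for such a
run.

## Numerical choices and degenerate inputs

- Field distances are in voxel units on the resampled isotropic grid;
  coordinates are 0-based `(x, y, z)` with z axial, evaluated at voxel
  centers.
- Coincident interaction points produce a zero map plus a warning (the
  fields cancel exactly); absent points fall back to the automatic path.
- `iou_loss` returns 0 when truth and prediction are both empty;
  `attraction_loss` returns 0 on an empty ROI. Training pairs always have
  non-empty masks, so these conventions only guard the no-interaction path.
- Early stopping means "no strict decrease of the epoch-mean validation
  loss for `patience` consecutive epochs"; the best epoch's weights are
  restored.
- Normalizing `M` by its global maximum (rather than an unspecified
  constant) is a choice; it makes `γ` scale-free.
- Masks warped by the annotator simulator are rejected and redrawn (up to
  5 times) if they come out empty or disconnected.
- ASD is undefined for empty masks and raises; the evaluation layer
  records NaN for empty *predictions* and averages over the defined ones.
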