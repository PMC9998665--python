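# Methods

## Measurement model

A single 2D CT slice, rendered to 8-bit grayscale with a soft-tissue
window, is the unit of analysis. Working coordinates are (row, col),
origin top-left, 0-based; "anterior" is the top of an axial image and the
left of a sagittal image. The exophthalmometric value is the perpendicular
distance from the corneal apex to the straight line through the two most
protruding points of the bony orbital rim:

* **axial view** — both lateral orbital rims are visible; one line joins
  their apexes and one distance is reported per eye (the two clinical
  parameters usually called A and B);
* **sagittal view** — the superior and inferior orbital rims bound one
  eye; their apex line yields a single distance (the parameter usually
  called C).

The rim line is stored in normalized Hesse form a·col + b·row + c = 0 with
a² + b² = 1 (sign convention a ≥ 0, b > 0 when a = 0), so
|a·col + b·row + c| is the exact Euclidean distance in pixels. Millimetre
output multiplies by the pixel spacing and requires isotropic in-plane
spacing — a perpendicular distance has no per-axis meaning under
anisotropic scaling, so such input raises an error rather than guessing.

## Pipeline stages and parameters

**Bone/rim extraction.** A pixel is bone iff intensity > 200 (strict; the
value presupposes the 8-bit soft-tissue-window rendering — DICOM input is
first windowed, default center 40 HU, width 400 HU, linear map, rounding
half away from zero, clipped to [0, 255]). A morphological opening with a
3×3 square element follows (the smallest element that erases width-≤2
watermark strokes), then 8-connected components below `min_component_area`
(default 100 px at 256×256; scaled with image area by
`phantom.rim_config_for`) are dropped. All three parameters live in
`RimConfig` and are echoed into every result file.

**Landmarks.** Axial rim apexes are the minimum-row bone pixels of the
left third (cols [0, ⌊W/3⌋)) and right third (cols [⌈2W/3⌉, W)); sagittal
apexes are the minimum-column bone pixels of the upper (rows [0, ⌊H/2⌋))
and lower halves. Corneal apexes are the minimum-row pixel per eye
component on axial masks (components labeled left/right by centroid
column; the two largest kept, more than two triggers a warning) and the
minimum-column pixel on sagittal masks. All extremal searches break ties
lexicographically (minimum secondary coordinate), making landmarks
deterministic on flat plateaus. Landmarks are integer pixel centers; there
is no subpixel refinement, which bounds the end-to-end error budget at
±1.5 px and contributes a systematic ≈ −0.5 px bias against continuous
ground truth.

**Segmentation.** The eye segmenter is a nested-skip encoder–decoder
(U-Net++ topology): node X[i][j] at level i re-convolves the concatenation
of all same-level predecessors with the 2× upsampled deeper node; each
node is two 3×3 conv + ReLU layers; the head is a 1×1 conv + sigmoid on
X[0][depth−1], thresholded at 0.5 (configurable). Weights use Kaiming
initialization; training minimizes the soft Dice loss
1 − 2Σ(p·t)/(Σp + Σt) (empty-vs-empty defined as 0 so the metric is total)
with Adam at lr 1e-4 decayed ×0.99 per epoch for 200 epochs at full scale
— defaults in `SegTrainConfig` (depth 5, base 32, batch 4, no
augmentation, intensities scaled to [0, 1]). The "decay rate" is read as a
per-epoch multiplicative learning-rate factor; Adam's internal moments
keep their standard defaults. One model is trained per view. The network
runs on a compact numpy reverse-mode autodiff engine (`exoct._nn`:
im2col convolution, max-pool, nearest-neighbour upsampling, Adam), so
training is single-CPU and bit-deterministic under a fixed seed. Inputs
not divisible by 2^(depth−1) are reflection-padded and cropped back.

**Scaled benchmark conditions.** CPU-scale validation uses 64×64 phantoms,
depth 3, base 8 (32,513 parameters), 30 epochs, 20 training / 2 validation
/ 10 held-out phantoms, seed 7. At this step count the full-scale lr 1e-4
cannot move the weights appreciably, so the scaled run uses lr 1e-3 with
batch 2 — the largest rate that stays out of the Dice loss's
all-background basin, chosen once from a coarse sweep and frozen. Typical
results: held-out Dice ≈ 0.95, end-to-end mean absolute distance error
≈ 0.7 px.

## Phantom design

A phantom renders: background (level 30), a tissue ellipse (80), one or
two globes as filled ellipses (150), bony rim arcs (230, the only
structure above 200), optional thin watermark strokes at bone level, and
additive Gaussian noise (default sd 3) clipped to [0, 255]. Ground-truth
masks are rasterized pre-noise; landmarks and distances come from the
continuous geometry. Default canvas 256×256 at 0.5 mm/px (in-plane spacing
is a chosen default; CT slice thickness is through-plane and irrelevant
here). Protrusion draws are 26–40 px (13–20 mm) per eye on axial and
10–22 px (5–11 mm) on sagittal — the clinical ranges of the two
parameters; rim-apex positions, arc radii, and globe geometry jitter
between seeds, and invalid draws (globes touching bone, apexes outside
their partitions) are rejected and redrawn deterministically.

Two deliberate idealizations keep the ground truth exact:

* **Apex plateaus.** The extremal-pixel rule is ill-conditioned at the
  tangent point of a smooth arc: a 3×3 opening always removes the single
  tangent pixel and the lexicographic tie-break then slides the apex
  laterally by O(√radius) px. Each arc therefore carries a 5×5 plateau
  whose corner is the true apex (at an integer pixel center), and
  `bone_mask_true` is the opened rasterization — so thresholding a
  noise-free phantom recovers bone ∪ strokes exactly and the raster apex
  equals the continuous one. Real orbital rims have blunt, irregular
  margins, so a plateau is not anatomically unreasonable, but the exact
  recovery it enables is a property of the phantom, not of patient CT.
* **Stroke placement.** Watermark strokes stay ≥ 1 px clear of bone and
  globes so the opening can always erase them completely. Real watermarks
  may cross anatomy and leave residues fused to bone after opening; that
  failure mode is outside what the phantom tests.

The phantom also does not emulate Hounsfield physics, partial-volume
blur, beam hardening, anatomical asymmetry, or pathology (incomplete or
displaced rims error out by design rather than being guessed). Passing
the phantom suite therefore demonstrates the correctness of the geometry,
morphology, learning machinery, and statistics — not clinical performance
on patient data.

## Statistics

Overlap metrics follow the confusion-count forms Dice = 2TP/(FP+2TP+FN),
IoU = TP/(TP+FN+FP), precision = TP/(TP+FP), recall = TP/(TP+FN);
zero-denominator cases return 0 with a warning so corpus means stay total.
CCC uses Lin's original 1/n moment convention (1/(n−1) would change values
slightly; the report records the convention). The ICC is the two-way,
absolute-agreement, single-measurement form ICC(A,1) =
(MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) with k = 2 raters —
"absolute consistency" in the source literature conflates two ICC types,
and absolute agreement is the one consistent with penalizing a constant
method bias; the choice is recorded in every report. Bland–Altman limits
are bias ± 1.96 × sample sd of the differences, with no confidence
intervals on the limits.

## Numerical and degenerate-input choices

* Strict `>` at the bone threshold (a pixel of exactly 200 is not bone).
* Component filtering keeps areas ≥ `min_component_area` (inclusive).
* Empty search regions (no bone in a third/half, empty eye mask, merged
  eye components) raise named errors; batch mode records and skips them.
* Opening with radius 0 is the identity; opening is idempotent and
  anti-extensive (property-tested).
* Training determinism is bit-exact under the numpy engine; histories are
  identical for identical seeds and data.
* The acceptance script's brute-force distance oracle refines a dense
  line sampling in three stages so its residual (≪ 1e-6 px) never limits
  the comparison.

## Known limitations

* Slice selection (the slice with the thickest lens) is the caller's
  responsibility; no multi-slice or 3D protrusion indices.
* No head-tilt correction; distances are in-plane.
* Incomplete, missing, or displaced orbital rims are not handled — the
  pipeline errors rather than guessing.
* The segmenter's full-scale recipe is provided but only the scaled-down
  configuration is exercised by the test suite; clinical-scale accuracy
  claims require patient data the package does not ship.
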