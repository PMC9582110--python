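# Methods

`octfluid` implements a slice-wise deep-learning pipeline that turns a 3D
OCT cube into an interactive visualization in which retinal-fluid presence,
position and severity can be read at a glance. This note documents the
models, the numerical choices, and what the synthetic phantom does and does
not show.

## Segmentation model

The segmenter is the classic 4-level U-net: per level two 3x3
convolutions, each followed by batch normalisation and ReLU; 2x2 max
pooling between encoder levels; 2x2-stride-2 transposed convolutions and
channel-concatenated skip connections on the decoder side; a final 1x1
convolution and sigmoid producing a per-pixel fluid probability. With
`base_width=32` the parameter names and shapes match the public brain-MRI
tumour-segmentation U-net (see `octfluid.model.PRETRAINED_POINTER`), so its
published weights can be loaded name-for-name from an `.npz` export and
fine-tuned — the transfer-learning route for real OCT data, where annotated
cubes are scarce. Narrower widths use seeded He-normal initialisation; the
final bias is initialised to −2 so an untrained network starts near "no
fluid", which keeps the Dice-loss gradients well scaled when the foreground
is rare.

Slices are normalised by the fixed constant 255 (not per-slice min-max, so
inter-slice brightness relations survive), replicated to three channels to
satisfy the pretrained input layer, and resized to the model's declared
input size — 256x256 for the pretrained-compatible layout. Models may also
be built fully convolutional (`input_size=None`) and run at native slice
resolution padded to a multiple of 16. Probability maps are resized back to
native resolution bilinearly and binarized at 0.5 by default.

The network and its optimiser are implemented directly on numpy (im2col
convolutions lowered to BLAS matrix products, explicit backward passes);
the backward passes are validated against finite differences in float64 in
the test suite.

## Loss and optimisation

Training minimises the Smooth Dice loss

    L(X, Y) = 1 − 2 (Σ X·Y + 1) / (Σ X + Σ Y + 1),

whose soft intersection handles the extreme class imbalance between fluid
and background. The default form places the `+1` smoothing term inside the
doubled numerator, so the loss reaches −1 (not 0) on an empty-vs-empty
pair; the more common variant `1 − (2I+1)/(|X|+|Y|+1)`, which scores
empty-vs-empty as 0, is available via
`smooth_dice_loss(..., conventional=True)`. The two differ by a constant
offset plus O(1/denominator), so they induce essentially the same gradients
and the same ranking of models.

The reference schedule is stochastic gradient descent with Nesterov
momentum 0.9 from an initial learning rate of 1e-3, batch size 10, the rate
multiplied by 0.3 whenever the validation loss has not strictly improved
for 40 consecutive epochs, early stopping after 80 epochs without
improvement, and the best-validation snapshot (never the last epoch)
returned. Validation slices are never augmented, and validation loss is the
same Smooth Dice loss. Splits are always at cube level: no B-scan of any
cube appears in two of train/validation/test.

## Augmentation

Each training pair passes an online chain in fixed order — horizontal
flip, one noise type (Gaussian σ=10 levels, salt-and-pepper at 2% of
pixels, or unit-mean speckle with variance 0.05, chosen uniformly), an
elastic deformation (displacement α=34 px smoothed with σ=4 px, the
standard recipe from the elastic-deformation literature), and a random
contrast change about the image mean (factor in [0.7, 1.3]) — each step
firing independently with probability 0.5. The geometric steps share one
displacement field between image and mask (mask resampled
nearest-neighbour, so it stays binary); the intensity steps never touch
the mask. Exactly one noise kind is drawn per activation.

## Post-processing and fusion

Predicted masks are smoothed per slice with a morphological closing
(default) or opening using a disk of radius 2; closing is the default
because it fills small false-negative gaps at diffuse fluid boundaries,
whereas opening deletes small true-positive regions. Pixels outside the
image count as background; the operators are computed on a padded plane so
both are true algebraic closings/openings (idempotent, extensive /
anti-extensive) — the structuring-element shape and radius are exposed.

Fluid thickness is the per-slice exact Euclidean distance transform of the
smoothed mask: each fluid pixel's distance (in pixels) to the nearest
non-fluid pixel of the same B-scan. Slices are treated independently,
matching the slice-wise segmentation.

Fusion packs anatomy and severity into one integer volume: voxels outside
the mask keep their [0, 255] intensity; mask voxels map to [256, 510] via
`256 + round(254·d/d_max)` with `d_max` the volume's maximum thickness
(default, full per-volume dynamic range), or `256 + min(round(d), 254)` in
clamp mode when absolute comparability across volumes matters. The mapping
law is a package choice — only the target range is fixed by the encoding.

## Rendering

A transfer function over the fused domain maps [0, 255] to achromatic grey
and [256, 510] to a green→red gradient (256 = pure green = thin fluid,
510 = pure red = thickest), interpolating linearly in RGB through yellow —
the clinical severity idiom. Still images are produced by ray casting with
maximum-intensity composition: one ray per pixel, trilinear sampling every
half voxel (Nyquist-safe), the pixel's scalar is the maximum sample and its
colour is the transfer function of that maximum. Colour is applied after
the maximum (true MIP), so opacity matters only for the interactive-viewer
export (`export_scene` writes the fused volume plus the 511-entry RGBA
table for a VTK-style ray-cast viewer). Axis-aligned orthographic cameras
from `Camera.axis_aligned` place one ray through every voxel centre of the
perpendicular plane, which makes the renderer exactly equal to a per-column
maximum and is how the renderer is verified. Interpolating the fused scalar
across the 255/256 boundary can mix anatomy into the fluid range along
blob borders; this is inherent to the single-scalar encoding and visually
negligible at the default step.

## Phantom

The phantom emulates the gross structure the pipeline relies on: a dark
background (level 8), 4 bright bands (intensities 120–220) whose
boundaries are sums of 2–3 low-frequency sinusoids with per-slice phase
drift (smooth retinal curvature across B-scans), dark ellipsoidal fluid
pockets (intensities 30–80, strictly below the band range — fluid is
hypo-reflective) placed within or just below the bands, and multiplicative
unit-mean speckle (variance 0.02, the dominant OCT noise model). Masks are
the exact voxel sets of the inserted ellipsoids, so ground truth carries
none of the annotation ambiguity of expert labels. The phantom does *not*
model vessel shadows, drusen, motion artifacts, or physically calibrated
speckle statistics, so passing tests demonstrate the pipeline's mechanics
and the network's trainability, not clinical-grade accuracy. Native
OCT256 (256 slices of 512x992) and OCT320 (320 of 320x992) geometries are
available as presets; tests use a 32x128x128 desk-scale geometry.

## Scaled-down study

`run_experiment` (and `scripts/acceptance.py`) trains a width-8 U-net from
random initialisation on 10 phantom cubes (8 train / 2 val, split at cube
level), evaluates 3 held-out cubes (one a healthy control), and reports
pooled and per-cube Dice/IoU for raw, closed and opened predictions plus
the false-positive voxel count on the healthy cube. Because no pretrained
start exists at width 8, the desk-scale run uses a larger initial learning
rate (0.02 — still-larger rates can saturate the sigmoid output into a
dead all-background state on some initialisations) with a two-epoch linear
warmup while the batch-norm statistics settle, and the plateau/early-stop
patience scaled to the shorter epoch budget (8/16 over at most 40 epochs);
the schedule shape (Nesterov SGD, x0.3 drops, best-snapshot early
stopping) is unchanged. `TrainConfig` also exposes optional global
gradient-norm clipping for users training at more aggressive rates. Training and
prediction run at 64x64 (the resize path of the model input contract),
whose mask round-trip Dice ceiling against the 128x128 ground truth is
about 0.98. Typical held-out pooled Dice is ~0.9 with closing slightly
above raw and opening slightly below, and zero false positives on the
healthy cube — the same qualitative ordering that motivates choosing
closing in the reference pipeline.

## Group aggregation

Per-group metrics pool voxel counts (TP/FP/FN summed over the group's
cubes) rather than averaging per-cube scores: pooling is well defined for
healthy cubes (empty truth, empty prediction: score 1, zero counts) and
robust to cubes with little fluid. The per-cube mean is reported alongside
for transparency.

## Known limitations

- The 2D slice-wise network ignores inter-slice context; transition slices
  at the ends of a fluid pocket are the dominant error mode. A 3D network
  is out of scope.
- The phantom's simplicity means desk-scale metrics should not be read as
  clinical performance.
- `load_pretrained` consumes an `.npz` export of the public state dict;
  the weights themselves are deliberately not bundled.
- Physical voxel spacing is not modelled; thickness is in pixels and unit
  spacing is assumed throughout.
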