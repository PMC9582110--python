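# octfluid

Fully automatic segmentation and 3D visualization of the retinal fluid that
characterises wet age-related macular degeneration (AMD) in OCT cubes.

Wet AMD leaks fluid into and beneath the retina; on optical coherence
tomography (OCT) it appears as hypo-reflective (dark) pockets inside the
bright retinal layers. An OCT exam produces hundreds of cross-sectional
B-scans per eye, which clinicians otherwise inspect slice by slice.
`octfluid` chains:

1. **Slice-wise U-net segmentation** trained with the Smooth Dice loss
   `L(X,Y) = 1 − 2(Σ X·Y + 1)/(Σ X + Σ Y + 1)` (robust to the extreme
   fluid/background imbalance), SGD with Nesterov momentum, a
   reduce-on-plateau learning-rate schedule (×0.3 after 40 stalled epochs)
   and early stopping (80 stalled epochs, best-validation snapshot kept).
   The `base_width=32` layout is tensor-for-tensor compatible with the
   public brain-MRI U-net, the transfer-learning starting point for real
   data. The network runs on pure numpy; no GPU framework is required.
2. **Mask smoothing** by per-slice morphological closing (default) or
   opening with a disk structuring element.
3. **Thickness analysis**: a per-slice Euclidean distance transform of the
   mask estimates local fluid thickness (severity).
4. **Volume fusion** into one integer scalar field: anatomy keeps its
   [0, 255] intensity where there is no fluid; fluid voxels are encoded in
   [256, 510] from their thickness (the thickest point maps to 510).
5. **Ray-cast rendering** with maximum-intensity composition and a
   red-green transfer function — grey anatomy, green = thin fluid,
   red = thick fluid — so presence, position and severity are visible at a
   glance; `export_scene` emits the fused volume + transfer table for an
   interactive VTK-style viewer.

Cube geometries `OCT256` (256 slices of 512x992) and `OCT320` (320 slices
of 320x992) are recognised presets; cubes are read/written as PNG/TIFF
slice stacks, MetaImage `.mha` or NIfTI. A synthetic **phantom** module
generates layered, speckled OCT-like cubes with exact fluid masks so every
stage is testable without clinical data. Evaluation reports the Dice
coefficient `DSC = 2|A∩B|/(|A|+|B|)` and Jaccard index
`IoU = |A∩B|/|A∪B|` per cube and pooled per geometry group.

## Worked example

```python
import numpy as np
from octfluid import (PhantomConfig, generate_cube, smooth_mask,
                      thickness_map, fuse, build_transfer_function,
                      render_mip, Camera, dice)

volume, mask = generate_cube(PhantomConfig(seed=3))   # 32 x 128 x 128 cube
smoothed = smooth_mask(mask, op="closing", radius=2)
thick = thickness_map(smoothed)
fused = fuse(volume, smoothed, thick)
print(volume.shape, int(mask.sum()), float(thick.max()), int(fused.max()))

tf = build_transfer_function()
img = render_mip(fused, tf, Camera.axis_aligned(fused.shape, "z"))
print(img.shape, float(img[..., 0].max()))
print(round(dice(smoothed, mask), 4))
```

prints

```
(32, 128, 128) 4216 6.0 510
(128, 128, 3) 1.0
0.9987
```

— the phantom holds 4,216 fluid voxels, up to 6 px thick in-slice, so the
fused volume tops out at 510 and the *en-face* maximum-intensity render
contains a fully red pixel over the thickest pocket. Closing barely
perturbs the already-smooth synthetic mask (Dice 0.999 against the
original).

To train and evaluate a model on phantoms from the shell:

```sh
octfluid phantom --out data --n-train 8 --n-val 2 --n-test 3 --seed 0
octfluid experiment --out results --seed 0
octfluid pipeline --cube data/test/test_000/cube \
                  --mask data/test/test_000/mask --out recon
```

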