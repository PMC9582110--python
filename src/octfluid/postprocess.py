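"""Pre-rendering mask processing: smoothing, thickness analysis, fusion.

Three steps turn a predicted fluid mask plus the source OCT cube into one
scalar volume that a single transfer function can render:

1. :func:`smooth_mask` — per-slice morphological closing (default) or
   opening with a disk structuring element, smoothing segmentation edges and
   mitigating artifacts.  Closing fills small false-negative gaps; opening
   removes small false-positive islands (at the risk of deleting small true
   fluid).  Outside the image is treated as background, implemented by
   padding before the operation, so both operators are true algebraic
   closings/openings (idempotent, extensive/anti-extensive).
2. :func:`thickness_map` — per-slice exact Euclidean distance transform of
   the mask: each fluid pixel's distance to the nearest non-fluid pixel of
   the same slice, a proxy for local fluid thickness (severity).
3. :func:`fuse` — anatomy keeps its [0, 255] intensity wherever the mask is
   0; fluid voxels are remapped to [256, 510] from their thickness, so one
   integer volume carries both signals.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, disk


def _footprint(radius: int, three_d: bool) -> np.ndarray:
    return ball(radius) if three_d else disk(radius)


def smooth_mask(mask: np.ndarray, op: str = "closing", radius: int = 2,
                three_d: bool = False) -> np.ndarray:
    """Morphologically smooth a binary mask, slice by slice.

    ``op`` is ``"closing"`` (dilation then erosion) or ``"opening"`` (erosion
    then dilation) with a disk (2D, default) or ball (``three_d=True``)
    structuring element of the given ``radius``.  Pixels outside the image
    count as background.
    """
    if op not in ("closing", "opening"):
        raise ValueError(f"unknown op {op!r}; use 'closing' or 'opening'")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    fp = _footprint(radius, three_d)

    def _apply(m: np.ndarray) -> np.ndarray:
        pad = 2 * radius + 2  # large enough that the border never interacts
        mp = np.pad(m, pad)
        if op == "closing":
            out = ndimage.binary_erosion(ndimage.binary_dilation(mp, fp), fp)
        else:
            out = ndimage.binary_dilation(ndimage.binary_erosion(mp, fp), fp)
        sl = tuple(slice(pad, -pad) for _ in range(m.ndim))
        return out[sl]

    if three_d:
        return _apply(mask)
    return np.stack([_apply(sl) for sl in mask])


def thickness_map(mask: np.ndarray) -> np.ndarray:
    """Per-slice Euclidean distance of each fluid pixel to the nearest
    non-fluid pixel in the same slice; 0 on non-fluid pixels.

    Slices are independent (the distance is 2D, matching the slice-wise
    segmentation).  In the degenerate case of a slice with no background,
    the image border counts as background.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError(f"expected a (z, y, x) mask, got shape {mask.shape}")
    out = np.zeros(mask.shape, dtype=np.float64)
    for i, sl in enumerate(mask):
        if not sl.any():
            continue
        if sl.all():
            padded = np.pad(sl, 1)
            out[i] = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
        else:
            out[i] = ndimage.distance_transform_edt(sl)
    return out


def fuse(cube: np.ndarray, mask: np.ndarray, thickness: np.ndarray,
         mode: str = "linear") -> np.ndarray:
    """Merge anatomy and thickness into one uint16 volume in [0, 510].

    Voxels with ``mask == 0`` copy the cube intensity unchanged ([0, 255]).
    Fluid voxels are encoded in [256, 510]:

    - ``mode="linear"`` (default): ``256 + round(254 * d / d_max)`` with
      ``d_max`` the maximum thickness of this volume, so the thickest point
      always maps to 510 (full per-volume dynamic range);
    - ``mode="clamp"``: ``256 + min(round(d), 254)`` — absolute thickness in
      pixels, comparable across volumes.

    An empty mask returns the cube unchanged (as uint16).
    """
    cube = np.asarray(cube)
    mask = np.asarray(mask, dtype=bool)
    thickness = np.asarray(thickness, dtype=np.float64)
    if not (cube.shape == mask.shape == thickness.shape):
        raise ValueError(
            f"geometry mismatch: cube {cube.shape}, mask {mask.shape}, "
            f"thickness {thickness.shape}")
    if cube.min(initial=0) < 0 or cube.max(initial=0) > 255:
        raise ValueError("cube intensities must lie in [0, 255]")
    if np.any((thickness > 0) & ~mask):
        raise ValueError("thickness is nonzero outside the mask")
    if np.any(mask & (thickness <= 0)):
        raise ValueError("thickness must be positive on every mask voxel")
    if mode not in ("linear", "clamp"):
        raise ValueError(f"unknown mode {mode!r}; use 'linear' or 'clamp'")

    fused = cube.astype(np.uint16)
    if mask.any():
        d = thickness[mask]
        if mode == "linear":
            vals = 256 + np.rint(254.0 * d / d.max())
        else:
            vals = 256 + np.minimum(np.rint(d), 254)
        fused[mask] = vals.astype(np.uint16)
    return fused
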