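"""Ray-cast visualization of fused volumes with a red-green severity scale.

The fused volume's scalar domain [0, 510] splits into anatomy ([0, 255],
rendered as grey) and fluid severity ([256, 510], rendered on a green→red
gradient: 256 = pure green = thin fluid, 510 = pure red = thickest fluid,
interpolating linearly in RGB through yellow — the clinical severity
idiom).  Composition is maximum-intensity projection (MIP): one ray per
output pixel, the scalar field sampled along the ray with trilinear
interpolation at a fixed step, the pixel's scalar is the maximum sample,
and the colour is the transfer function applied to that maximum.  Rays that
miss the volume produce the background colour.

World coordinates equal voxel index coordinates ``(z, y, x)`` with samples
at voxel centres (integer positions); the volume occupies the box
[-0.5, n-0.5] per axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

import SimpleITK as sitk

FUSED_MAX = 510  # top of the fused scalar domain


@dataclass(frozen=True)
class TransferFunction:
    """Lookup table over integer scalars 0..510 -> (R, G, B, opacity)."""

    table: np.ndarray  # (511, 4) float in [0, 1]

    def __post_init__(self) -> None:
        if self.table.shape != (FUSED_MAX + 1, 4):
            raise ValueError(f"table must be ({FUSED_MAX + 1}, 4), got {self.table.shape}")

    def color(self, scalar: np.ndarray) -> np.ndarray:
        """RGB for (possibly fractional) scalar values, linearly interpolated."""
        s = np.clip(np.asarray(scalar, dtype=np.float64), 0, FUSED_MAX)
        xp = np.arange(FUSED_MAX + 1)
        return np.stack([np.interp(s, xp, self.table[:, c]) for c in range(3)], axis=-1)

    def __call__(self, scalar: np.ndarray) -> np.ndarray:
        """RGBA for scalar values."""
        s = np.clip(np.asarray(scalar, dtype=np.float64), 0, FUSED_MAX)
        xp = np.arange(FUSED_MAX + 1)
        return np.stack([np.interp(s, xp, self.table[:, c]) for c in range(4)], axis=-1)


def build_transfer_function(grey_opacity: float = 0.05,
                            fluid_opacity: float = 0.6) -> TransferFunction:
    """The red-green severity transfer function.

    Scalars 0..255 map to achromatic grey (R=G=B=v/255) at ``grey_opacity``;
    256 maps to pure green, 510 to pure red, linear in RGB between, at
    ``fluid_opacity``.  Opacities only matter for interactive-viewer export;
    MIP stills use the colour channels.
    """
    if not (0 <= grey_opacity <= 1 and 0 <= fluid_opacity <= 1):
        raise ValueError("opacities must lie in [0, 1]")
    table = np.zeros((FUSED_MAX + 1, 4))
    grey = np.arange(256) / 255.0
    table[:256, 0] = table[:256, 1] = table[:256, 2] = grey
    table[:256, 3] = grey_opacity
    t = (np.arange(256, FUSED_MAX + 1) - 256) / 254.0  # 0 at 256 -> 1 at 510
    table[256:, 0] = t        # red rises with severity
    table[256:, 1] = 1.0 - t  # green falls
    table[256:, 3] = fluid_opacity
    return TransferFunction(table)


@dataclass(frozen=True)
class Camera:
    """Pinhole/orthographic camera in (z, y, x) voxel-world coordinates."""

    eye: tuple[float, float, float]
    direction: tuple[float, float, float]
    up: tuple[float, float, float]
    image_size: tuple[int, int] = (256, 256)  # (rows, cols)
    orthographic: bool = True
    scale: float = 256.0       # world height of the orthographic view window
    fov_deg: float = 45.0      # vertical field of view (perspective only)

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        d = np.asarray(self.direction, dtype=np.float64)
        u = np.asarray(self.up, dtype=np.float64)
        nd = np.linalg.norm(d)
        if nd == 0:
            raise ValueError("view direction must be non-zero")
        d = d / nd
        right = np.cross(d, u)
        nr = np.linalg.norm(right)
        if nr < 1e-12:
            raise ValueError("view direction and up vector are parallel")
        right /= nr
        true_up = np.cross(right, d)
        return d, right, true_up

    @staticmethod
    def axis_aligned(volume_shape: tuple[int, int, int], axis: str = "z",
                     distance: float = 2.0) -> "Camera":
        """Orthographic camera looking along +axis with pixel (i, j) mapped
        exactly onto the voxel grid of the perpendicular plane (one pixel per
        voxel, rays through voxel centres)."""
        nz, ny, nx = volume_shape
        # each view is chosen so the right-handed camera basis maps pixel
        # (i, j) exactly onto the perpendicular voxel plane: row i -> first
        # remaining axis, column j -> second remaining axis
        if axis == "z":
            centre_y, centre_x = (ny - 1) / 2.0, (nx - 1) / 2.0
            return Camera(eye=(nz - 1 + distance, centre_y, centre_x),
                          direction=(-1, 0, 0), up=(0, -1, 0),
                          image_size=(ny, nx), orthographic=True, scale=float(ny))
        if axis == "y":
            centre_z, centre_x = (nz - 1) / 2.0, (nx - 1) / 2.0
            return Camera(eye=(centre_z, -distance, centre_x), direction=(0, 1, 0),
                          up=(-1, 0, 0), image_size=(nz, nx),
                          orthographic=True, scale=float(nz))
        if axis == "x":
            centre_z, centre_y = (nz - 1) / 2.0, (ny - 1) / 2.0
            return Camera(eye=(centre_z, centre_y, nx - 1 + distance),
                          direction=(0, 0, -1), up=(-1, 0, 0),
                          image_size=(nz, ny), orthographic=True, scale=float(nz))
        raise ValueError(f"axis must be 'z', 'y' or 'x', got {axis!r}")


def _ray_grid(cam: Camera) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel ray origins (H, W, 3) and directions (H, W, 3)."""
    d, right, true_up = cam.basis()
    h, w = cam.image_size
    eye = np.asarray(cam.eye, dtype=np.float64)
    px = cam.scale / h
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    u = (jj - (w - 1) / 2.0) * px
    v = ((h - 1) / 2.0 - ii) * px
    offsets = u[..., None] * right + v[..., None] * true_up
    if cam.orthographic:
        origins = eye + offsets
        dirs = np.broadcast_to(d, origins.shape).copy()
    else:
        focal = (cam.scale / 2.0) / np.tan(np.deg2rad(cam.fov_deg) / 2.0)
        origins = np.broadcast_to(eye, offsets.shape).copy()
        dirs = focal * d + offsets
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    return origins, dirs


def _box_intersect(origins: np.ndarray, dirs: np.ndarray,
                   shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit distances of each ray with the volume box [-0.5, n-0.5]."""
    lo = np.full(3, -0.5)
    hi = np.asarray(shape, dtype=np.float64) - 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - origins) / dirs
        t2 = (hi - origins) / dirs
    tmin = np.where(np.isnan(t1), -np.inf, np.minimum(t1, t2))
    tmax = np.where(np.isnan(t2), np.inf, np.maximum(t1, t2))
    # axes with zero direction: inside-slab check
    zero = dirs == 0
    inside = (origins >= lo) & (origins <= hi)
    tmin = np.where(zero, np.where(inside, -np.inf, np.inf), tmin)
    tmax = np.where(zero, np.where(inside, np.inf, -np.inf), tmax)
    return np.maximum(tmin.max(axis=-1), 0.0), tmax.min(axis=-1)


def render_mip(volume: np.ndarray, tf: TransferFunction, cam: Camera,
               step: float = 0.5,
               background: tuple[float, float, float] = (0.0, 0.0, 0.0)
               ) -> np.ndarray:
    """Maximum-intensity ray casting of a fused volume.

    Returns a float RGB image of shape ``cam.image_size + (3,)``.  The
    scalar field is sampled with trilinear interpolation every ``step``
    world units (default half a voxel) from the ray's entry to its exit
    point; each pixel's colour is ``tf`` applied to the maximum sample.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3 or volume.size == 0:
        raise ValueError(f"expected a non-empty 3D volume, got shape {volume.shape}")
    if step <= 0:
        raise ValueError("step must be > 0")
    origins, dirs = _ray_grid(cam)
    t_near, t_far = _box_intersect(origins, dirs, volume.shape)
    hit = t_far >= t_near
    h, w = cam.image_size
    scalars = np.full((h, w), -np.inf)
    if hit.any():
        span = float(np.max(np.where(hit, t_far - t_near, 0.0)))
        n_samples = int(np.ceil(span / step)) + 1
        ts = t_near[..., None] + step * np.arange(n_samples)
        valid = hit[..., None] & (ts <= t_far[..., None])
        pts = origins[..., None, :] + ts[..., None] * dirs[..., None, :]
        coords = pts.reshape(-1, 3).T
        # large negative fill: out-of-box contributions can never win the max
        samples = map_coordinates(volume.astype(np.float64), coords, order=1,
                                  mode="constant", cval=-1e30)
        samples = samples.reshape(h, w, n_samples)
        samples[~valid] = -np.inf
        scalars = samples.max(axis=-1)
    image = np.empty((h, w, 3))
    miss = ~np.isfinite(scalars) | (scalars < 0)
    image[~miss] = tf.color(scalars[~miss])
    image[miss] = np.asarray(background, dtype=np.float64)
    return image


def save_png(image: np.ndarray, path: str | Path) -> Path:
    """Write a float [0, 1] RGB image as an 8-bit PNG."""
    import imageio.v3 as iio
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.clip(np.rint(image * 255), 0, 255).astype(np.uint8))
    return path


def export_scene(volume: np.ndarray, tf: TransferFunction, path: str | Path) -> Path:
    """Export a fused volume + transfer tables for an interactive viewer.

    Writes ``fused.mha`` (uint16 scalar grid) and ``transfer_function.json``
    (511 entries of ``[value, r, g, b, opacity]``) into directory ``path``.
    A VTK-based viewer can map these directly onto a ray-cast volume
    property.  Round-trips losslessly via :func:`load_scene`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    vol = np.asarray(volume)
    if vol.min(initial=0) < 0 or vol.max(initial=0) > FUSED_MAX:
        raise ValueError("fused volume values must lie in [0, 510]")
    sitk.WriteImage(sitk.GetImageFromArray(vol.astype(np.uint16)), str(path / "fused.mha"))
    entries = [[int(v), *map(float, tf.table[v])] for v in range(FUSED_MAX + 1)]
    (path / "transfer_function.json").write_text(
        json.dumps({"domain": [0, FUSED_MAX], "rgba": entries}))
    return path


def load_scene(path: str | Path) -> tuple[np.ndarray, TransferFunction]:
    """Reload a scene written by :func:`export_scene`."""
    path = Path(path)
    vol = sitk.GetArrayFromImage(sitk.ReadImage(str(path / "fused.mha")))
    data = json.loads((path / "transfer_function.json").read_text())
    table = np.array([e[1:] for e in data["rgba"]], dtype=np.float64)
    return vol, TransferFunction(table)
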