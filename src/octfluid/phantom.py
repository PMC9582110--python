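"""Synthetic OCT-like phantom cubes with paired fluid masks.

The phantom emulates the gross appearance of a macular OCT cube: a dark
vitreous/choroid background, a stack of bright, gently wavy retinal bands
whose boundaries drift smoothly from B-scan to B-scan, hypo-reflective
(dark) ellipsoidal fluid pockets placed within or just below the bands, and
multiplicative speckle noise.  The paired mask is the exact voxel set of the
inserted pockets, so the ground truth is perfect by construction.

These cubes stand in for clinical data in every downstream stage (training,
evaluation, post-processing, rendering); they are deliberately simple —
no vessel shadows, drusen, or physically calibrated speckle statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .io import PRESETS

#: Constant background (vitreous/choroid) intensity before speckle.
BACKGROUND_LEVEL = 8


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic cube generator.

    Defaults are the desk-scale test geometry (32 slices of 128 x 128);
    the native acquisition geometries are available through
    :func:`preset_config`.
    """

    n_slices: int = 32
    height: int = 128
    width: int = 128
    n_layers: int = 4
    layer_intensity_range: tuple[int, int] = (120, 220)
    boundary_waviness: float = 3.0
    n_fluid_blobs: int = 3
    blob_radius_range: tuple[int, int] = (4, 10)
    fluid_intensity_range: tuple[int, int] = (30, 80)
    speckle_variance: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_slices, self.height, self.width) < 8:
            raise ValueError("n_slices, height and width must all be >= 8")
        if self.n_layers < 1:
            raise ValueError("need at least one retinal band")
        lo, hi = self.fluid_intensity_range
        llo, lhi = self.layer_intensity_range
        if not (0 <= lo <= hi <= 255 and 0 <= llo <= lhi <= 255):
            raise ValueError("intensity ranges must lie in [0, 255]")
        if hi >= llo:
            raise ValueError(
                "fluid must be hypo-reflective: fluid_intensity_range max "
                f"({hi}) must be < layer_intensity_range min ({llo})"
            )
        if lo <= BACKGROUND_LEVEL:
            raise ValueError(
                f"fluid_intensity_range min ({lo}) must exceed the background "
                f"level ({BACKGROUND_LEVEL}) so fluid stays identifiable"
            )
        rlo, rhi = self.blob_radius_range
        if not (1 <= rlo <= rhi):
            raise ValueError("blob_radius_range must satisfy 1 <= lo <= hi")
        if self.speckle_variance < 0:
            raise ValueError("speckle_variance must be >= 0")


def preset_config(preset: Literal["OCT256", "OCT320", "test"], **overrides) -> PhantomConfig:
    """A :class:`PhantomConfig` at a named geometry (``test`` = 32x128x128)."""
    if preset == "test":
        return replace(PhantomConfig(), **overrides)
    geom = PRESETS[preset]
    return replace(
        PhantomConfig(n_slices=geom.n_slices, height=geom.height, width=geom.width,
                      blob_radius_range=(10, 40), boundary_waviness=12.0),
        **overrides,
    )


def _layer_boundaries(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Row position of each band boundary, shape (n_layers+1, n_slices, width).

    Each boundary is a sum of 2-3 low-frequency sinusoids in the column
    coordinate whose phases drift slowly across slices, mimicking smooth
    retinal curvature between adjacent B-scans.
    """
    z = np.arange(cfg.n_slices)[:, None]
    x = np.arange(cfg.width)[None, :]
    top, bottom = 0.25 * cfg.height, 0.70 * cfg.height
    bases = np.linspace(top, bottom, cfg.n_layers + 1)
    boundaries = np.empty((cfg.n_layers + 1, cfg.n_slices, cfg.width))
    for k, base in enumerate(bases):
        wave = np.zeros((cfg.n_slices, cfg.width))
        n_waves = rng.integers(2, 4)
        amps = rng.dirichlet(np.ones(n_waves)) * cfg.boundary_waviness
        for amp in amps:
            freq = rng.uniform(0.5, 2.0)  # cycles across the slice width
            phase = rng.uniform(0, 2 * np.pi)
            drift = rng.uniform(-1.0, 1.0) * 2 * np.pi / max(cfg.n_slices, 1)
            wave += amp * np.sin(2 * np.pi * freq * x / cfg.width + phase + drift * z)
        boundaries[k] = base + wave
    return boundaries


def generate_cube(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phantom cube and its exact fluid mask.

    Returns ``(volume, mask)``: a uint8 ``(z, y, x)`` intensity volume and an
    aligned boolean mask.  Identical config (including seed) gives
    bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    r_max = cfg.blob_radius_range[1]
    if cfg.n_fluid_blobs > 0 and 2 * r_max + 2 > min(cfg.n_slices, cfg.height, cfg.width):
        raise ValueError(
            f"geometry {cfg.n_slices}x{cfg.height}x{cfg.width} too small to "
            f"contain blobs of radius up to {r_max} (needs every dimension "
            f">= {2 * r_max + 2})"
        )

    volume = np.full((cfg.n_slices, cfg.height, cfg.width), BACKGROUND_LEVEL, dtype=np.float64)
    boundaries = _layer_boundaries(cfg, rng)
    rows = np.arange(cfg.height)[None, :, None]
    for k in range(cfg.n_layers):
        intensity = float(rng.integers(cfg.layer_intensity_range[0],
                                       cfg.layer_intensity_range[1] + 1))
        band = (rows >= boundaries[k][:, None, :]) & (rows < boundaries[k + 1][:, None, :])
        volume[band] = intensity

    mask = np.zeros(volume.shape, dtype=bool)
    band_top = float(boundaries[0].min())
    band_bottom = float(boundaries[-1].max())
    for _ in range(cfg.n_fluid_blobs):
        rz, ry, rx = rng.integers(cfg.blob_radius_range[0], r_max + 1, size=3)
        cz = rng.uniform(rz, cfg.n_slices - 1 - rz)
        # centre constrained to the band region or just below it (sub-band fluid)
        y_lo = min(band_top + ry, cfg.height - 1 - ry)
        y_hi = min(band_bottom + 0.1 * cfg.height, cfg.height - 1 - ry)
        cy = rng.uniform(y_lo, max(y_lo, y_hi))
        cx = rng.uniform(rx, cfg.width - 1 - rx)
        zz, yy, xx = np.ogrid[:cfg.n_slices, :cfg.height, :cfg.width]
        blob = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
                + ((xx - cx) / rx) ** 2) <= 1.0
        intensity = float(rng.integers(cfg.fluid_intensity_range[0],
                                       cfg.fluid_intensity_range[1] + 1))
        volume[blob] = intensity
        mask |= blob

    if cfg.speckle_variance > 0:
        noise = rng.normal(0.0, np.sqrt(cfg.speckle_variance), volume.shape)
        volume = volume * (1.0 + noise)
    volume = np.clip(np.rint(volume), 0, 255).astype(np.uint8)
    return volume, mask


@dataclass(frozen=True)
class PhantomCube:
    """One generated cube tagged with its dataset split."""

    cube_id: str
    split: Literal["train", "val", "test"]
    volume: np.ndarray
    mask: np.ndarray
    config: PhantomConfig

    @property
    def healthy(self) -> bool:
        return not bool(self.mask.any())


@dataclass(frozen=True)
class PhantomDataset:
    cubes: tuple[PhantomCube, ...] = field(default_factory=tuple)

    def split(self, name: str) -> list[PhantomCube]:
        return [c for c in self.cubes if c.split == name]


def generate_dataset(
    n_train_cubes: int,
    n_val_cubes: int,
    n_test_cubes: int,
    config: PhantomConfig | None = None,
) -> PhantomDataset:
    """Generate disjoint train/val/test phantom cubes.

    Per-cube seeds are derived deterministically from ``config.seed``.  When
    the test split has three or more cubes, one of them is a healthy
    (zero-blob) control cube so false-positive robustness can be evaluated,
    mirroring the inclusion of control patients in a held-out clinical set.
    """
    cfg = config if config is not None else PhantomConfig()
    if min(n_train_cubes, n_val_cubes, n_test_cubes) < 0:
        raise ValueError("cube counts must be >= 0")
    counts = {"train": n_train_cubes, "val": n_val_cubes, "test": n_test_cubes}
    seeds = np.random.SeedSequence(cfg.seed).generate_state(sum(counts.values()))
    cubes: list[PhantomCube] = []
    i = 0
    for split, n in counts.items():
        for j in range(n):
            cube_cfg = replace(cfg, seed=int(seeds[i] % (2 ** 31)))
            if split == "test" and n >= 3 and j == n - 1:
                cube_cfg = replace(cube_cfg, n_fluid_blobs=0)  # healthy control
            volume, mask = generate_cube(cube_cfg)
            cubes.append(PhantomCube(f"{split}_{j:03d}", split, volume, mask, cube_cfg))
            i += 1
    return PhantomDataset(tuple(cubes))
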