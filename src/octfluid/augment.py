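"""Online training-time augmentation for OCT slices.

The chain applies, in order and each independently with probability
``p_apply`` (default 0.5): horizontal flip, one noise type (Gaussian,
salt-and-pepper or speckle, chosen uniformly), an elastic deformation, and a
random contrast change.  Geometric transforms (flip, elastic) are applied
identically to image and mask; intensity transforms (noise, contrast) touch
the image only, so the mask stays strictly binary throughout.

Elastic deformation follows the standard recipe: a random displacement
field, Gaussian-smoothed with ``elastic_sigma`` and scaled by
``elastic_alpha``, shared between image (bilinear sampling) and mask
(nearest-neighbour sampling).  It mimics the smooth deformations real
(healthy and pathological) retinas exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

_NOISE_KINDS = ("gaussian", "salt_pepper", "speckle")


@dataclass(frozen=True)
class AugmentConfig:
    p_apply: float = 0.5
    noise_kinds: tuple[str, ...] = _NOISE_KINDS
    gaussian_sigma: float = 10.0          # additive noise std, intensity levels
    sp_amount: float = 0.02               # fraction of pixels hit by salt/pepper
    speckle_variance: float = 0.05
    elastic_alpha: float = 34.0           # displacement scale, px
    elastic_sigma: float = 4.0            # field smoothing, px
    contrast_factor_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError("p_apply must be in [0, 1]")
        if not 0.0 <= self.sp_amount < 1.0:
            raise ValueError("sp_amount must be in [0, 1)")
        if self.elastic_sigma <= 0:
            raise ValueError("elastic_sigma must be > 0")
        unknown = set(self.noise_kinds) - set(_NOISE_KINDS)
        if unknown:
            raise ValueError(f"unknown noise kinds: {sorted(unknown)}")
        lo, hi = self.contrast_factor_range
        if not 0 <= lo <= hi:
            raise ValueError("contrast_factor_range must be non-negative and ordered")


def horizontal_flip(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mirror image and mask about the vertical axis (columns reversed)."""
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} differ")
    return image[..., ::-1].copy(), mask[..., ::-1].copy()


def add_noise(image: np.ndarray, kind: str, config: AugmentConfig,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Corrupt the image (only) with one noise type; output clipped to [0, 255]."""
    if kind not in _NOISE_KINDS:
        raise ValueError(f"unknown noise kind {kind!r}; use one of {_NOISE_KINDS}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    img = np.asarray(image, dtype=np.float64)
    if kind == "gaussian":
        out = img + rng.normal(0.0, config.gaussian_sigma, img.shape)
    elif kind == "speckle":
        out = img * (1.0 + rng.normal(0.0, np.sqrt(config.speckle_variance), img.shape))
    else:  # salt_pepper: sp_amount of pixels forced to 0 or 255, half each in expectation
        out = img.copy()
        hit = rng.random(img.shape) < config.sp_amount
        salt = rng.random(img.shape) < 0.5
        out[hit & salt] = 255.0
        out[hit & ~salt] = 0.0
    return np.clip(out, 0.0, 255.0)


def elastic_transform(image: np.ndarray, mask: np.ndarray, config: AugmentConfig,
                      rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Apply one shared smoothed random displacement field to image and mask."""
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} differ")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    shape = image.shape
    dy = gaussian_filter(rng.uniform(-1, 1, shape), config.elastic_sigma) * config.elastic_alpha
    dx = gaussian_filter(rng.uniform(-1, 1, shape), config.elastic_sigma) * config.elastic_alpha
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    coords = np.array([yy + dy, xx + dx])
    warped = map_coordinates(np.asarray(image, dtype=np.float64), coords,
                             order=1, mode="reflect")
    warped_mask = map_coordinates(np.asarray(mask, dtype=np.uint8), coords,
                                  order=0, mode="reflect").astype(mask.dtype)
    return warped, warped_mask


def random_contrast(image: np.ndarray, config: AugmentConfig,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Rescale contrast about the image mean by a random factor; clip to [0, 255]."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    factor = rng.uniform(*config.contrast_factor_range)
    img = np.asarray(image, dtype=np.float64)
    mean = img.mean()
    return np.clip(mean + factor * (img - mean), 0.0, 255.0)


def augment_pair(image: np.ndarray, mask: np.ndarray, config: AugmentConfig,
                 rng: np.random.Generator | None = None,
                 record: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Full chain flip -> noise -> elastic -> contrast, each firing with ``p_apply``.

    Fully reproducible from ``(inputs, config, rng-or-seed)``.  When noise
    fires, exactly one kind is chosen uniformly from ``config.noise_kinds``.
    If ``record`` (a dict) is given it is filled with which transforms fired
    (``flip``/``elastic``: bool, ``noise``: kind or None, ``contrast``: bool)
    so runs can be audited.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    image = np.asarray(image, dtype=np.float64)
    fired = {"flip": False, "noise": None, "elastic": False, "contrast": False}
    if rng.random() < config.p_apply:
        fired["flip"] = True
        image, mask = horizontal_flip(image, mask)
    if rng.random() < config.p_apply:
        kind = config.noise_kinds[rng.integers(len(config.noise_kinds))]
        fired["noise"] = kind
        image = add_noise(image, kind, config, rng)
    if rng.random() < config.p_apply:
        fired["elastic"] = True
        image, mask = elastic_transform(image, mask, config, rng)
    if rng.random() < config.p_apply:
        fired["contrast"] = True
        image = random_contrast(image, config, rng)
    if record is not None:
        record.update(fired)
    return image, mask
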