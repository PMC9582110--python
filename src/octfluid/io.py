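"""Readers/writers for OCT cubes, masks and geometry metadata.

Cubes are exchanged either as directories of 2D grayscale slice images
(PNG/TIFF, lexicographic order = B-scan order) or as single 3D volume files
(MetaImage ``.mha``/``.mhd`` or NIfTI ``.nii``/``.nii.gz``).  In memory every
volume is a numpy array indexed ``(z, y, x)`` = (slice, row, column).

Two native swept-source acquisition geometries are recognised as presets:

- ``OCT256``: 256 slices, each 512 px wide x 992 px tall
- ``OCT320``: 320 slices, each 320 px wide x 992 px tall
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

_SLICE_EXTENSIONS = (".png", ".tif", ".tiff", ".bmp")
_VOLUME_EXTENSIONS = (".mha", ".mhd", ".nii", ".nii.gz")


@dataclass(frozen=True)
class CubeGeometry:
    """Cube shape ``(n_slices, height, width)`` plus a preset tag."""

    n_slices: int
    height: int
    width: int
    preset: str = "custom"

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_slices, self.height, self.width)


#: The two native acquisition geometries, keyed by preset tag.
PRESETS: dict[str, CubeGeometry] = {
    "OCT256": CubeGeometry(256, 992, 512, "OCT256"),
    "OCT320": CubeGeometry(320, 992, 320, "OCT320"),
}


def infer_geometry(volume: np.ndarray) -> CubeGeometry:
    """Return the :class:`CubeGeometry` of ``volume``, preset-tagged if known."""
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) volume, got shape {volume.shape}")
    shape = tuple(volume.shape)
    for geom in PRESETS.values():
        if geom.shape == shape:
            return geom
    return CubeGeometry(*shape)


def _list_slice_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in _SLICE_EXTENSIONS and p.is_file()
    )
    if not files:
        raise ValueError(f"no slice images found in {directory}")
    return files


def _read_stack(directory: Path) -> np.ndarray:
    files = _list_slice_files(directory)
    slices = []
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 3:  # collapse RGB(A) written by other tools
            img = img[..., :3].mean(axis=-1)
        slices.append(img)
    shapes = [s.shape for s in slices]
    ref = max(set(shapes), key=shapes.count)
    offenders = [f.name for f, s in zip(files, shapes) if s != ref]
    if offenders:
        raise ValueError(
            f"inconsistent slice sizes in {directory}: expected {ref}, "
            f"offending files: {', '.join(offenders)}"
        )
    return np.stack(slices, axis=0)


def read_cube(path: str | Path) -> np.ndarray:
    """Read an OCT cube from a slice directory or a 3D volume file.

    Returns a ``(z, y, x)`` array with intensities in [0, 255]; use
    :func:`infer_geometry` to recover the preset tag.
    """
    path = Path(path)
    if path.is_dir():
        vol = _read_stack(path)
    elif "".join(path.suffixes[-2:]) == ".nii.gz" or path.suffix in (".nii",):
        vol = np.asarray(nib.load(path).dataobj)
        vol = np.transpose(vol, (2, 1, 0))  # nibabel stores (x, y, z)
    elif path.suffix in (".mha", ".mhd"):
        vol = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    else:
        raise ValueError(f"unsupported cube source: {path}")
    if vol.ndim != 3:
        raise ValueError(f"{path} does not contain a 3D volume (shape {vol.shape})")
    geom = infer_geometry(vol)
    if geom.preset != "custom":
        logger.info("read %s: recognised preset %s", path, geom.preset)
    return vol


def write_cube(volume: np.ndarray, path: str | Path, format: str = "png_stack") -> Path:
    """Write ``volume`` losslessly.

    ``format`` is one of ``png_stack`` (a directory of zero-padded-index PNG
    slices; 8-bit or 16-bit), ``mha`` or ``nifti``.
    """
    path = Path(path)
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    if format == "png_stack":
        path.mkdir(parents=True, exist_ok=True)
        dtype = np.uint16 if volume.max(initial=0) > 255 else np.uint8
        ndigits = max(4, len(str(volume.shape[0] - 1)))
        for i, sl in enumerate(volume.astype(dtype)):
            iio.imwrite(path / f"slice_{i:0{ndigits}d}.png", sl)
    elif format == "mha":
        path.parent.mkdir(parents=True, exist_ok=True)
        sitk.WriteImage(sitk.GetImageFromArray(volume), str(path))
    elif format == "nifti":
        path.parent.mkdir(parents=True, exist_ok=True)
        img = nib.Nifti1Image(np.transpose(volume, (2, 1, 0)), affine=np.eye(4))
        nib.save(img, path)
    else:
        raise ValueError(f"unknown cube format {format!r}; use png_stack, mha or nifti")
    return path


def read_mask(path: str | Path, threshold: int = 128) -> np.ndarray:
    """Read a binary fluid mask (0 = background, 255 = fluid).

    Values other than {0, 255} (e.g. anti-aliased edges) are tolerated and
    binarized at ``threshold``; the number of such pixels is logged.
    """
    raw = read_cube(path)
    nonbinary = int(np.count_nonzero((raw != 0) & (raw != 255)))
    if nonbinary:
        logger.warning(
            "mask %s contains %d non-binary pixels; binarizing at %d",
            path, nonbinary, threshold,
        )
    return np.asarray(raw) >= threshold


def write_mask(mask: np.ndarray, path: str | Path, format: str = "png_stack") -> Path:
    """Write a binary mask as a 0/255 stack (or volume file)."""
    return write_cube(np.asarray(mask, dtype=bool).astype(np.uint8) * 255, path, format)
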