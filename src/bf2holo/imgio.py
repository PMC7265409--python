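"""Image reading/writing with [0, 1] normalization, plus manifest helpers.

Supported formats are single-channel TIFF (8/16-bit) and PNG.  Intensities
are normalized to [0, 1] on read by dividing by the dtype's full scale; the
original bit depth is recorded and writing inverts the normalization.
Multi-channel images are collapsed to luminance with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["ImageMeta", "read_image", "write_image"]

_FULL_SCALE = {np.dtype("uint8"): 255.0, np.dtype("uint16"): 65535.0}


@dataclass(frozen=True)
class ImageMeta:
    """Provenance of a read image: source path, dtype and normalization scale."""

    path: str
    dtype: str
    scale: float  # raw = normalized * scale
    converted_to_gray: bool = False


def read_image(path: str | Path) -> tuple[np.ndarray, ImageMeta]:
    """Read a TIFF/PNG image, normalize to [0, 1], return (array, metadata)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        raw = tifffile.imread(str(path))
    else:
        raw = iio.imread(str(path))
    raw = np.asarray(raw)
    converted = False
    if raw.ndim == 3:
        warnings.warn(f"{path.name}: multi-channel image converted to luminance")
        raw = raw.astype(np.float64).mean(axis=-1 if raw.shape[-1] in (3, 4) else 0)
        converted = True
    if raw.ndim != 2:
        raise IOError(f"{path.name}: expected a 2D image, got shape {raw.shape}")
    scale = _FULL_SCALE.get(raw.dtype, None)
    if scale is None:
        # float input: assume already normalized
        values = np.clip(raw.astype(np.float64), 0.0, 1.0)
        meta = ImageMeta(str(path), str(raw.dtype), 1.0, converted)
    else:
        values = raw.astype(np.float64) / scale
        meta = ImageMeta(str(path), str(raw.dtype), scale, converted)
    return values, meta


def write_image(image: np.ndarray, path: str | Path, dtype: str = "uint16") -> None:
    """Write a [0, 1] image as TIFF or PNG at the requested bit depth."""
    path = Path(path)
    image = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    np_dtype = np.dtype(dtype)
    if np_dtype not in _FULL_SCALE:
        raise ValueError(f"unsupported output dtype {dtype}; use uint8 or uint16")
    raw = np.round(image * _FULL_SCALE[np_dtype]).astype(np_dtype)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), raw)
    elif suffix == ".png":
        iio.imwrite(str(path), raw)
    else:
        raise ValueError(f"unsupported image format {suffix}; use .tif or .png")
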