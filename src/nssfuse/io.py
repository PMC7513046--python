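"""Image reading and writing.

Images are loaded as float arrays normalised to [0, 1] by their bit depth
(no rescaling to the data range, no silent clipping); grayscale files stay
single-channel.  Writing quantises to the requested bit depth and is atomic
(temp file + rename).  Supported formats: PNG, TIFF, PGM/PPM.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["LoadedImage", "InputError", "read_image", "write_image"]

_SUPPORTED = {".png", ".tif", ".tiff", ".pgm", ".ppm"}


class InputError(ValueError):
    """A problem with an input file; carries the offending path."""


@dataclass
class LoadedImage:
    pixels: np.ndarray  # float in [0, 1]; (H, W) or (H, W, 3)
    bit_depth: int
    channels: int
    path: str


def read_image(path: str | Path) -> LoadedImage:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix.lower() not in _SUPPORTED:
        raise InputError(f"unsupported image format: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # corrupt or unreadable
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[..., :3]
    if raw.ndim not in (2, 3):
        raise InputError(f"unsupported image layout {raw.shape} in {path}")
    if np.issubdtype(raw.dtype, np.integer):
        bit_depth = 16 if raw.dtype.itemsize >= 2 else 8
        pixels = raw.astype(float) / (2**bit_depth - 1)
    else:
        bit_depth = 32
        pixels = raw.astype(float)
    channels = 1 if pixels.ndim == 2 else pixels.shape[2]
    return LoadedImage(
        pixels=pixels, bit_depth=bit_depth, channels=channels, path=str(path)
    )


def write_image(img: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Quantise to ``bit_depth`` and write atomically; ``img`` must be in [0, 1]."""
    img = np.asarray(img, dtype=float)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("pixel values outside [0, 1]; clip before writing")
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    scale = 2**bit_depth - 1
    quant = np.round(img * scale).astype(np.uint8 if bit_depth == 8 else np.uint16)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=path.suffix)
    os.close(fd)
    try:
        iio.imwrite(tmp, quant)
        os.replace(tmp, path)
    except Exception:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
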