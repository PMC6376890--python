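"""Grayscale image I/O: PNG and TIFF, integer or float.

8- and 16-bit integer images are mapped to [0, 1] by dividing by their
type's peak (255 or 65535); float TIFF data is passed through untouched
with peak 1.0.  Writing inverts the mapping.  Color inputs are rejected —
the pipeline is single-channel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from wavedn.pipeline import Image2D

__all__ = ["read_image", "write_image"]

_PNG_EXT = {".png"}
_TIFF_EXT = {".tif", ".tiff"}


def read_image(path) -> Image2D:
    """Read a grayscale PNG or TIFF into an Image2D on [0, 1]."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _TIFF_EXT:
        arr = tifffile.imread(path)
    elif ext in _PNG_EXT:
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {ext!r}; use PNG or TIFF")
    if arr.ndim == 3:
        raise ValueError(
            f"{path.name} has {arr.shape[-1]} channels; convert to single-channel grayscale first"
        )
    if arr.dtype == np.uint8:
        return Image2D(pixels=arr / 255.0)
    if arr.dtype == np.uint16:
        return Image2D(pixels=arr / 65535.0)
    if np.issubdtype(arr.dtype, np.floating):
        return Image2D(pixels=np.asarray(arr, dtype=float))
    raise ValueError(f"unsupported pixel dtype {arr.dtype} in {path.name}")


def write_image(img: Image2D, path, bitdepth: int | None = None) -> None:
    """Write an Image2D to PNG (8/16-bit) or TIFF (8/16-bit or float32).

    ``bitdepth`` is 8, 16, or None; None means 8-bit for PNG and float32
    for TIFF.  Pixels are scaled from [0, peak] to the integer range with
    rounding; float TIFF output is written as-is on [0, peak].
    """
    path = Path(path)
    ext = path.suffix.lower()
    unit = np.clip(img.pixels / img.peak, 0.0, 1.0)
    if ext in _PNG_EXT:
        depth = 8 if bitdepth is None else bitdepth
        if depth == 8:
            iio.imwrite(path, np.round(unit * 255).astype(np.uint8))
        elif depth == 16:
            iio.imwrite(path, np.round(unit * 65535).astype(np.uint16))
        else:
            raise ValueError(f"PNG bit depth must be 8 or 16, got {bitdepth!r}")
    elif ext in _TIFF_EXT:
        if bitdepth is None:
            tifffile.imwrite(path, img.pixels.astype(np.float32))
        elif bitdepth == 8:
            tifffile.imwrite(path, np.round(unit * 255).astype(np.uint8))
        elif bitdepth == 16:
            tifffile.imwrite(path, np.round(unit * 65535).astype(np.uint16))
        else:
            raise ValueError(f"TIFF bit depth must be 8, 16 or None (float), got {bitdepth!r}")
    else:
        raise ValueError(f"unsupported image format {ext!r}; use PNG or TIFF")
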