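"""Reading and writing 8-bit greyscale images and binary masks.

Images travel as single-channel 8-bit TIFF or PNG; masks as 8-bit binary
PNG (0 = background, 255 = ooplasm).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image


class ImageIOError(ValueError):
    """Raised for unreadable or non-conforming image files."""


def write_image(path, image) -> None:
    """Write an 8-bit greyscale image as TIFF (.tif/.tiff) or PNG (.png)."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8 or arr.ndim != 2:
        raise ImageIOError("expected a 2-D uint8 image")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        Image.fromarray(arr, mode="L").save(path)
    else:
        raise ImageIOError(f"unsupported image format {path.suffix!r}")


def read_image(path) -> np.ndarray:
    """Read a single-channel 8-bit image as a 2-D uint8 array."""
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such image: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ImageIOError(f"{path} is not single-channel")
    if arr.dtype != np.uint8:
        raise ImageIOError(f"{path} is not 8-bit")
    return arr


def write_mask(path, mask) -> None:
    """Write a boolean mask as an 8-bit binary PNG (255 inside)."""
    arr = np.asarray(mask, dtype=bool)
    write_image(path, (arr * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG back to a boolean array."""
    arr = read_image(path)
    values = np.unique(arr)
    if not set(values.tolist()) <= {0, 255}:
        raise ImageIOError(f"{path} is not a binary 0/255 mask")
    return arr > 0
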