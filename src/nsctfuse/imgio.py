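"""Reading and writing 8/16-bit PNG/TIFF images on the internal [0, 1] scale."""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image"]


def read_image(path) -> np.ndarray:
    """Load a PNG/TIFF image as float in [0, 1].

    Grayscale files become 2-D arrays; RGB stays H x W x 3 (an alpha
    channel, if present, is dropped).  8-bit codes are divided by 255,
    16-bit by 65535.

    Raises
    ------
    OSError
        If the file is missing or not a supported image.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"image not found: {path}")
    try:
        data = iio.imread(path)
    except Exception as exc:  # imageio raises assorted types
        raise OSError(f"could not read image {path}: {exc}") from exc
    if data.dtype == np.uint8:
        scale = 255.0
    elif data.dtype == np.uint16:
        scale = 65535.0
    else:
        raise OSError(
            f"unsupported bit depth {data.dtype} in {path}; expected 8- or "
            "16-bit integer codes"
        )
    img = data.astype(float) / scale
    if img.ndim == 3:
        if img.shape[2] == 4:
            img = img[..., :3]
        elif img.shape[2] != 3:
            raise OSError(f"unsupported channel count in {path}")
    elif img.ndim != 2:
        raise OSError(f"unsupported image dimensionality in {path}")
    return img


def write_image(path, img) -> None:
    """Write a [0, 1] float image as 8-bit PNG/TIFF (round(255 * clip))."""
    img = np.asarray(img, dtype=float)
    codes = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, codes)
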