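"""Image and mask I/O with a strict 8-bit RGB / 0-255 binary-mask contract."""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "read_mask", "write_mask", "MaskValueError"]

log = logging.getLogger("ki67area")


class MaskValueError(ValueError):
    """Mask file contains values other than 0 and 255."""


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as 8-bit RGB (H, W, 3).

    16-bit input is rescaled to 8 bits with a logged warning; an alpha
    channel, if present, is dropped; grayscale input is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint16:
        log.warning("%s: 16-bit input rescaled to 8-bit", path)
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8 or image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an 8-bit RGB image")
    iio.imwrite(Path(path), image)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel 0/255 PNG mask as a boolean array (255 = in)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel mask, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 255))):
        raise MaskValueError(f"{path}: mask values must be 0 or 255, found {vals[:10]}")
    return arr == 255


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D mask")
    iio.imwrite(Path(path), np.where(mask.astype(bool), 255, 0).astype(np.uint8))
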