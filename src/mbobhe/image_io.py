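"""Grayscale image container and file I/O.

The package works on single-channel images with integer gray levels in
``[0, L-1]`` (``L = 256`` by default).  All quality metrics operate on the
normalized ``[0, 1]`` view obtained with :func:`normalize`, so the stability
constant used by the metrics has a scale-free meaning regardless of ``L``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["GrayImage", "read_image", "write_image", "normalize"]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of integer gray levels in ``[0, levels - 1]``.

    Parameters
    ----------
    pixels : ndarray
        2-D integer array, row-major, ``(row, column)`` indexed, 0-based.
    levels : int
        Number of gray levels ``L`` (256 for ordinary 8-bit images).
    """

    pixels: np.ndarray = field(repr=False)
    levels: int = 256

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"pixels must have an integer dtype, got {arr.dtype}")
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if arr.min() < 0 or arr.max() > self.levels - 1:
            raise ValueError(
                f"pixel values must lie in [0, {self.levels - 1}], "
                f"found range [{arr.min()}, {arr.max()}]"
            )
        object.__setattr__(self, "pixels", np.ascontiguousarray(arr, dtype=np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def size(self) -> int:
        return self.pixels.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.levels == other.levels and np.array_equal(self.pixels, other.pixels)


def read_image(path, levels: int = 256) -> GrayImage:
    """Read a PNG/TIFF/PGM file as a :class:`GrayImage`.

    Multi-channel inputs are converted to grayscale by averaging the channels
    (many radiograph exports are RGB-encoded grayscale); the conversion is
    logged.  For ``levels != 256`` the 8-bit values are rescaled by
    ``v * (levels - 1) / 255`` with round-half-up.
    """
    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError(f"{path}: zero-sized image")
    if arr.ndim == 3:
        logger.warning("%s: multi-channel image, converting by channel mean", path)
        arr = arr.astype(np.float64).mean(axis=2)
    elif arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    arr = arr.astype(np.float64)
    src_max = 255.0  # 8-bit source assumed for the supported formats
    if levels != 256:
        arr = arr * (levels - 1) / src_max
    arr = np.floor(arr + 0.5)  # round half up
    arr = np.clip(arr, 0, levels - 1).astype(np.int64)
    return GrayImage(arr, levels)


def write_image(img: GrayImage, path) -> None:
    """Write a :class:`GrayImage` to PNG/TIFF/PGM (8-bit).

    Only ``levels == 256`` images map losslessly onto the 8-bit formats; other
    level counts are rejected so a read/write round trip is always exact.
    """
    if img.levels != 256:
        raise ValueError(
            f"only 256-level images can be written as 8-bit files (got levels={img.levels}); "
            "rescale explicitly first"
        )
    iio.imwrite(path, img.pixels.astype(np.uint8))


def normalize(img: GrayImage) -> np.ndarray:
    """The unit-interval view ``v / (levels - 1)`` used by all metrics."""
    return img.pixels / (img.levels - 1)
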