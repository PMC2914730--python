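"""Grayscale image container and conversion helpers.

All morphological operators in this package work on plain 2-D float
arrays; :class:`GrayImage` is the thin carrier used at the I/O boundary,
recording the bit depth so results can be quantized back to the range
of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrayImage", "as_float", "quantize"]


@dataclass
class GrayImage:
    """A single-channel raster image.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities. Stored as given; use :func:`as_float`
        for computation.
    bit_depth : int
        8 or 16; the nominal range is ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("image intensities must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    def to_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def quantized(self, values: np.ndarray) -> "GrayImage":
        """Return *values* rounded and clipped back to this image's depth."""
        return GrayImage(quantize(values, self.bit_depth), self.bit_depth)


def as_float(image) -> np.ndarray:
    """Coerce a GrayImage or array-like to a 2-D float64 array."""
    if isinstance(image, GrayImage):
        return image.to_float()
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 1:  # tolerate 1-D profiles in examples/tests
        arr = arr[None, :]
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale array")
    return arr


def quantize(values: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Round half up and clip to the integer range of *bit_depth*.

    Internal arithmetic is floating point throughout the package; this is
    the single place results are brought back to gray levels.
    """
    hi = 2**bit_depth - 1
    q = np.floor(np.asarray(values, dtype=np.float64) + 0.5)
    q = np.clip(q, 0, hi)
    return q.astype(np.uint8 if bit_depth == 8 else np.uint16)
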