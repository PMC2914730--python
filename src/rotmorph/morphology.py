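"""Classical flat grayscale morphology.

Erosion, dilation, opening, closing, top-hat, geodesic reconstruction and
the h-dome transform, with flat (binary) structuring elements. These are
the building blocks of rotational morphological processing and the
conventional baselines it is compared against.

Border handling: images are implicitly extended by edge replication, so a
flat structuring element never introduces values outside the image's local
range and the top-hat of a constant image is exactly zero everywhere,
including at the frame border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import reconstruction as _sk_reconstruction

from .image import as_float

__all__ = [
    "StructuringElement",
    "make_line_se",
    "make_disk_se",
    "make_square_se",
    "erode",
    "dilate",
    "open_gray",
    "close_gray",
    "tophat",
    "geodesic_reconstruct",
    "h_dome",
]

_BORDER = "nearest"  # edge replication


@dataclass(frozen=True)
class StructuringElement:
    """A flat binary structuring element with a central origin.

    ``mask`` is a 2-D boolean footprint with odd side lengths, so the
    origin sits at the geometric center. Weighted ("ball") elements are
    deliberately not supported: all operators here are flat.
    """

    shape: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or not m.any():
            raise ValueError("structuring element mask must be 2-D and non-empty")
        if m.shape[0] % 2 == 0 or m.shape[1] % 2 == 0:
            raise ValueError("structuring element sides must be odd")
        object.__setattr__(self, "mask", m)

    @property
    def origin(self) -> tuple[int, int]:
        return (self.mask.shape[0] // 2, self.mask.shape[1] // 2)


def _odd_positive(value: int, name: str) -> int:
    value = int(value)
    if value < 1 or value % 2 == 0:
        raise ValueError(f"{name} must be a positive odd integer, got {value}")
    return value


def make_line_se(length: int) -> StructuringElement:
    """Horizontal straight line-segment element of ``length x 1`` pixels.

    The 1-pixel width is the point of the whole method: it sets the
    minimum separation at which two adjacent spots can still be told
    apart. ``length=1`` is the morphological identity.
    """
    length = _odd_positive(length, "length")
    return StructuringElement("line", np.ones((1, length), dtype=bool))


def make_disk_se(diameter: int) -> StructuringElement:
    """Flat disk: pixel (i, j) included iff its center lies within
    radius ``(diameter - 1) / 2`` of the origin."""
    diameter = _odd_positive(diameter, "diameter")
    r = (diameter - 1) // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return StructuringElement("disk", yy * yy + xx * xx <= r * r)


def make_square_se(side: int) -> StructuringElement:
    side = _odd_positive(side, "side")
    return StructuringElement("square", np.ones((side, side), dtype=bool))


def _footprint(se) -> np.ndarray:
    if isinstance(se, StructuringElement):
        return se.mask
    return np.asarray(se, dtype=bool)


def erode(f, se) -> np.ndarray:
    """Flat grayscale erosion: local minimum over the footprint."""
    return ndi.grey_erosion(as_float(f), footprint=_footprint(se), mode=_BORDER)


def dilate(f, se) -> np.ndarray:
    """Flat grayscale dilation: local maximum over the reflected footprint."""
    return ndi.grey_dilation(as_float(f), footprint=_footprint(se), mode=_BORDER)


def open_gray(f, se) -> np.ndarray:
    """Opening = erosion followed by dilation. Anti-extensive, idempotent,
    increasing; removes bright structures the element cannot fit inside."""
    return dilate(erode(f, se), se)


def close_gray(f, se) -> np.ndarray:
    """Closing = dilation followed by erosion."""
    return erode(dilate(f, se), se)


def tophat(f, se) -> np.ndarray:
    """Top-hat transform: ``f - opening(f)``; non-negative everywhere."""
    f = as_float(f)
    return f - open_gray(f, se)


def _connectivity_footprint(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndi.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


def geodesic_reconstruct(marker, mask, connectivity: int = 8) -> np.ndarray:
    """Grayscale reconstruction by dilation of *marker* under *mask*.

    Iterates geodesic dilation (3x3 neighbourhood, then pixelwise minimum
    with the mask) to the exact fixed point. Requires ``marker <= mask``
    pixelwise. The result lies between marker and mask.
    """
    marker = as_float(marker)
    mask = as_float(mask)
    if marker.shape != mask.shape:
        raise ValueError("marker and mask must have the same shape")
    if np.any(marker > mask + 1e-12):
        raise ValueError("marker must not exceed mask anywhere")
    # hybrid-queue algorithm; identical fixed point to the iterative definition
    return _sk_reconstruction(
        np.minimum(marker, mask),
        mask,
        method="dilation",
        footprint=_connectivity_footprint(connectivity),
    )


def h_dome(f, h: float, connectivity: int = 8) -> np.ndarray:
    """h-dome transform: ``f - reconstruct(f - h, f)``.

    Extracts bright domes of height at most *h*; the result is bounded
    to ``[0, h]``. ``h`` must be strictly positive.
    """
    if h <= 0:
        raise ValueError(f"h must be > 0, got {h}")
    f = as_float(f)
    return f - geodesic_reconstruct(f - h, f, connectivity=connectivity)
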