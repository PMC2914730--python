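"""Shared fixtures and independent brute-force oracles.

The oracles implement flat morphology straight from its definition
(double loops over the footprint, edge replication at the border) and are
kept deliberately independent of the package implementation.
"""

import numpy as np
import pytest


def brute_local_extremum(f, mask, op):
    f = np.asarray(f, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    h, w = f.shape
    mh, mw = mask.shape
    oy, ox = mh // 2, mw // 2
    out = np.empty_like(f)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(mh):
                for dj in range(mw):
                    if mask[di, dj]:
                        y = min(max(i + di - oy, 0), h - 1)
                        x = min(max(j + dj - ox, 0), w - 1)
                        vals.append(f[y, x])
            out[i, j] = op(vals)
    return out


def brute_erode(f, mask):
    return brute_local_extremum(f, mask, min)


def brute_dilate(f, mask):
    return brute_local_extremum(f, mask, max)


def brute_open(f, mask):
    return brute_dilate(brute_erode(f, mask), mask)


def brute_reconstruct(marker, mask_img):
    """Iterative geodesic dilation (3x3, 8-connected) to the fixed point."""
    marker = np.asarray(marker, dtype=float).copy()
    mask_img = np.asarray(mask_img, dtype=float)
    footprint = np.ones((3, 3), dtype=bool)
    while True:
        grown = np.minimum(brute_dilate(marker, footprint), mask_img)
        if np.array_equal(grown, marker):
            return grown
        marker = grown


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_u8(rng):
    """A batch of small random 8-bit images for property checks."""
    return [rng.integers(0, 256, size=(16, 16)).astype(float) for _ in range(3)]
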