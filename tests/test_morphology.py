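"""Classical morphology: structuring elements, basic operators,
reconstruction and h-dome, checked against brute-force oracles and
their defining algebraic properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from conftest import brute_dilate, brute_erode, brute_open, brute_reconstruct
from rotmorph import (
    StructuringElement,
    close_gray,
    dilate,
    erode,
    geodesic_reconstruct,
    h_dome,
    make_disk_se,
    make_line_se,
    make_square_se,
    open_gray,
    tophat,
)

u8_images = hnp.arrays(
    dtype=np.int64,
    shape=st.tuples(st.integers(4, 12), st.integers(4, 12)),
    elements=st.integers(0, 255),
).map(lambda a: a.astype(float))


# --- structuring elements ---------------------------------------------------


@pytest.mark.parametrize("length", [1, 11, 13])
def test_line_se_shape_and_origin(length):
    se = make_line_se(length)
    assert se.mask.shape == (1, length)
    assert se.mask.all()
    assert se.origin == (0, length // 2)


@pytest.mark.parametrize("bad", [0, -3, 2, 12])
def test_line_and_disk_reject_even_or_nonpositive(bad):
    with pytest.raises(ValueError):
        make_line_se(bad)
    with pytest.raises(ValueError):
        make_disk_se(bad)


def test_disk_se_footprints():
    assert make_disk_se(1).mask.sum() == 1
    # diameter 3: pixels with center distance <= 1 -> plus shape, 5 pixels
    plus = make_disk_se(3).mask
    assert plus.sum() == 5
    assert plus[1, :].all() and plus[:, 1].all()
    # general criterion on the cleanup disk
    d13 = make_disk_se(13).mask
    yy, xx = np.mgrid[-6:7, -6:7]
    np.testing.assert_array_equal(d13, yy**2 + xx**2 <= 36)


def test_structuring_element_validation():
    with pytest.raises(ValueError):
        StructuringElement("line", np.zeros((1, 3), dtype=bool))
    with pytest.raises(ValueError):
        StructuringElement("square", np.ones((2, 2), dtype=bool))
    assert make_square_se(3).mask.sum() == 9


# --- erosion / dilation / opening ------------------------------------------


def test_constant_image_is_fixed_point():
    c = np.full((7, 9), 42.0)
    for se in (make_line_se(5), make_disk_se(5)):
        np.testing.assert_array_equal(erode(c, se), c)
        np.testing.assert_array_equal(dilate(c, se), c)
        np.testing.assert_array_equal(open_gray(c, se), c)
        np.testing.assert_array_equal(close_gray(c, se), c)
        np.testing.assert_array_equal(tophat(c, se), np.zeros_like(c))


def test_single_bright_pixel_eroded_away():
    f = np.zeros((5, 7))
    f[2, 3] = 255
    assert erode(f, make_line_se(3)).max() == 0


def test_profile_examples_match_brute_force():
    profile = np.array([[0.0, 0, 5, 5, 5, 0, 0]])
    np.testing.assert_array_equal(
        dilate(profile, make_line_se(3)), np.array([[0.0, 5, 5, 5, 5, 5, 0]])
    )
    # plateau of width 3 removed by a length-5 line, kept by a length-3 line
    np.testing.assert_array_equal(open_gray(profile, make_line_se(5)), np.zeros((1, 7)))
    np.testing.assert_array_equal(open_gray(profile, make_line_se(3)), profile)
    np.testing.assert_array_equal(tophat(profile, make_line_se(5)), profile)
    for se in (make_line_se(5), make_line_se(3)):
        np.testing.assert_array_equal(open_gray(profile, se), brute_open(profile, se.mask))


def test_identity_structuring_element():
    f = np.arange(20.0).reshape(4, 5)
    np.testing.assert_array_equal(open_gray(f, make_line_se(1)), f)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(u8_images, st.sampled_from([3, 5]))
def test_erode_dilate_match_brute_force(f, size):
    for se in (make_line_se(size), make_disk_se(size)):
        np.testing.assert_array_equal(erode(f, se), brute_erode(f, se.mask))
        np.testing.assert_array_equal(dilate(f, se), brute_dilate(f, se.mask))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(u8_images)
def test_duality_and_opening_properties(f):
    se = make_disk_se(3)
    # duality for a symmetric element
    np.testing.assert_array_equal(erode(f, se), -dilate(-f, se))
    opened = open_gray(f, se)
    # anti-extensive and idempotent
    assert (opened <= f + 1e-9).all()
    np.testing.assert_allclose(open_gray(opened, se), opened)
    # increasing
    g = f + 7.0
    assert (open_gray(g, se) >= opened - 1e-9).all()
    # top-hat is non-negative
    assert (tophat(f, se) >= -1e-9).all()


def test_overlapped_spots_not_separated_by_disk_tophat():
    """Two Gaussian spots closer than the disk diameter stay one blob in
    the conventional top-hat residual."""
    yy, xx = np.mgrid[0:48, 0:48]
    f = np.zeros((48, 48))
    for cx in (20, 28):
        f += 255 * np.exp(-((yy - 24) ** 2 + (xx - cx) ** 2) / 8.0)
    f = np.rint(np.clip(f, 0, 255))
    residual = np.rint(tophat(f, make_disk_se(11)))
    from scipy import ndimage as ndi

    _, n = ndi.label(residual > 0, structure=np.ones((3, 3)))
    assert n == 1


# --- reconstruction and h-dome ----------------------------------------------


def test_reconstruction_fixed_points():
    f = np.array([[3.0, 1, 4], [1, 5, 9], [2, 6, 5]])
    np.testing.assert_array_equal(geodesic_reconstruct(f, f), f)
    np.testing.assert_array_equal(
        geodesic_reconstruct(np.zeros_like(f), f), np.zeros_like(f)
    )


def test_reconstruction_two_peaks_matches_iterative_oracle():
    # two peaks (100 and 50) separated by a zero valley; marker = mask - 10
    mask = np.array([[0.0, 80, 100, 80, 0, 40, 50, 40, 0]])
    marker = mask - 10
    expected = brute_reconstruct(marker, mask)
    result = geodesic_reconstruct(marker, mask)
    np.testing.assert_array_equal(result, expected)
    # each peak rebuilt to its own height minus h, clipped by the valley
    assert result[0, 2] == 90 and result[0, 6] == 40
    assert (result >= marker).all() and (result <= mask).all()


def test_reconstruction_rejects_marker_above_mask():
    mask = np.zeros((3, 3))
    with pytest.raises(ValueError):
        geodesic_reconstruct(mask + 1, mask)


def test_hdome_constant_and_bounds(rng):
    # a constant image is a single plateau: the reconstruction of f - h
    # cannot climb anywhere, so the dome height is exactly h
    c = np.full((6, 6), 100.0)
    np.testing.assert_array_equal(h_dome(c, 30), np.full_like(c, 30.0))
    f = rng.integers(0, 256, (16, 16)).astype(float)
    d = h_dome(f, 25)
    assert (d >= -1e-9).all() and (d <= 25 + 1e-9).all()
    with pytest.raises(ValueError):
        h_dome(f, 0)


def test_hdome_isolated_peak_capped_at_h():
    yy, xx = np.mgrid[0:33, 0:33]
    f = np.rint(200 * np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / 18.0))
    d = h_dome(f, 50)
    assert d.max() == pytest.approx(50, abs=1e-9)
    assert d[16, 16] == pytest.approx(50, abs=1e-9)
    np.testing.assert_array_equal(
        d, f - brute_reconstruct(f - 50, f)
    )
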