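"""Preprocessing: registration, canonical framing, renormalisation, contrast."""

import numpy as np
import pytest
from scipy.signal import convolve2d

from trajfuse.datasets.study import render_frame
from trajfuse.prep import (BlankImageError, PrepConfig, REFERENCE_ANGLE,
                           _foreground_mask, logistic_contrast, prep_pipeline,
                           register, renormalize_local, resize_to_canonical)


@pytest.fixture(scope="module")
def symmetric_frame():
    # t=0: pure centred ellipse, centroid at the grid centre
    return render_frame(0.0, 64)["nuclei"]


class TestRegister:
    def test_identity_when_already_at_reference(self, symmetric_frame):
        out = register(symmetric_frame, REFERENCE_ANGLE)
        np.testing.assert_allclose(out, symmetric_frame, atol=1e-10)

    def test_half_turn_matches_index_reversal_oracle(self, symmetric_frame):
        # annotated at reference + pi: output must equal a 180-degree
        # rotation, which for a centred grid is exact index reversal
        out = register(symmetric_frame, REFERENCE_ANGLE + np.pi)
        np.testing.assert_allclose(out, symmetric_frame[::-1, ::-1], atol=1e-10)

    def test_quarter_turn_matches_rot90_oracle(self, symmetric_frame):
        out = register(symmetric_frame, 0.0)
        oracle = min(np.abs(out - np.rot90(symmetric_frame, 1)).max(),
                     np.abs(out - np.rot90(symmetric_frame, -1)).max())
        assert oracle < 1e-10

    def test_ventral_indentation_lands_at_reference(self):
        # a late-stage embryo rotated away and annotated accordingly
        img = render_frame(0.9, 64)["nuclei"]
        from trajfuse.prep import _rotate_about_center
        rot = _rotate_about_center(img, np.pi / 3)
        out = register(rot, REFERENCE_ANGLE + np.pi / 3)
        mask = _foreground_mask(out)
        r, c = np.nonzero(mask)
        # the indentation thins the bottom: foreground extends further
        # above the centroid than below it
        assert (r.mean() - r.min()) > (r.max() - r.mean())

    def test_blank_image_rejected(self):
        with pytest.raises(BlankImageError):
            register(np.zeros((32, 32)))


class TestResize:
    def test_canonical_shape_and_occupancy(self):
        yy, xx = np.mgrid[0:200, 0:200]
        ell = ((((xx - 90) / 62.0) ** 2 + ((yy - 110) / 40.0) ** 2) <= 1).astype(float)
        out = resize_to_canonical(ell, PrepConfig())
        assert out.shape == (100, 100)
        r, c = np.nonzero(_foreground_mask(out))
        major = max(r.max() - r.min() + 1, c.max() - c.min() + 1)
        assert abs(major - 80) <= 2

    def test_blank_rejected(self):
        with pytest.raises(BlankImageError):
            resize_to_canonical(np.zeros((50, 50)), PrepConfig())

    def test_full_frame_foreground_rejected(self):
        img = np.ones((50, 50))
        img[0, 0] = 0.0
        with pytest.raises(BlankImageError):
            resize_to_canonical(img, PrepConfig())


class TestRenormalize:
    def test_constant_image_maps_to_one(self):
        out = renormalize_local(np.full((40, 40), 3.7), 5.0)
        np.testing.assert_allclose(out, 1.0, atol=1e-9)

    def test_invariant_to_global_intensity_scale(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.1, 1.0, (40, 40))
        a = renormalize_local(img, 4.0)
        b = renormalize_local(5.3 * img, 4.0)
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_stripe_pattern_matches_direct_convolution_oracle(self):
        img = np.zeros((48, 48))
        img[::2] = 1.0
        img += 0.2
        sigma = 2.0
        out = renormalize_local(img, sigma)
        # oracle: explicit sampled Gaussian kernel, edge padding, division
        r = int(6 * sigma)
        ax = np.arange(-r, r + 1)
        k1 = np.exp(-ax ** 2 / (2 * sigma ** 2))
        kern = np.outer(k1, k1) / np.outer(k1, k1).sum()
        padded = np.pad(img, r, mode="edge")
        local = convolve2d(padded, kern, mode="valid")
        # agreement up to the smoothing kernel's tail-truncation policy
        np.testing.assert_allclose(out, img / local, atol=1e-4)

    def test_negative_pixels_rejected(self):
        with pytest.raises(ValueError):
            renormalize_local(np.full((8, 8), -1.0), 2.0)


class TestLogistic:
    def test_midpoint_maps_to_half(self):
        assert logistic_contrast(np.array([[0.3]]), 8.0, 0.3)[0, 0] == pytest.approx(0.5)

    def test_large_gain_approaches_threshold_step(self):
        img = np.array([[0.1, 0.9]])
        out = logistic_contrast(img, 500.0, 0.5)
        np.testing.assert_allclose(out, (img > 0.5).astype(float), atol=1e-10)

    def test_monotone(self):
        x = np.sort(np.random.default_rng(1).uniform(0, 1, 50))
        y = logistic_contrast(x[None, :], 6.0, 0.4)[0]
        assert np.all(np.diff(y) > 0)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            logistic_contrast(np.zeros((4, 4)), 0.0, 0.5)


def test_pipeline_deterministic():
    img = render_frame(0.6, 64)["nuclei"]
    cfg = PrepConfig(canonical_size=64)
    a = prep_pipeline(img, 0.0, cfg)
    b = prep_pipeline(img, 0.0, cfg)
    assert np.array_equal(a, b)
    assert a.shape == (64, 64)
    assert np.all((a >= 0) & (a <= 1))


def test_pipeline_insensitive_to_global_intensity_scale():
    img = render_frame(0.6, 64)["nuclei"]
    cfg = PrepConfig(canonical_size=64)
    a = prep_pipeline(img, 0.0, cfg)
    b = prep_pipeline(0.2 * img, 0.0, cfg)
    assert np.abs(a - b).max() < 1e-6
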