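"""Affine registration, histogram matching, median smoothing, adjustment."""

import numpy as np
import pytest
from scipy import ndimage

from fluorosynth.clinical import (
    AffineTransform2D,
    adjust_sequence,
    affine_register,
    apply_transform,
    histogram_match,
    median_smooth,
)


@pytest.fixture(scope="module")
def drr_like():
    """Smooth synthetic radiograph-like image with interior structure."""
    rng = np.random.default_rng(7)
    img = ndimage.gaussian_filter(rng.random((96, 96)), 4.0)
    yy, xx = np.mgrid[:96, :96]
    img += 0.3 * np.exp(-(((yy - 48) / 22) ** 2 + ((xx - 48) / 30) ** 2))
    img += 0.15 * np.sin(yy / 5.0) * np.exp(-(((xx - 48) / 25) ** 2))
    return (img - img.min()) / (img.max() - img.min())


class TestAffineRegister:
    def test_identity_when_fixed_equals_moving(self, drr_like):
        t = affine_register(drr_like, drr_like)
        assert abs(t.translation[0]) < 0.1 and abs(t.translation[1]) < 0.1
        assert abs(t.rotation_deg) < 0.05
        assert t.scale == pytest.approx(1.0, abs=0.005)

    def test_recovers_pure_translation(self, drr_like):
        known = AffineTransform2D(translation=(5.0, 3.0))
        fixed = apply_transform(drr_like, known)
        t = affine_register(drr_like, fixed)
        assert t.translation[0] == pytest.approx(5.0, abs=0.5)
        assert t.translation[1] == pytest.approx(3.0, abs=0.5)

    def test_recovers_rotation_and_scale(self, drr_like):
        known = AffineTransform2D(rotation_deg=2.0, scale=1.05)
        fixed = apply_transform(drr_like, known)
        t = affine_register(drr_like, fixed)
        assert t.rotation_deg == pytest.approx(2.0, abs=0.2)
        assert t.scale == pytest.approx(1.05, abs=0.01)

    def test_divergence_returns_identity_with_warning(self, rng):
        moving = rng.random((64, 64))
        fixed = rng.random((64, 64))  # unrelated noise
        with pytest.warns(UserWarning, match="diverged"):
            t = affine_register(moving, fixed, min_similarity=0.9)
        assert t == AffineTransform2D()


class TestHistogramMatch:
    def test_self_reference_is_identity(self, drr_like):
        img8 = (drr_like * 255).astype(np.uint8)
        out = histogram_match(img8, img8)
        assert np.abs(out.astype(int) - img8.astype(int)).max() <= 1

    def test_constant_reference_gives_constant(self, drr_like):
        ref = np.full((32, 32), 77.0)
        out = histogram_match(drr_like, ref)
        assert np.all(out == 77.0)

    def test_cdf_matches_reference_quantiles(self, rng):
        img = (rng.uniform(0, 255, (128, 128))).astype(np.uint8)
        ref = np.clip(rng.normal(120, 30, (128, 128)), 0, 255).astype(np.uint8)
        out = histogram_match(img, ref)
        qs = np.linspace(0.02, 0.98, 25)
        assert np.all(
            np.abs(np.quantile(out, qs) - np.quantile(ref, qs)) <= 1.0 + 1e-9
        )

    def test_monotone_never_inverts_pixel_order(self, rng):
        img = rng.random((64, 64))
        ref = rng.random((64, 64)) ** 2
        out = histogram_match(img, ref)
        order = np.argsort(img.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= -1e-12)


class TestMedianSmooth:
    def test_constant_unchanged(self):
        img = np.full((20, 20), 5.0)
        assert np.array_equal(median_smooth(img), img)

    def test_impulse_removed(self):
        img = np.zeros((21, 21))
        img[10, 10] = 100.0
        assert median_smooth(img)[10, 10] == 0.0

    def test_matches_brute_force_with_reflect_border(self, rng):
        img = rng.random((7, 7))
        out = median_smooth(img, size=5)
        padded = np.pad(img, 2, mode="symmetric")  # scipy 'reflect' = edge-inclusive
        for i in range(7):
            for j in range(7):
                assert out[i, j] == np.median(padded[i : i + 5, j : j + 5])


class TestAdjustSequence:
    def test_reference_sequence_round_trips(self, drr_like):
        adjusted, t = adjust_sequence([drr_like], drr_like)
        assert t.scale == pytest.approx(1.0, abs=0.01)
        # registration -> matching is near-identity; smoothing perturbs mildly
        assert np.abs(adjusted[0] - median_smooth(drr_like)).mean() < 0.02

    def test_output_histogram_matches_drr(self, drr_like, rng):
        frames = [np.clip(drr_like * 1.4 + rng.normal(0, 0.03, drr_like.shape), 0, 2)]
        adjusted, _ = adjust_sequence(frames, drr_like)
        qs = np.linspace(0.05, 0.95, 19)
        # smoothing shifts the histogram slightly; allow a few gray levels
        dev = np.abs(np.quantile(adjusted[0], qs) - np.quantile(drr_like, qs))
        assert dev.max() < 5 / 255

    def test_idempotent_up_to_smoothing(self, drr_like, rng):
        frames = [np.clip(drr_like + rng.normal(0, 0.02, drr_like.shape), 0, 1)]
        once, _ = adjust_sequence(frames, drr_like)
        twice, _ = adjust_sequence(once, drr_like)
        assert np.abs(twice[0] - once[0]).mean() < 2 / 255

    def test_preserves_frame_dimensions(self, drr_like):
        adjusted, _ = adjust_sequence([drr_like, drr_like * 0.8], drr_like)
        assert all(a.shape == drr_like.shape for a in adjusted)

    def test_empty_sequence_rejected(self, drr_like):
        with pytest.raises(ValueError):
            adjust_sequence([], drr_like)
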