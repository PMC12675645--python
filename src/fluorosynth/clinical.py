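"""Treatment-session preprocessing: adjust fluoroscopy toward DRR appearance.

Clinical fluoroscopic frames differ from the DRRs the synthesis model was
trained on in geometry, contrast and texture.  The adjustment workflow is:
(1) a 2D affine registration (translation, rotation, isotropic scale)
between the reference DRR and the *first* frame, performed once per
sequence; (2) per frame, resampling into the DRR geometry, histogram
matching to the DRR, and a 5x5 median smoothing filter, in that order.

Registration maximizes zero-normalized cross-correlation with a Powell
search over a multi-resolution pyramid; if the final similarity is poor a
warning is emitted and the identity transform is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage import transform as sktransform
from skimage.exposure import match_histograms

__all__ = [
    "AffineTransform2D",
    "affine_register",
    "apply_transform",
    "histogram_match",
    "median_smooth",
    "adjust_sequence",
]


@dataclass(frozen=True)
class AffineTransform2D:
    """Translation (px), rotation (deg) and isotropic scale about the center."""

    translation: tuple[float, float] = (0.0, 0.0)  # (row, col)
    rotation_deg: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def to_dict(self) -> dict:
        return {
            "translation": list(self.translation),
            "rotation_deg": self.rotation_deg,
            "scale": self.scale,
        }


def _similarity(t: AffineTransform2D, shape) -> sktransform.SimilarityTransform:
    """Forward map moving -> fixed coordinates, rotation/scale about center."""
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    center = sktransform.SimilarityTransform(translation=(-cx, -cy))
    core = sktransform.SimilarityTransform(
        scale=t.scale, rotation=np.deg2rad(t.rotation_deg)
    )
    back = sktransform.SimilarityTransform(
        translation=(cx + t.translation[1], cy + t.translation[0])
    )
    return center + core + back


def apply_transform(moving: np.ndarray, t: AffineTransform2D) -> np.ndarray:
    """Warp the moving image into fixed coordinates (linear interpolation)."""
    tf = _similarity(t, moving.shape)
    return sktransform.warp(
        moving.astype(np.float64), tf.inverse, order=1, mode="constant", cval=0.0
    )


def resample_inverse(fixed_frame: np.ndarray, t: AffineTransform2D) -> np.ndarray:
    """Pull a fixed-geometry frame back into the moving (DRR) geometry."""
    tf = _similarity(t, fixed_frame.shape)
    return sktransform.warp(
        fixed_frame.astype(np.float64), tf, order=1, mode="constant", cval=0.0
    )


def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _downscale(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img.astype(np.float64)
    return sktransform.rescale(img.astype(np.float64), 1.0 / factor, order=1, anti_aliasing=True)


def affine_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    pyramid: tuple[int, ...] = (4, 2, 1),
    min_similarity: float = 0.2,
) -> AffineTransform2D:
    """Estimate the similarity transform aligning ``moving`` onto ``fixed``.

    Powell optimization of negative zero-normalized cross-correlation,
    coarse-to-fine over ``pyramid`` downscale factors.  Returns the identity
    with a warning if the achieved similarity is below ``min_similarity``.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    params = np.array([0.0, 0.0, 0.0, 1.0])  # ty, tx, rot_deg, scale

    for factor in pyramid:
        mv, fx = _downscale(moving, factor), _downscale(fixed, factor)
        if min(mv.shape + fx.shape) < 8:
            continue

        def cost(p):
            t = AffineTransform2D((p[0], p[1]), p[2], max(p[3], 1e-3))
            w = apply_transform(mv, t)
            return -_zncc(w, fx)

        x0 = params.copy()
        x0[:2] /= factor
        res = optimize.minimize(
            cost,
            x0,
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 200},
        )
        params = res.x.copy()
        params[:2] *= factor

    t = AffineTransform2D((params[0], params[1]), params[2], max(params[3], 1e-3))
    final = _zncc(apply_transform(moving, t), fixed)
    if final < min_similarity:
        warnings.warn(
            f"affine registration diverged (similarity {final:.3f}); returning identity",
            stacklevel=2,
        )
        return AffineTransform2D()
    return t


def histogram_match(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Monotone intensity remap of ``image`` onto the reference histogram.

    Exact quantile mapping (scikit-image); a constant reference maps every
    pixel to the reference value.  Geometry is unchanged.
    """
    image = np.asarray(image)
    reference = np.asarray(reference)
    if reference.min() == reference.max():
        return np.full_like(image, reference.flat[0], dtype=reference.dtype)
    return match_histograms(image, reference)


def median_smooth(image: np.ndarray, size: int = 5) -> np.ndarray:
    """Median filter with reflecting borders (default 5x5)."""
    return ndimage.median_filter(np.asarray(image), size=size, mode="reflect")


def adjust_sequence(
    frames: list[np.ndarray], reference_drr: np.ndarray
) -> tuple[list[np.ndarray], AffineTransform2D]:
    """Adjust a fluoroscopic sequence to DRR-like appearance.

    Registration runs once, between the reference DRR (moving) and the
    first frame (fixed); every frame is then pulled into the DRR geometry,
    histogram matched to the DRR and median smoothed.
    """
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    t = affine_register(reference_drr, frames[0])
    out = []
    for frame in frames:
        g = resample_inverse(np.asarray(frame, dtype=np.float64), t)
        g = histogram_match(g, reference_drr)
        g = median_smooth(g)
        out.append(g)
    return out, t
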