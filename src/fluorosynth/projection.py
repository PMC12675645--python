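"""Volume rotation and digitally reconstructed radiographs (DRRs).

The acquisition geometry is described by two couch angles (theta, phi) and
a gantry angle gamma.  The attenuation volume is resampled under the
composed rotation R = Rx(theta) @ Ry(phi) @ Rz(gamma) about the grid
center, then forward-projected with parallel rays along one grid axis:

    I(i, j) = I0 * exp(-integral mu dl)

with the line integral evaluated by fixed-step sampling (half-voxel steps,
linear interpolation).  No noise or scatter is simulated.

The elemental rotation matrices follow the convention where Ry carries
-sin(phi) in its first row (the transpose of the more common right-handed
form); the rotation is applied to coordinates, V_rot(r) = V(R r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "AcquisitionAngles",
    "RadiographImage",
    "DetectorConfig",
    "rotation_matrix",
    "rotate_volume",
    "project",
]


@dataclass(frozen=True)
class AcquisitionAngles:
    """Couch angles theta, phi and gantry angle gamma, in degrees."""

    theta: float = 0.0
    phi: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        for a in (self.theta, self.phi, self.gamma):
            if not np.isfinite(a):
                raise ValueError("angles must be finite")


@dataclass
class RadiographImage:
    """2D projection image with pixel spacing (mm) and acquisition metadata.

    ``meta`` carries at least ``kind`` (one of SE, HE, LE, DES,
    synthesized_DES), and usually ``energy_name``, ``phase`` and ``angles``.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class DetectorConfig:
    """Parallel-beam detector: projection axis and optional resampling."""

    axis: int = 1  # grid axis the rays run along (1 = anterior-posterior)
    output_shape: tuple[int, int] | None = None  # resample detector grid
    i0: float = 1.0
    step_voxels: float = 0.5  # ray sampling step, in voxels


def rotation_matrix(angles: AcquisitionAngles) -> np.ndarray:
    """Compose R = Rx(theta) @ Ry(phi) @ Rz(gamma), angles in degrees."""
    t, p, g = np.deg2rad([angles.theta, angles.phi, angles.gamma])
    ct, st = np.cos(t), np.sin(t)
    cp, sp = np.cos(p), np.sin(p)
    cg, sg = np.cos(g), np.sin(g)
    rx = np.array([[1, 0, 0], [0, ct, -st], [0, st, ct]])
    ry = np.array([[cp, 0, -sp], [0, 1, 0], [sp, 0, cp]])
    rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return rx @ ry @ rz


def _check_orthonormal(r: np.ndarray, tol: float = 1e-8) -> None:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError("rotation matrix must be 3x3")
    if not np.allclose(r.T @ r, np.eye(3), atol=tol) or not np.isclose(
        np.linalg.det(r), 1.0, atol=tol
    ):
        raise ValueError("matrix is not a proper rotation (orthonormal, det +1)")


def rotate_volume(mu_grid: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Resample a volume under V_rot(x) = V(R x) about the grid center.

    Trilinear interpolation; voxels rotated in from outside the field are
    air (0).  An identity rotation returns the input unchanged.
    """
    _check_orthonormal(r)
    mu_grid = np.asarray(mu_grid)
    if np.allclose(r, np.eye(3)):
        return mu_grid.copy()
    center = (np.asarray(mu_grid.shape) - 1) / 2.0
    offset = center - r @ center
    return ndimage.affine_transform(
        mu_grid, r, offset=offset, order=1, mode="constant", cval=0.0, prefilter=False
    )


def _line_integrals(mu: np.ndarray, spacing_mm: float, axis: int, step_voxels: float) -> np.ndarray:
    """Path integrals of mu (1/cm) along one axis, in optical-depth units.

    Fixed-step sampling at ``step_voxels`` intervals across the full
    physical extent [-0.5, n-0.5] voxels, values linearly interpolated
    between voxel centers (clamped at the ends).
    """
    mu = np.moveaxis(mu, axis, 0)
    n = mu.shape[0]
    n_steps = int(round(n / step_voxels))
    s = -0.5 + (np.arange(n_steps) + 0.5) * (n / n_steps)
    base = np.floor(s)
    w = (s - base)[:, None, None]
    i0 = np.clip(base.astype(int), 0, n - 1)
    i1 = np.clip(base.astype(int) + 1, 0, n - 1)
    samples = (1.0 - w) * mu[i0] + w * mu[i1]
    dl_cm = (n / n_steps) * spacing_mm / 10.0
    return samples.sum(axis=0) * dl_cm


def project(
    mu_grid: np.ndarray,
    spacing: tuple[float, float, float],
    detector: DetectorConfig | None = None,
    meta: dict | None = None,
) -> RadiographImage:
    """Parallel-beam DRR: per pixel, I = I0 * exp(-integral mu dl).

    ``mu_grid`` is in 1/cm, ``spacing`` in mm.  Rays run along
    ``detector.axis``; the detector grid is the two remaining axes, in
    order, optionally resampled to ``detector.output_shape``.
    """
    det = detector or DetectorConfig()
    mu_grid = np.asarray(mu_grid, dtype=np.float64)
    if np.any(mu_grid < 0):
        raise ValueError("attenuation coefficients must be non-negative")
    integrals = _line_integrals(mu_grid, spacing[det.axis], det.axis, det.step_voxels)

    keep = [a for a in range(3) if a != det.axis]
    px_spacing = (spacing[keep[0]], spacing[keep[1]])
    if det.output_shape is not None and tuple(det.output_shape) != integrals.shape:
        # resample in the line-integral domain: detector binning stays linear
        # in optical depth, preserving the log-domain additivity the
        # subtraction algebra relies on
        in_shape = integrals.shape
        integrals = resize(integrals, det.output_shape, order=1, anti_aliasing=True)
        px_spacing = (
            px_spacing[0] * in_shape[0] / det.output_shape[0],
            px_spacing[1] * in_shape[1] / det.output_shape[1],
        )
    pixels = det.i0 * np.exp(-integrals)
    m = dict(meta or {})
    m.setdefault("kind", "SE")
    return RadiographImage(pixels=pixels, pixel_spacing=px_spacing, meta=m)


def project_point(
    point_vox: np.ndarray,
    shape: tuple[int, int, int],
    r: np.ndarray,
    detector: DetectorConfig | None = None,
) -> np.ndarray:
    """Detector-pixel position of a volume feature under rotate-then-project.

    A feature at voxel position v0 in the unrotated volume appears at
    v = R^T (v0 - c) + c in the rotated volume (V_rot(x) = V(R x)); its
    projection is v with the ray axis dropped, mapped through any detector
    resampling.  Used for exact tumor-centroid ground truth.
    """
    det = detector or DetectorConfig()
    _check_orthonormal(r)
    c = (np.asarray(shape) - 1) / 2.0
    v = np.asarray(r).T @ (np.asarray(point_vox, dtype=float) - c) + c
    keep = [a for a in range(3) if a != det.axis]
    pos = v[keep]
    if det.output_shape is not None:
        in_shape = np.asarray(shape)[keep]
        scale = np.asarray(det.output_shape) / in_shape
        pos = (pos + 0.5) * scale - 0.5
    return pos
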