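"""Tracking and image-quality metrics, and the paired bootstrap comparison.

RMSE is the root mean square Euclidean error between tracked and
ground-truth positions in mm; the tracking success rate (TSR) is the
percentage of frames whose error is strictly below 25% of the maximum
tumor movement range.  Image quality uses PSNR (8-bit scale by default)
and single-scale SSIM with the standard 11x11 Gaussian window (sigma 1.5)
and stabilizers C1 = (0.01 L)^2, C2 = (0.03 L)^2.

The SE-vs-DES comparison resamples frames i.i.d. with replacement and
compares the bootstrap distribution of the statistic difference against
zero (two-sided, +1-smoothed p-value; percentile confidence intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .tracking import Trajectory

__all__ = [
    "SUCCESS_FRACTION",
    "TrackingReport",
    "BootstrapResult",
    "rmse",
    "tracking_errors_mm",
    "tsr",
    "psnr",
    "ssim",
    "paired_bootstrap_test",
    "evaluate_tracking",
]

#: A frame counts as a tracking success below this fraction of the motion range.
SUCCESS_FRACTION = 0.25


def _positions_mm(traj) -> np.ndarray:
    if isinstance(traj, Trajectory):
        return traj.positions_mm()
    return np.asarray(traj, dtype=float)


def tracking_errors_mm(traj, gt) -> np.ndarray:
    """Per-frame Euclidean errors (mm) between two trajectories."""
    a, b = _positions_mm(traj), _positions_mm(gt)
    if a.shape != b.shape:
        raise ValueError("trajectories must have equal length")
    return np.sqrt(((a - b) ** 2).sum(axis=1))


def rmse(traj, gt) -> float:
    """Root mean square Euclidean tracking error in mm."""
    e = tracking_errors_mm(traj, gt)
    return float(np.sqrt(np.mean(e * e)))


def tsr(traj, gt, motion_range_mm: float) -> float:
    """Tracking success rate (%) at the strict 25%-of-range threshold."""
    if motion_range_mm <= 0:
        raise ValueError("motion range must be positive")
    e = tracking_errors_mm(traj, gt)
    return float(100.0 * np.mean(e < SUCCESS_FRACTION * motion_range_mm))


def psnr(a: np.ndarray, b: np.ndarray, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10*log10(max^2 / MSE), in dB.

    Identical images have infinite PSNR, reported as ``inf``.
    """
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(max_value**2 / mse))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Single-scale SSIM, 11x11 Gaussian window (sigma 1.5), mean over the map.

    ``data_range`` defaults to 255 for 8-bit integers and 1.0 otherwise.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if np.array_equal(a, b):
        return 1.0
    if data_range is None:
        data_range = 255.0 if a.dtype == np.uint8 else 1.0
    return float(
        structural_similarity(
            a.astype(np.float64),
            b.astype(np.float64),
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


@dataclass
class BootstrapResult:
    """Two-sided paired bootstrap comparison of a tracking statistic."""

    p_value: float
    reject: bool
    stat_a: float
    stat_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    n_resamples: int
    alpha: float


def _stat_fn(statistic, motion_range_mm):
    if statistic == "rmse":
        return lambda e: np.sqrt(np.mean(e * e, axis=-1))
    if statistic == "tsr":
        if motion_range_mm is None:
            raise ValueError("tsr statistic needs motion_range_mm")
        thr = SUCCESS_FRACTION * motion_range_mm
        return lambda e: 100.0 * np.mean(e < thr, axis=-1)
    raise ValueError(f"unknown statistic {statistic!r}")


def paired_bootstrap_test(
    errors_a: np.ndarray,
    errors_b: np.ndarray,
    n_resamples: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "rmse",
    motion_range_mm: float | None = None,
) -> BootstrapResult:
    """Paired bootstrap test of H0: stat(errors_a) == stat(errors_b).

    Frame indices are resampled with replacement ``n_resamples`` times; the
    two-sided p-value is 2*min(P(d <= 0), P(d >= 0)) with +1 smoothing,
    where d is the bootstrap statistic difference.  95% percentile CIs are
    returned per arm.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("error arrays must be 1D and of equal length")
    if n_resamples < 100:
        raise ValueError("need at least 100 resamples")
    fn = _stat_fn(statistic, motion_range_mm)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(a), size=(n_resamples, len(a)))
    sa, sb = fn(a[idx]), fn(b[idx])
    d = sa - sb
    p = 2.0 * min(
        (1 + np.count_nonzero(d <= 0)) / (n_resamples + 1),
        (1 + np.count_nonzero(d >= 0)) / (n_resamples + 1),
    )
    p = min(p, 1.0)
    q = 100 * np.array([alpha / 2, 1 - alpha / 2])
    return BootstrapResult(
        p_value=float(p),
        reject=bool(p < alpha),
        stat_a=float(fn(a)),
        stat_b=float(fn(b)),
        ci_a=tuple(np.percentile(sa, q)),
        ci_b=tuple(np.percentile(sb, q)),
        n_resamples=n_resamples,
        alpha=alpha,
    )


@dataclass
class TrackingReport:
    """Per-sequence tracking evaluation against ground truth."""

    errors_mm: np.ndarray
    rmse_mm: float
    tsr_percent: float
    success_threshold_mm: float
    rmse_ci: tuple[float, float]
    tsr_ci: tuple[float, float]
    comparison: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.tsr_percent <= 100:
            raise ValueError("TSR must be a percentage")
        if self.rmse_mm < 0:
            raise ValueError("RMSE must be non-negative")


def evaluate_tracking(
    traj,
    gt,
    motion_range_mm: float,
    n_resamples: int = 1000,
    seed: int = 0,
) -> TrackingReport:
    """RMSE, TSR and 95% bootstrap CIs for one tracked sequence."""
    e = tracking_errors_mm(traj, gt)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(e), size=(n_resamples, len(e)))
    boot = e[idx]
    r = np.sqrt(np.mean(boot * boot, axis=1))
    thr = SUCCESS_FRACTION * motion_range_mm
    t = 100.0 * np.mean(boot < thr, axis=1)
    return TrackingReport(
        errors_mm=e,
        rmse_mm=rmse(traj, gt),
        tsr_percent=tsr(traj, gt, motion_range_mm),
        success_threshold_mm=thr,
        rmse_ci=tuple(np.percentile(r, [2.5, 97.5])),
        tsr_ci=tuple(np.percentile(t, [2.5, 97.5])),
    )
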