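"""Dual-energy subtraction, data augmentation and training-set generation.

The soft-tissue enhancing subtraction is the weighted log subtraction

    ln I_DES = ln I_HE - omega * ln I_LE

with omega = 0.5 by default.  With the default attenuation coefficients the
bone HE/LE ratio is exactly 0.5, so this omega cancels the bone pathlength
contribution analytically for noiseless parallel-beam projections — the
central oracle of this module.

Training pairs (SE, DES) — the high-energy image plays the SE role — are
enumerated over a grid of 10 respiratory phases x 36 equal-couch-angle
pairs x 100 gantry angles, then augmented with a shared random
scale/crop/zero-pad transform.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import rescale

from .phantom import (
    EnergySpec,
    PhantomConfig,
    attenuation_volume,
    bone_free,
    build_phantom,
)
from .projection import (
    AcquisitionAngles,
    DetectorConfig,
    RadiographImage,
    project,
    rotate_volume,
    rotation_matrix,
)

__all__ = [
    "LOG_FLOOR",
    "DEFAULT_OMEGA",
    "AugmentationRecord",
    "TrainingPair",
    "GridConfig",
    "des_subtract",
    "bone_cancel_weight",
    "augment_pair",
    "enumerate_training_grid",
    "PairSimulator",
    "generate_dataset",
]

#: Intensity floor applied before logarithms (the subtraction is undefined at 0).
LOG_FLOOR = 1e-8

#: Soft-tissue enhancing weight for 120/60 kVp surrogate energies.
DEFAULT_OMEGA = 0.5


@dataclass(frozen=True)
class AugmentationRecord:
    """Parameters of one shared scale/crop/zero-pad transform."""

    scale: float
    crop_box: tuple[int, int, int, int]  # (row0, col0, height, width)
    padding: tuple[int, int, int, int]  # zeros around the kept box (t, b, l, r)
    seed: int

    def __post_init__(self):
        if not 0.8 <= self.scale <= 1.2:
            raise ValueError("scale factor outside [0.8, 1.2]")


@dataclass
class TrainingPair:
    """Geometrically aligned (SE, DES) image pair with provenance."""

    se: RadiographImage
    des: RadiographImage
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se.shape != self.des.shape:
            raise ValueError("SE and DES members must have identical shape")


def des_subtract(
    i_he: RadiographImage, i_le: RadiographImage, omega: float = DEFAULT_OMEGA
) -> RadiographImage:
    """Weighted log subtraction, returned in the intensity domain.

    I_DES = I_HE * I_LE^(-omega); the log-domain array is preserved in
    ``meta["log_pixels"]`` for metric computations.
    """
    if i_he.shape != i_le.shape:
        raise ValueError("HE and LE images must have the same shape")
    he = np.asarray(i_he.pixels, dtype=np.float64)
    le = np.asarray(i_le.pixels, dtype=np.float64)
    if np.any(he < 0) or np.any(le < 0):
        raise ValueError("negative intensities are not valid radiograph values")
    log_des = np.log(np.maximum(he, LOG_FLOOR)) - omega * np.log(np.maximum(le, LOG_FLOOR))
    pixels = np.exp(log_des)
    meta = {
        "kind": "DES",
        "omega": float(omega),
        "phase": i_he.meta.get("phase"),
        "angles": i_he.meta.get("angles"),
        "log_pixels": log_des,
    }
    return RadiographImage(pixels=pixels, pixel_spacing=i_he.pixel_spacing, meta=meta)


def bone_cancel_weight(spec_he: EnergySpec, spec_le: EnergySpec) -> float:
    """The weight that exactly cancels bone: mu_HE(rib) / mu_LE(rib)."""
    from .phantom import Material

    le = spec_le.mu[Material.RIB]
    if le == 0:
        raise ValueError("LE bone attenuation is zero; no cancelling weight exists")
    return spec_he.mu[Material.RIB] / le


def _resize_to(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Center-crop or zero-pad an array to an exact shape."""
    out = np.zeros(shape, dtype=img.dtype)
    r = min(img.shape[0], shape[0])
    c = min(img.shape[1], shape[1])
    ir, ic = (img.shape[0] - r) // 2, (img.shape[1] - c) // 2
    orr, oc = (shape[0] - r) // 2, (shape[1] - c) // 2
    out[orr : orr + r, oc : oc + c] = img[ir : ir + r, ic : ic + c]
    return out


def _apply_augmentation(
    img: np.ndarray, scale: float, crop_box: tuple[int, int, int, int]
) -> np.ndarray:
    shape = img.shape
    if scale != 1.0:
        img = rescale(img, scale, order=1, anti_aliasing=scale < 1.0)
        img = _resize_to(img, shape)
    r0, c0, h, w = crop_box
    out = np.zeros_like(img)
    out[r0 : r0 + h, c0 : c0 + w] = img[r0 : r0 + h, c0 : c0 + w]
    return out


def augment_pair(
    pair: TrainingPair,
    seed: int,
    scale: float | None = None,
    crop_fraction: float | None = None,
) -> TrainingPair:
    """Apply one shared scale/crop/zero-pad transform to both members.

    Scale is sampled from [0.8, 1.2] and the crop side fraction from
    [0.5, 1.0] with a uniformly random placement; zero padding restores the
    original dimensions, leaving the kept content at its original position.
    Explicit ``scale`` / ``crop_fraction`` override the sampling (useful for
    deterministic identity transforms).
    """
    rng = np.random.default_rng(seed)
    s = float(rng.uniform(0.8, 1.2)) if scale is None else float(scale)
    f = float(rng.uniform(0.5, 1.0)) if crop_fraction is None else float(crop_fraction)
    shape = pair.se.shape
    h, w = max(1, round(shape[0] * f)), max(1, round(shape[1] * f))
    r0 = int(rng.integers(0, shape[0] - h + 1))
    c0 = int(rng.integers(0, shape[1] - w + 1))
    box = (r0, c0, h, w)
    record = AugmentationRecord(
        scale=s,
        crop_box=box,
        padding=(r0, shape[0] - r0 - h, c0, shape[1] - c0 - w),
        seed=int(seed),
    )

    def _member(img: RadiographImage) -> RadiographImage:
        out = _apply_augmentation(np.asarray(img.pixels, dtype=np.float64), s, box)
        meta = {k: v for k, v in img.meta.items() if k != "log_pixels"}
        meta["augmentation"] = record
        return RadiographImage(pixels=out, pixel_spacing=img.pixel_spacing, meta=meta)

    prov = dict(pair.provenance)
    prov["augmentation"] = record
    return TrainingPair(se=_member(pair.se), des=_member(pair.des), provenance=prov)


@dataclass(frozen=True)
class GridConfig:
    """Acquisition grid: gantry sweep x couch pairs x respiratory phases."""

    gantry_start_deg: float = 3.6
    gantry_stop_deg: float = 360.0
    gantry_step_deg: float = 3.6
    couch_pairs: tuple[tuple[float, float], ...] = tuple((k, k) for k in range(36))
    phases: tuple[int, ...] = tuple(range(1, 11))

    def gantry_angles(self) -> np.ndarray:
        n = int(round((self.gantry_stop_deg - self.gantry_start_deg) / self.gantry_step_deg)) + 1
        return self.gantry_start_deg + self.gantry_step_deg * np.arange(n)


def enumerate_training_grid(grid: GridConfig | None = None) -> list[tuple[int, AcquisitionAngles]]:
    """All (phase, angles) entries, phase-major, then couch pair, then gantry.

    The default grid is 10 phases x 36 couch pairs x 100 gantry angles =
    36,000 entries.
    """
    grid = grid or GridConfig()
    gammas = grid.gantry_angles()
    return [
        (int(p), AcquisitionAngles(theta=t, phi=f, gamma=float(g)))
        for p in grid.phases
        for (t, f) in grid.couch_pairs
        for g in gammas
    ]


class PairSimulator:
    """Simulates aligned (SE, DES) projections of the phantom.

    Caches the HE/LE attenuation volumes per respiratory phase so sweeping
    angles over a fixed phase costs one volume rotation per energy.
    """

    def __init__(
        self,
        config: PhantomConfig,
        detector: DetectorConfig | None = None,
        omega: float = DEFAULT_OMEGA,
        specs: tuple[EnergySpec, EnergySpec] | None = None,
    ):
        self.config = config
        self.detector = detector or DetectorConfig()
        self.omega = omega
        self.specs = specs or config.energy_specs
        self._mu_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def attenuations(self, phase: int) -> tuple[np.ndarray, np.ndarray]:
        if phase not in self._mu_cache:
            vol = build_phantom(self.config, phase)
            he, le = self.specs
            self._mu_cache[phase] = (
                attenuation_volume(vol, he),
                attenuation_volume(vol, le),
            )
        return self._mu_cache[phase]

    def projections(
        self, phase: int, angles: AcquisitionAngles
    ) -> tuple[RadiographImage, RadiographImage]:
        """(HE, LE) DRRs at one phase and acquisition geometry."""
        mu_he, mu_le = self.attenuations(phase)
        r = rotation_matrix(angles)
        meta = {"phase": phase, "angles": angles}
        i_he = project(
            rotate_volume(mu_he, r),
            self.config.spacing,
            self.detector,
            meta={**meta, "kind": "SE", "energy_name": "HE"},
        )
        i_le = project(
            rotate_volume(mu_le, r),
            self.config.spacing,
            self.detector,
            meta={**meta, "kind": "LE", "energy_name": "LE"},
        )
        return i_he, i_le

    def pair(self, phase: int, angles: AcquisitionAngles) -> TrainingPair:
        """Un-augmented (SE, DES) pair; SE is the HE image."""
        i_he, i_le = self.projections(phase, angles)
        i_des = des_subtract(i_he, i_le, self.omega)
        return TrainingPair(
            se=i_he,
            des=i_des,
            provenance={"phase": phase, "angles": angles, "omega": self.omega},
        )


def _subsample(entries: list, n: int | None, seed: int) -> tuple[list, list[int]]:
    if n is None or n >= len(entries):
        return entries, list(range(len(entries)))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(entries), size=n, replace=False))
    return [entries[i] for i in idx], idx.tolist()


def simulate_training_set(
    config: PhantomConfig,
    grid: GridConfig | None = None,
    n_pairs: int | None = None,
    master_seed: int = 0,
    detector: DetectorConfig | None = None,
    omega: float = DEFAULT_OMEGA,
    augment: bool = True,
) -> list[TrainingPair]:
    """In-memory training set over a (possibly subsampled) acquisition grid."""
    entries, grid_idx = _subsample(enumerate_training_grid(grid), n_pairs, master_seed)
    sim = PairSimulator(config, detector, omega)
    pairs = []
    for (phase, angles), gi in zip(entries, grid_idx):
        pair = sim.pair(phase, angles)
        pair.provenance["grid_index"] = gi
        if augment:
            seed = int(np.random.SeedSequence([master_seed, gi]).generate_state(1)[0] % 2**31)
            pair = augment_pair(pair, seed)
        pairs.append(pair)
    return pairs


def generate_dataset(
    config: PhantomConfig,
    grid: GridConfig | None,
    out_dir: str | Path,
    n_pairs: int | None = None,
    master_seed: int = 0,
    detector: DetectorConfig | None = None,
    omega: float = DEFAULT_OMEGA,
    augment: bool = True,
) -> Path:
    """Write an (SE, DES) training set to disk with a provenance manifest.

    Layout: ``pairs/{index:06d}_{se|des}.tif`` (float32 TIFF) plus
    ``manifest.csv`` recording phase, angles, omega and the augmentation
    record, so any pair can be regenerated.  Partial output is removed on
    failure.
    """
    out = Path(out_dir)
    pairs_dir = out / "pairs"
    pairs_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    try:
        pairs = simulate_training_set(
            config, grid, n_pairs, master_seed, detector, omega, augment
        )
        for i, pair in enumerate(pairs):
            tifffile.imwrite(pairs_dir / f"{i:06d}_se.tif", pair.se.pixels.astype(np.float32))
            tifffile.imwrite(pairs_dir / f"{i:06d}_des.tif", pair.des.pixels.astype(np.float32))
            a = pair.se.meta["angles"] if "angles" in pair.se.meta else pair.provenance["angles"]
            rec = pair.provenance.get("augmentation")
            rows.append(
                {
                    "index": i,
                    "grid_index": pair.provenance.get("grid_index", i),
                    "phase": pair.provenance["phase"],
                    "theta": a.theta,
                    "phi": a.phi,
                    "gamma": a.gamma,
                    "omega": omega,
                    "aug_seed": rec.seed if rec else "",
                    "aug_scale": rec.scale if rec else "",
                    "aug_crop_box": ";".join(map(str, rec.crop_box)) if rec else "",
                }
            )
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    except Exception:
        shutil.rmtree(pairs_dir, ignore_errors=True)
        (out / "manifest.csv").unlink(missing_ok=True)
        raise
    return out


def bone_cancellation_residual(
    config: PhantomConfig,
    phase: int = 1,
    angles: AcquisitionAngles | None = None,
    detector: DetectorConfig | None = None,
) -> float:
    """Max |log DES(with bone) - log DES(bone removed)| at the cancelling weight.

    The same label volume is projected twice, once with the configured bone
    attenuation and once with rib/spine coefficients zeroed; at
    omega* = mu_HE(rib)/mu_LE(rib) the two DES images agree to numerical
    precision because the subtraction is linear in the bone pathlength.
    """
    he, le = config.energy_specs
    omega = bone_cancel_weight(he, le)
    angles = angles or AcquisitionAngles(theta=5.0, phi=5.0, gamma=30.0)

    des_images = []
    for specs in ((he, le), (bone_free(he), bone_free(le))):
        sim = PairSimulator(config, detector, omega, specs=specs)
        des_images.append(sim.pair(phase, angles).des.meta["log_pixels"])
    return float(np.max(np.abs(des_images[0] - des_images[1])))
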