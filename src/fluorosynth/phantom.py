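"""4D dual-energy digital thorax phantom.

Generates labelled voxel volumes of a breathing thorax — ellipsoidal torso,
two lungs, a posterior spine column, parametric curved rib arcs and a
spherical tumor — over a cycle of discrete respiratory phases, plus the
per-material linear attenuation coefficients at two effective beam energies
(high-energy/low-energy surrogates for 120 and 60 kVp).

Geometry is analytic and rasterized on demand, so volumes are bit-identical
for identical configurations.  The tumor (and the lungs it sits in)
translate superior–inferiorly with a sin^2 respiratory surrogate; ribs,
spine and torso are static, which is what produces the rib/tumor overlap
that degrades single-energy tracking.

Axes convention: arrays are indexed (x, y, z) = (left–right,
anterior–posterior, superior–inferior), voxel centers at (i + 0.5) * spacing
mm.  +z is inferior; inhale displaces the tumor toward +z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "Material",
    "MaterialVolume",
    "EnergySpec",
    "PhantomConfig",
    "default_energy_specs",
    "build_phantom",
    "attenuation_volume",
    "respiratory_displacement_mm",
    "tumor_center_mm",
]


class Material(IntEnum):
    """Voxel material codes."""

    AIR = 0
    SOFT_TISSUE = 1
    LUNG = 2
    RIB = 3
    SPINE = 4
    TUMOR = 5


#: Default effective monoenergetic attenuation coefficients (1/cm).
#: Bone (rib, spine) HE/LE ratio is exactly 0.5, so the soft-tissue
#: enhancing weight omega = 0.5 cancels bone analytically.
_DEFAULT_MU = {
    "HE": {
        Material.AIR: 0.0,
        Material.SOFT_TISSUE: 0.18,
        Material.LUNG: 0.04,
        Material.RIB: 0.30,
        Material.SPINE: 0.30,
        Material.TUMOR: 0.19,
    },
    "LE": {
        Material.AIR: 0.0,
        Material.SOFT_TISSUE: 0.25,
        Material.LUNG: 0.06,
        Material.RIB: 0.60,
        Material.SPINE: 0.60,
        Material.TUMOR: 0.27,
    },
}


@dataclass(frozen=True)
class EnergySpec:
    """Linear attenuation coefficients of every material at one energy.

    Parameters
    ----------
    energy_name : str
        ``"HE"`` or ``"LE"``.
    mu : dict
        Material code -> linear attenuation coefficient in 1/cm.
    """

    energy_name: str
    mu: dict

    def __post_init__(self):
        if self.mu.get(Material.AIR, 0.0) != 0.0:
            raise ValueError("mu(air) must be exactly 0")
        for m, v in self.mu.items():
            if v < 0:
                raise ValueError(f"negative attenuation for material {m!r}")

    def table(self, n: int = 8) -> np.ndarray:
        """Coefficients as a lookup table indexed by material code."""
        t = np.zeros(n)
        for m, v in self.mu.items():
            t[int(m)] = v
        return t


def default_energy_specs() -> tuple[EnergySpec, EnergySpec]:
    """Default (HE, LE) attenuation specs (120/60 kVp surrogates)."""
    he = EnergySpec("HE", dict(_DEFAULT_MU["HE"]))
    le = EnergySpec("LE", dict(_DEFAULT_MU["LE"]))
    return he, le


def validate_energy_pair(he: EnergySpec, le: EnergySpec) -> None:
    """Check mu_LE >= mu_HE for every non-air material."""
    for m in he.mu:
        if m == Material.AIR:
            continue
        if m in le.mu and le.mu[m] < he.mu[m]:
            raise ValueError(f"mu_LE < mu_HE for material {m!r}")


@dataclass(frozen=True)
class MaterialVolume:
    """3D grid of material labels with spacing and respiratory phase."""

    labels: np.ndarray  # integer grid, axes (x, y, z)
    spacing: tuple[float, float, float]  # mm per voxel
    phase: int  # 1-based respiratory phase

    def __post_init__(self):
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        if not (1 <= self.phase):
            raise ValueError("phase must be >= 1")
        codes = {int(m) for m in Material}
        present = set(np.unique(self.labels).tolist())
        if not present <= codes:
            raise ValueError(f"invalid material codes in volume: {present - codes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def material_count(self, material: Material) -> int:
        return int(np.count_nonzero(self.labels == int(material)))


@dataclass(frozen=True)
class PhantomConfig:
    """Parametric thorax geometry, in grid fractions and millimetres.

    Torso/lung/spine/rib sizes are fractions of the grid extent so the same
    anatomy scales to coarse test grids; tumor diameter and motion amplitude
    are absolute mm.
    """

    shape: tuple[int, int, int] = (160, 160, 160)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    phase_count: int = 10

    # torso elliptic cylinder (fractions of extent along x, y)
    torso_semiaxes: tuple[float, float] = (0.44, 0.36)
    # lungs: ellipsoid semi-axes and lateral center offset (fractions)
    lung_semiaxes: tuple[float, float, float] = (0.14, 0.20, 0.32)
    lung_offset_x: float = 0.20
    lung_offset_y: float = -0.03
    # spine cylinder: posterior offset and radius (fractions)
    spine_offset_y: float = 0.26
    spine_radius: float = 0.06
    # ribs
    rib_count: int = 9  # arcs per side
    rib_half_thickness_mm: float = 4.0
    rib_shell: tuple[float, float] = (0.80, 0.95)  # normalized radial band
    rib_droop_mm: float = 15.0  # inferior slope posterior -> anterior
    rib_angle_deg: tuple[float, float] = (12.0, 150.0)  # azimuth band from posterior

    # tumor + motion
    tumor_center_mm: tuple[float, float, float] | None = None  # default: in right lung
    tumor_diameter_mm: float = 10.0
    motion_amplitude_mm: float = 10.0

    energy_specs: tuple[EnergySpec, EnergySpec] = field(default_factory=default_energy_specs)

    def __post_init__(self):
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid dimensions must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.phase_count < 1:
            raise ValueError("phase_count must be >= 1")
        if self.tumor_diameter_mm <= 0:
            raise ValueError("tumor diameter must be positive")
        validate_energy_pair(*self.energy_specs)
        # tumor containment: lungs translate rigidly with the tumor, so the
        # phase-1 relative position decides containment at every phase
        c = np.asarray(self.resolved_tumor_center_mm())
        lc = self._lung_center_mm(side=1 if c[0] >= self.extent_mm()[0] / 2 else -1)
        semi = np.asarray(self.lung_semiaxes) * self.extent_mm()
        margin = semi - self.tumor_diameter_mm / 2.0
        if np.any(margin <= 0) or np.sum(((c - lc) / margin) ** 2) > 1.0:
            raise ValueError("tumor placement outside the lung")

    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def _lung_center_mm(self, side: int) -> np.ndarray:
        ex = self.extent_mm()
        return np.array(
            [
                ex[0] / 2 + side * self.lung_offset_x * ex[0],
                ex[1] / 2 + self.lung_offset_y * ex[1],
                ex[2] / 2,
            ]
        )

    def resolved_tumor_center_mm(self) -> tuple[float, float, float]:
        """Configured tumor center, or the default spot in the right lung."""
        if self.tumor_center_mm is not None:
            return self.tumor_center_mm
        c = self._lung_center_mm(side=1)
        ex = self.extent_mm()
        # slightly superior and lateral of the lung center, so the breathing
        # excursion sweeps the tumor across rib z-bands
        return (c[0] + 0.04 * ex[0], c[1], c[2] - 0.08 * ex[2])


def respiratory_displacement_mm(config: PhantomConfig, phase: float) -> float:
    """Superior–inferior displacement A*sin^2(pi*(p-1)/P) at phase p.

    Phase 1 is the full-exhale reference (zero displacement); fractional
    phases interpolate the same surrogate for continuous-time sequences.
    """
    p, amp = float(phase), config.motion_amplitude_mm
    return amp * np.sin(np.pi * (p - 1.0) / config.phase_count) ** 2


def tumor_center_mm(config: PhantomConfig, phase: float) -> np.ndarray:
    """Analytic tumor center (mm) at a given (possibly fractional) phase."""
    c = np.asarray(config.resolved_tumor_center_mm(), dtype=float).copy()
    c[2] += respiratory_displacement_mm(config, phase)
    return c


def _voxel_centers_mm(config: PhantomConfig):
    grids = [
        (np.arange(n) + 0.5) * s
        for n, s in zip(config.shape, config.spacing)
    ]
    return np.meshgrid(*grids, indexing="ij", sparse=True)


def build_phantom(config: PhantomConfig, phase: int) -> MaterialVolume:
    """Rasterize the thorax at one respiratory phase.

    Deterministic: the geometry is analytic and carries no randomness.
    Lungs and tumor translate together by the respiratory surrogate; torso,
    ribs and spine are static.
    """
    phase = int(phase)
    if not 1 <= phase <= config.phase_count:
        raise ValueError(f"phase {phase} outside 1..{config.phase_count}")

    ex = config.extent_mm()
    cx, cy = ex[0] / 2, ex[1] / 2
    x, y, z = _voxel_centers_mm(config)
    d = respiratory_displacement_mm(config, phase)

    labels = np.zeros(config.shape, dtype=np.int8)

    def bc(mask: np.ndarray) -> np.ndarray:
        return np.broadcast_to(mask, config.shape)

    # torso: elliptic cylinder along z
    ax_t, ay_t = config.torso_semiaxes[0] * ex[0], config.torso_semiaxes[1] * ex[1]
    nx_, ny_ = (x - cx) / ax_t, (y - cy) / ay_t
    rho2 = nx_ * nx_ + ny_ * ny_
    torso = bc(rho2 <= 1.0)
    labels[torso] = Material.SOFT_TISSUE

    # lungs: two ellipsoids, translated inferiorly with breathing
    semi = np.asarray(config.lung_semiaxes) * ex
    for side in (-1, 1):
        lc = config._lung_center_mm(side)
        m = (
            ((x - lc[0]) / semi[0]) ** 2
            + ((y - lc[1]) / semi[1]) ** 2
            + ((z - (lc[2] + d)) / semi[2]) ** 2
        ) <= 1.0
        labels[bc(m) & torso] = Material.LUNG

    # ribs: curved arcs on a normalized radial shell of the torso section,
    # drooping inferiorly from posterior to anterior
    rho = np.sqrt(rho2)
    phi = np.arctan2(np.abs(nx_), ny_)  # 0 at posterior (+y), pi at anterior
    a0, a1 = np.deg2rad(config.rib_angle_deg)
    shell = (rho >= config.rib_shell[0]) & (rho <= config.rib_shell[1])
    band = (phi >= a0) & (phi <= a1)
    z0, z1 = 0.22 * ex[2], 0.78 * ex[2]
    zk = np.linspace(z0, z1, config.rib_count)
    frac = (phi - a0) / (a1 - a0)
    rib_any = np.zeros(np.broadcast_shapes(shell.shape, (np.shape(z)[0] if False else 1,)) if False else np.broadcast(shell, z).shape, dtype=bool)
    for k in range(config.rib_count):
        zc = zk[k] + config.rib_droop_mm * frac
        rib_any |= shell & band & (np.abs(z - zc) <= config.rib_half_thickness_mm)
    labels[bc(rib_any) & torso] = Material.RIB

    # spine: posterior cylinder along z
    sy = cy + config.spine_offset_y * ex[1]
    sr = config.spine_radius * min(ex[0], ex[1])
    spine = ((x - cx) ** 2 + (y - sy) ** 2) <= sr**2
    labels[bc(spine) & torso] = Material.SPINE

    # tumor: sphere, rigidly attached to the lung tissue
    tc = tumor_center_mm(config, phase)
    r = config.tumor_diameter_mm / 2.0
    tum = ((x - tc[0]) ** 2 + (y - tc[1]) ** 2 + (z - tc[2]) ** 2) <= r**2
    labels[bc(tum)] = Material.TUMOR

    vol = MaterialVolume(labels=labels, spacing=tuple(config.spacing), phase=phase)
    for m in (Material.SOFT_TISSUE, Material.LUNG, Material.RIB, Material.SPINE, Material.TUMOR):
        if vol.material_count(m) == 0:
            raise ValueError(f"degenerate phantom: no {m.name} voxels on this grid")
    return vol


def attenuation_volume(vol: MaterialVolume, spec: EnergySpec) -> np.ndarray:
    """Map material labels to linear attenuation coefficients (1/cm).

    Element-wise lookup; air maps to exactly 0.  Raises on labels missing
    from the spec.
    """
    present = np.unique(vol.labels)
    known = {int(m) for m in spec.mu}
    for lab in present.tolist():
        if lab not in known:
            raise ValueError(f"no attenuation coefficient for material label {lab}")
    table = spec.table(n=int(present.max()) + 1)
    return table[vol.labels].astype(np.float64)


def bone_free(spec: EnergySpec) -> EnergySpec:
    """Copy of an energy spec with rib and spine attenuation set to zero.

    Used by the bone-cancellation oracle: subtracting with the exact
    bone-cancelling weight must reproduce the projections of this spec.
    """
    mu = dict(spec.mu)
    mu[Material.RIB] = 0.0
    mu[Material.SPINE] = 0.0
    return replace(spec, mu=mu)
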