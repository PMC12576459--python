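"""CT gantry model: geometry, scan protocol, projection schedule, bowtie, source.

Conventions: world coordinates in mm, isocenter at (0, 0) in the gantry plane,
z along the table feed (toward the head). Gantry angle 0 is 12 o'clock (+y);
rotation is clockwise viewed from the patient's feet by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .attenuation import element_table
from .spectrum import Spectrum, sample_energy

__all__ = [
    "TableModel",
    "ScannerGeometry",
    "ScanProtocol",
    "BowtieProfile",
    "projection_schedule",
    "source_position",
    "bowtie_from_fixed_tube_measurements",
    "load_default_bowtie",
    "initial_photons",
]


@dataclass(frozen=True)
class TableModel:
    """Patient table: carbon-fiber shell around a foam core."""

    shell_material: str = "carbon_fiber"
    shell_density: float = 1.6          # g/cm^3
    shell_thickness_mm: float = 2.0     # not stated by vendor; configurable
    core_material: str = "foam"
    core_density: float = 0.015
    core_thickness_mm: float = 46.0
    top_offset_mm: float = -180.0       # y of the table top surface


@dataclass(frozen=True)
class ScannerGeometry:
    source_to_isocenter_cm: float = 62.6
    source_to_detector_cm: float = 110.0
    fan_angle_deg: float = 47.0
    beam_width_mm: float = 80.0
    start_angle_deg: float = 0.0        # 0 = 12 o'clock
    clockwise: bool = True
    table: TableModel = field(default_factory=TableModel)

    def __post_init__(self) -> None:
        if self.source_to_isocenter_cm >= self.source_to_detector_cm:
            raise ValueError("SID must be smaller than SDD")
        if not 0 < self.fan_angle_deg < 90:
            raise ValueError("fan angle must be in (0, 90) degrees")
        if self.beam_width_mm <= 0:
            raise ValueError("beam width must be positive")

    @property
    def sid_mm(self) -> float:
        return self.source_to_isocenter_cm * 10.0


@dataclass(frozen=True)
class ScanProtocol:
    kvp: float = 120.0
    mode: str = "axial"                 # "axial" | "helical"
    tube_current_ma: float = 100.0
    rotation_time_s: float = 1.0
    pitch: float = 1.0
    scan_length_mm: float = 0.0
    projections_per_rotation: int = 40

    def __post_init__(self) -> None:
        if self.mode not in ("axial", "helical"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.projections_per_rotation < 1:
            raise ValueError("projections_per_rotation must be >= 1")

    @property
    def angular_step_deg(self) -> float:
        return 360.0 / self.projections_per_rotation

    def table_feed_mm(self, beam_width_mm: float) -> float:
        return self.pitch * beam_width_mm


def projection_schedule(protocol: ScanProtocol,
                        geometry: ScannerGeometry) -> np.ndarray:
    """Ordered (gantry_angle_deg, table_z_mm) pairs for the whole scan.

    Axial: one rotation at fixed z. Helical: z advances by
    (pitch x beam_width) / projections_per_rotation per step; the projection
    count is ceil(scan_length / table_feed x projections_per_rotation) so the
    schedule covers the full scan length.
    """
    npr = protocol.projections_per_rotation
    step = protocol.angular_step_deg
    start = geometry.start_angle_deg
    sign = -1.0 if geometry.clockwise else 1.0
    if protocol.mode == "axial":
        k = np.arange(npr)
        angles = np.mod(start + sign * k * step, 360.0)
        return np.column_stack([angles, np.zeros(npr)])
    if protocol.scan_length_mm <= 0:
        raise ValueError("scan_length must be positive in helical mode")
    feed = protocol.table_feed_mm(geometry.beam_width_mm)
    rotations = protocol.scan_length_mm / feed
    n = math.ceil(rotations * npr - 1e-9)
    k = np.arange(n)
    angles = np.mod(start + sign * k * step, 360.0)
    z = k * feed / npr
    return np.column_stack([angles, z])


def source_position(gantry_angle_deg: float, table_z_mm: float,
                    geometry: ScannerGeometry) -> np.ndarray:
    """Focal-spot position in mm; angle 0 maps to +y (12 o'clock)."""
    r = geometry.sid_mm
    sign = -1.0 if geometry.clockwise else 1.0
    a = math.radians(gantry_angle_deg)
    return np.array([sign * r * math.sin(a), r * math.cos(a), table_z_mm])


@dataclass(frozen=True)
class BowtieProfile:
    """Equivalent aluminum thickness (mm) versus fan angle (degrees)."""

    fan_angles_deg: np.ndarray
    thickness_mm: np.ndarray
    symmetric: bool = True
    material: str = "aluminum"
    density: float = 2.7

    def __post_init__(self) -> None:
        if np.any(self.thickness_mm < 0):
            raise ValueError("bowtie thickness must be non-negative")
        if np.any(np.diff(self.fan_angles_deg) <= 0):
            raise ValueError("fan angles must be strictly increasing")

    def thickness_at(self, theta_deg) -> np.ndarray:
        theta = np.abs(theta_deg) if self.symmetric else np.asarray(theta_deg, float)
        return np.interp(theta, self.fan_angles_deg, self.thickness_mm)

    def transmission(self, theta_deg, energy_kev) -> np.ndarray:
        """exp(-mu_Al(E) * rho * t(theta)), broadcasting theta against energy."""
        al = element_table("Al")
        mu = al.mu_rho_at(energy_kev) * self.density  # 1/cm at rho=2.7
        return np.exp(-mu * self.thickness_at(theta_deg) / 10.0)

    @classmethod
    def flat(cls) -> "BowtieProfile":
        return cls(np.array([0.0, 45.0]), np.zeros(2))


def bowtie_from_fixed_tube_measurements(offsets_mm, exposure_ratios,
                                        mu_al_eff_per_cm: float,
                                        geometry: ScannerGeometry,
                                        symmetric: bool = True) -> BowtieProfile:
    """Fixed-tube bowtie estimate: chamber raised through the fan in the
    isocenter plane; each exposure ratio (relative to the unattenuated center
    ray) inverts to an equivalent Al thickness at fan angle atan(y / SID).
    """
    offsets = np.asarray(offsets_mm, dtype=float)
    ratios = np.asarray(exposure_ratios, dtype=float)
    if np.any(ratios > 1.0):
        raise ValueError("exposure ratio > 1 implies amplification")
    if np.any(ratios <= 0.0):
        raise ValueError("exposure ratio must be positive")
    theta = np.degrees(np.arctan2(offsets, geometry.sid_mm))
    t_mm = -np.log(ratios) / mu_al_eff_per_cm * 10.0
    order = np.argsort(theta)
    return BowtieProfile(theta[order], t_mm[order], symmetric=symmetric)


def load_default_bowtie() -> BowtieProfile:
    """Parametric body bowtie shipped with the package (CSV fixture)."""
    ref = resources.files("ctdosim.data").joinpath("bowtie_body.csv")
    with ref.open("rb") as fh:
        raw = np.genfromtxt(fh, delimiter=",", names=True)
    return BowtieProfile(np.ascontiguousarray(raw["fan_angle_deg"]),
                         np.ascontiguousarray(raw["thickness_mm_al"]))


def initial_photons(n: int, spectrum: Spectrum, bowtie: BowtieProfile | None,
                    geometry: ScannerGeometry, gantry_angle_deg: float,
                    table_z_mm: float, rng: np.random.Generator,
                    bowtie_mode: str = "weight"):
    """Sample source photons for one projection.

    Directions are uniform in fan angle over +-fan_angle/2 and uniform in the
    z-tangent so rays span the collimated beam width at the isocenter plane.
    The bowtie is applied as a multiplicative statistical weight by default,
    or by rejection when ``bowtie_mode='rejection'``.

    Returns (positions (n,3) mm, directions (n,3), energies keV, weights).
    """
    src = source_position(gantry_angle_deg, table_z_mm, geometry)
    to_iso = -src.copy()
    to_iso[2] = 0.0
    to_iso /= np.linalg.norm(to_iso)
    # in-plane unit vector perpendicular to the central ray
    perp = np.array([-to_iso[1], to_iso[0], 0.0])

    half_fan = 0.5 * math.radians(geometry.fan_angle_deg)
    theta = rng.uniform(-half_fan, half_fan, n)
    half_tan_z = (geometry.beam_width_mm / 2.0) / geometry.sid_mm
    tz = rng.uniform(-half_tan_z, half_tan_z, n)

    d = (np.cos(theta)[:, None] * to_iso[None, :]
         + np.sin(theta)[:, None] * perp[None, :])
    d[:, 2] += tz * np.cos(theta)
    d /= np.linalg.norm(d, axis=1, keepdims=True)

    energies = sample_energy(spectrum.normalized(), rng, size=n)
    weights = np.ones(n)
    if bowtie is not None:
        trans = bowtie.transmission(np.degrees(theta), energies)
        if bowtie_mode == "weight":
            weights = trans
        elif bowtie_mode == "rejection":
            keep = rng.random(n) < trans
            # killed photons stay in the arrays with zero weight so the
            # emitted count is unchanged
            weights = keep.astype(float)
        else:
            raise ValueError(f"unknown bowtie_mode {bowtie_mode!r}")
    positions = np.broadcast_to(src, (n, 3)).copy()
    return positions, d, energies, weights
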