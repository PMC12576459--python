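"""Dosimetry metrics: CTDI quantities, normalization, organ-dose reports,
dosimeter-side corrections, and comparison statistics.

All comparison quantities (relative difference, dose reduction) are evaluated
on full-precision inputs; printed-table rounding is the caller's concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attenuation import material_table
from .phantom import VoxelPhantom
from .transport import KEV_TO_JOULE, TallyResult

__all__ = [
    "CTDIResult",
    "DoseReport",
    "ctdi100_from_tally",
    "ctdi100_from_profile",
    "ctdi_w",
    "normalization_factor",
    "relative_difference",
    "dose_reduction_percent",
    "rpld_correction_factor",
    "rpld_organ_dose",
    "muen_tissue_air_ratio",
    "chamber_dose_gy_per_photon",
    "organ_dose_report",
]


@dataclass(frozen=True)
class CTDIResult:
    """CTDI_100 set (mGy) for the standard five chamber positions."""

    ctdi100_center: float
    ctdi100_periphery: tuple[float, float, float, float]   # 12/3/6/9 o'clock
    beam_width_mm: float
    ctdi_air: float | None = None

    @property
    def ctdi_w(self) -> float:
        return ctdi_w(self.ctdi100_center, self.ctdi100_periphery)


def ctdi100_from_tally(mean_chamber_dose_mgy: float, beam_width_mm: float,
                       chamber_length_mm: float = 100.0) -> float:
    """CTDI_100 = (1/NT) * integral of D(z) over the 100 mm chamber.

    With a uniform chamber tally the integral is mean dose x chamber length.
    """
    if beam_width_mm <= 0:
        raise ValueError("beam width must be positive")
    return mean_chamber_dose_mgy * chamber_length_mm / beam_width_mm


def ctdi100_from_profile(z_mm: np.ndarray, dose_mgy: np.ndarray,
                         beam_width_mm: float,
                         chamber_length_mm: float = 100.0) -> float:
    """CTDI_100 from a sampled dose profile D(z), integrated over +-50 mm."""
    if beam_width_mm <= 0:
        raise ValueError("beam width must be positive")
    z = np.asarray(z_mm, dtype=float)
    d = np.asarray(dose_mgy, dtype=float)
    half = chamber_length_mm / 2.0
    if z.min() > -half or z.max() < half:
        raise ValueError("dose profile does not cover the chamber length")
    sel = (z >= -half) & (z <= half)
    return float(np.trapezoid(d[sel], z[sel])) / beam_width_mm


def ctdi_w(center: float, periphery) -> float:
    """Weighted CTDI: one third center plus two thirds mean periphery."""
    periphery = np.asarray(periphery, dtype=float)
    if center < 0 or np.any(periphery < 0):
        raise ValueError("CTDI components must be non-negative")
    return float(center / 3.0 + 2.0 / 3.0 * periphery.mean())


def normalization_factor(ctdi_air_measured: float,
                         ctdi_air_simulated: float) -> float:
    """NF = measured CTDI_air / simulated CTDI_air (per source photon, per
    calibration mAs). Downstream absolute dose = tally x NF x protocol-mAs
    relative to the calibration mAs."""
    if ctdi_air_simulated <= 0:
        raise ValueError("simulated CTDI_air must be positive")
    return ctdi_air_measured / ctdi_air_simulated


def relative_difference(simulated: float, measured: float) -> float:
    """Signed percentage relative difference, measured as reference."""
    if measured == 0:
        raise ValueError("measured dose must be nonzero")
    return (simulated - measured) / measured * 100.0


def dose_reduction_percent(dose_fixed: float, dose_tcm: float) -> float:
    """Percentage dose reduction of a TCM run relative to fixed tube current."""
    if dose_fixed <= 0:
        raise ValueError("fixed-current dose must be positive")
    return (dose_fixed - dose_tcm) / dose_fixed * 100.0


def free_in_air_kerma_per_photon(spectrum, geometry, bowtie=None) -> float:
    """Air kerma at the isocenter per emitted source photon (Gy), primary only.

    Free-in-air the chamber sees essentially unscattered fluence, so the kerma
    is a deterministic spectrum integral: the point fluence for one photon
    emitted uniformly over the collimated cone is 1 / (SID^2 * dOmega), and
    each energy contributes E * (muen/rho)_air, attenuated by the bowtie's
    central-ray transmission. Analog Monte Carlo scoring of a small air cavity
    is hopeless at desk-scale budgets; this estimator replaces it while
    keeping the normalization-factor contract intact.
    """
    s = spectrum.normalized()
    centers = s.bin_centers
    muen = material_table("air").muen_rho_at(centers)  # cm^2/g
    w = bowtie.transmission(0.0, centers) if bowtie is not None else 1.0
    fan_rad = np.radians(geometry.fan_angle_deg)
    d_omega = fan_rad * (geometry.beam_width_mm / geometry.sid_mm)
    fluence_cm2 = 1.0 / ((geometry.source_to_isocenter_cm) ** 2 * d_omega)
    e_joule = centers * KEV_TO_JOULE
    kerma_per_g = np.sum(s.relative_fluence * w * e_joule * muen) * fluence_cm2
    return float(kerma_per_g * 1000.0)  # J/g -> J/kg = Gy


def rpld_correction_factor(k_ic: float, k_rpld: float) -> float:
    """Dosimeter correction factor: chamber kerma over dosimeter kerma."""
    if k_rpld <= 0:
        raise ValueError("dosimeter kerma must be positive")
    return k_ic / k_rpld


def muen_tissue_air_ratio(energy_kev: float,
                          tissue: str = "soft_tissue") -> float:
    """(muen/rho)_tissue / (muen/rho)_air at the given (effective) energy."""
    t = material_table(tissue).muen_rho_at(energy_kev)
    a = material_table("air").muen_rho_at(energy_kev)
    return float(t / a)


def rpld_organ_dose(readings_mgy, background_mgy: float, correction: float,
                    muen_ratio: float) -> float:
    """Mean organ dose from dosimeter readings:
    mean_i (M_i - M_b) * C * (muen/rho)_tissue / (muen/rho)_air.
    """
    readings = np.asarray(readings_mgy, dtype=float)
    if readings.size == 0:
        raise ValueError("no dosimeter readings")
    net = readings - background_mgy
    if np.any(net < 0):
        import warnings

        warnings.warn("reading below background", stacklevel=2)
    return float(np.mean(net) * correction * muen_ratio)


def chamber_dose_gy_per_photon(tally: TallyResult, phantom: VoxelPhantom,
                               label: int) -> float:
    """Absorbed dose per source photon (Gy) in one labeled chamber region."""
    doses = tally.label_dose_gy_per_photon(phantom)
    if label not in doses:
        raise ValueError(f"label {label} has no mass in phantom")
    return doses[label]


@dataclass
class DoseReport:
    """Per-organ absolute doses with uncertainties and comparison columns."""

    organ_dose_mgy: dict[str, float]
    rel_uncertainty: dict[str, float] = field(default_factory=dict)
    measured_mgy: dict[str, float] = field(default_factory=dict)
    normalization_factor: float = 1.0
    mas_scale: float = 1.0
    protocol: str = ""

    def relative_differences(self) -> dict[str, float]:
        return {o: relative_difference(d, self.measured_mgy[o])
                for o, d in self.organ_dose_mgy.items() if o in self.measured_mgy}

    def dose_reductions_vs(self, fixed: "DoseReport") -> dict[str, float]:
        return {o: dose_reduction_percent(fixed.organ_dose_mgy[o], d)
                for o, d in self.organ_dose_mgy.items()
                if o in fixed.organ_dose_mgy}

    def to_rows(self) -> list[dict]:
        rows = []
        for organ, dose in self.organ_dose_mgy.items():
            rows.append({
                "organ": organ,
                "dose_mgy": dose,
                "rel_uncertainty": self.rel_uncertainty.get(organ),
                "measured_mgy": self.measured_mgy.get(organ),
                "rd_percent": (relative_difference(dose, self.measured_mgy[organ])
                               if organ in self.measured_mgy else None),
            })
        return rows

    def to_csv(self, path) -> None:
        import csv

        rows = self.to_rows()
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=rows[0].keys())
            writer.writeheader()
            writer.writerows(rows)


def organ_dose_report(tally: TallyResult, phantom: VoxelPhantom,
                      nf: float, mas_scale: float,
                      protocol: str = "") -> DoseReport:
    """Convert a scan tally into absolute per-organ doses (mGy).

    Dose = (label energy / label mass) per source photon x NF x mAs scale.
    NF carries the Gy-per-(Gy/source-photon) calibration at the calibration
    mAs; ``mas_scale`` is protocol mAs relative to calibration mAs.
    """
    doses = {}
    uncert = {}
    per_photon = tally.label_dose_gy_per_photon(phantom)
    names = phantom.label_names or {}
    rel = None
    if tally.batch_label_edep is not None:
        rel = tally.relative_uncertainty()
    for label, d in per_photon.items():
        name = names.get(label, f"label_{label}")
        doses[name] = d * nf * mas_scale * 1000.0  # Gy -> mGy
        if rel is not None:
            uncert[name] = float(rel[label])
    if not doses:
        raise ValueError("no labeled region has mass")
    return DoseReport(doses, uncert, normalization_factor=nf,
                      mas_scale=mas_scale, protocol=protocol)
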