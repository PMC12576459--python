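"""X-ray tube spectrum model: generation, HVL calibration, effective energy, sampling.

The bremsstrahlung shape is a Kramers continuum with tungsten self-filtration
set by the target angle, plus the tungsten K fluorescence lines folded into
their 0.5 keV bins. The model is deliberately simple: the one measured
constraint a spectrum must reproduce is its first half-value layer, which
``calibrate_filtration`` enforces by solving for the added aluminum.

HVL is defined on air-kerma-weighted transmission (fluence x energy x
(muen/rho)_air), matching what a calibrated ionization chamber reads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .attenuation import AttenuationTable, element_table, material_table

__all__ = [
    "Spectrum",
    "generate_spectrum",
    "first_hvl",
    "hvl_thickness",
    "calibrate_filtration",
    "effective_energy",
    "sample_energy",
]

BIN_WIDTH_KEV = 0.5
ENERGY_CUTOFF_KEV = 5.0

# Tungsten K fluorescence: (energy keV, relative intensity)
_W_K_LINES = ((57.98, 0.58), (59.32, 1.00), (67.24, 0.33), (69.10, 0.08))
_W_K_EDGE_KEV = 69.525


@dataclass(frozen=True)
class Spectrum:
    """Binned relative photon fluence, uniform 0.5 keV bins over (cutoff, kvp]."""

    bin_edges: np.ndarray          # keV, length n_bins + 1
    relative_fluence: np.ndarray   # unitless, per bin
    kvp: float
    target_angle: float            # degrees
    added_filtration_al: float     # mm

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, BIN_WIDTH_KEV, atol=1e-9):
            raise ValueError("bin width must be uniformly 0.5 keV")
        if np.any(self.relative_fluence < 0):
            raise ValueError("fluence must be non-negative")
        if self.bin_edges.shape[0] != self.relative_fluence.shape[0] + 1:
            raise ValueError("edges/fluence length mismatch")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean_energy(self) -> float:
        f = self.relative_fluence
        return float(np.sum(self.bin_centers * f) / np.sum(f))

    def normalized(self) -> "Spectrum":
        total = self.relative_fluence.sum()
        if total == 0:
            raise ValueError("all-zero spectrum cannot be normalized")
        return replace(self, relative_fluence=self.relative_fluence / total)

    def filtered(self, table: AttenuationTable, thickness_mm: float) -> "Spectrum":
        """Spectrum attenuated by ``thickness_mm`` of the table's material."""
        trans = np.exp(-table.mu_at(self.bin_centers) * thickness_mm / 10.0)
        return replace(self, relative_fluence=self.relative_fluence * trans)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.bin_centers, self.relative_fluence]),
                   delimiter=",", header="bin_center_kev,relative_fluence", comments="")

    @classmethod
    def from_csv(cls, path, kvp: float, target_angle: float = 10.0,
                 added_filtration_al: float = 0.0) -> "Spectrum":
        raw = np.genfromtxt(path, delimiter=",", names=True)
        centers = np.atleast_1d(raw["bin_center_kev"])
        fluence = np.atleast_1d(raw["relative_fluence"])
        edges = np.concatenate([centers - BIN_WIDTH_KEV / 2,
                                [centers[-1] + BIN_WIDTH_KEV / 2]])
        return cls(edges, fluence, kvp, target_angle, added_filtration_al)


def generate_spectrum(kvp: float, target_angle: float = 10.0,
                      added_filtration_al: float = 0.0,
                      inherent_al_mm: float = 1.0,
                      self_filtration_w_um: float = 4.0) -> Spectrum:
    """Kramers continuum + W K lines, filtered by inherent and added aluminum.

    ``self_filtration_w_um`` is the effective tungsten depth traversed at 90
    degrees takeoff; the actual path scales as 1/tan(target_angle).
    """
    if not 40.0 <= kvp <= 150.0:
        raise ValueError(f"unsupported kvp {kvp} (need 40-150)")
    if added_filtration_al < 0:
        raise ValueError("negative filtration")

    edges = np.round(np.arange(ENERGY_CUTOFF_KEV, kvp + BIN_WIDTH_KEV / 2,
                               BIN_WIDTH_KEV), 6)
    centers = 0.5 * (edges[:-1] + edges[1:])

    fluence = np.clip(kvp - centers, 0.0, None) / centers  # Kramers N(E) dE

    w = element_table("W")
    w_path_mm = self_filtration_w_um * 1e-3 / np.tan(np.radians(target_angle))
    fluence *= np.exp(-w.mu_at(centers) * w_path_mm / 10.0)

    if kvp > _W_K_EDGE_KEV:
        # simple overvoltage scaling for the characteristic yield
        k_total = 0.35 * fluence.sum() * (kvp / _W_K_EDGE_KEV - 1.0) ** 1.65
        weights = np.array([w for _, w in _W_K_LINES])
        weights /= weights.sum()
        for (e_line, _), frac in zip(_W_K_LINES, weights / 1.0):
            idx = int(np.searchsorted(edges, e_line, side="right")) - 1
            fluence[idx] += k_total * frac

    spec = Spectrum(edges, fluence, float(kvp), float(target_angle),
                    float(added_filtration_al))
    al = element_table("Al")
    return spec.filtered(al, inherent_al_mm + added_filtration_al)


def _kerma_response(spectrum: Spectrum, attenuator: AttenuationTable,
                    thickness_mm: float, muen_air: np.ndarray,
                    centers: np.ndarray) -> float:
    trans = np.exp(-attenuator.mu_at(centers) * thickness_mm / 10.0)
    return float(np.sum(spectrum.relative_fluence * centers * muen_air * trans))


def hvl_thickness(spectrum: Spectrum, attenuator: AttenuationTable,
                  fraction: float = 0.5, t_max_mm: float = 100.0) -> float:
    """Thickness (mm) reducing air-kerma-weighted transmission to ``fraction``.

    Solved by bisection to a relative kerma tolerance of 1e-8.
    """
    if spectrum.relative_fluence.sum() <= 0:
        raise ValueError("empty spectrum")
    centers = spectrum.bin_centers
    muen_air = material_table("air").muen_rho_at(centers)
    k0 = _kerma_response(spectrum, attenuator, 0.0, muen_air, centers)
    target = fraction * k0
    lo, hi = 0.0, t_max_mm
    if _kerma_response(spectrum, attenuator, hi, muen_air, centers) > target:
        raise ValueError(f"search interval [0, {t_max_mm}] mm does not bracket HVL")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        k = _kerma_response(spectrum, attenuator, mid, muen_air, centers)
        if abs(k - target) / k0 < 1e-8:
            return mid
        if k > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def first_hvl(spectrum: Spectrum, attenuator: AttenuationTable | None = None) -> float:
    """First half-value layer in mm of the attenuator (default aluminum)."""
    if attenuator is None:
        attenuator = element_table("Al")
    return hvl_thickness(spectrum, attenuator, 0.5)


def calibrate_filtration(kvp: float, target_angle: float, target_hvl: float,
                         bracket_mm: tuple[float, float] = (0.0, 20.0),
                         tol_mm: float = 0.005, **gen_kwargs) -> float:
    """Added Al filtration (mm) whose spectrum has the requested first HVL."""
    al = element_table("Al")

    def f(t: float) -> float:
        return first_hvl(generate_spectrum(kvp, target_angle, t, **gen_kwargs), al) - target_hvl

    lo, hi = bracket_mm
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if flo * fhi > 0:
        raise ValueError(
            f"target HVL {target_hvl} mm Al not bracketed by filtration in {bracket_mm}")
    while hi - lo > tol_mm:
        mid = 0.5 * (lo + hi)
        if f(mid) * flo <= 0:
            hi = mid
        else:
            lo, flo = mid, f(lo)
    return 0.5 * (lo + hi)


def effective_energy(hvl_al_mm: float,
                     al_table: AttenuationTable | None = None) -> float:
    """Monoenergetic energy (keV) with the same HVL in aluminum.

    Inverts mu_Al(E) = ln2 / HVL on the bundled table (log-log, monotone over
    4-150 keV where Al has no edges).
    """
    if hvl_al_mm <= 0:
        raise ValueError("hvl must be positive")
    if al_table is None:
        al_table = element_table("Al")
    mu_rho_target = np.log(2.0) / (hvl_al_mm / 10.0) / al_table.density
    grid_e, grid_mu = al_table.energies_kev, al_table.mu_rho
    if not grid_mu[-1] <= mu_rho_target <= grid_mu[0]:
        raise ValueError(f"hvl {hvl_al_mm} mm implies mu/rho outside table range")
    # mu is decreasing with E: interpolate E(log mu) on reversed arrays
    le = np.interp(np.log(mu_rho_target), np.log(grid_mu[::-1]), np.log(grid_e[::-1]))
    return float(np.exp(le))


def sample_energy(spectrum: Spectrum, rng: np.random.Generator,
                  size: int | None = None) -> np.ndarray | float:
    """Draw photon energies by inverse-CDF over bins, uniform within a bin."""
    f = spectrum.relative_fluence
    total = f.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum")
    cdf = np.cumsum(f) / total
    n = 1 if size is None else size
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="right")
    lo = spectrum.bin_edges[idx]
    e = lo + rng.random(n) * BIN_WIDTH_KEV
    return float(e[0]) if size is None else e
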