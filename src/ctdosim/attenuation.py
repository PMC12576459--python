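"""Photon attenuation data: element tables, material mixtures, log-log interpolation.

Element cross sections (photoelectric, incoherent, coherent, total, mass
energy-absorption; all cm^2/g) are bundled as CSV files on a 0.25 keV grid
from 4 to 150 keV. Materials are element mass-fraction mixtures combined with
the standard mixture rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "AttenuationTable",
    "Material",
    "MATERIALS",
    "element_table",
    "material_table",
    "material_partial_mu_rho",
]

_ELEMENT_CACHE: dict[str, dict[str, np.ndarray]] = {}

_COLUMNS = (
    "energy_kev",
    "photoelectric_cm2_g",
    "incoherent_cm2_g",
    "coherent_cm2_g",
    "total_cm2_g",
    "energy_absorption_cm2_g",
)


def _load_element(symbol: str) -> dict[str, np.ndarray]:
    if symbol not in _ELEMENT_CACHE:
        ref = resources.files("ctdosim.data.elements").joinpath(f"{symbol}.csv")
        with ref.open("rb") as fh:
            raw = np.genfromtxt(fh, delimiter=",", names=True)
        _ELEMENT_CACHE[symbol] = {name: np.ascontiguousarray(raw[name]) for name in _COLUMNS}
    return _ELEMENT_CACHE[symbol]


def _loglog_interp(e: np.ndarray, grid_e: np.ndarray, grid_y: np.ndarray) -> np.ndarray:
    """Interpolate y(e) linearly in log-log space; linear extrapolation in log."""
    le = np.log(np.asarray(e, dtype=float))
    return np.exp(np.interp(le, np.log(grid_e), np.log(grid_y)))


@dataclass(frozen=True)
class AttenuationTable:
    """Mass attenuation and energy-absorption coefficients for one material."""

    name: str
    energies_kev: np.ndarray
    mu_rho: np.ndarray       # cm^2/g
    muen_rho: np.ndarray     # cm^2/g
    density: float           # g/cm^3

    def __post_init__(self) -> None:
        if np.any(np.diff(self.energies_kev) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(self.mu_rho <= 0) or np.any(self.muen_rho <= 0):
            raise ValueError("coefficients must be strictly positive")

    def mu_rho_at(self, energy_kev) -> np.ndarray:
        return _loglog_interp(energy_kev, self.energies_kev, self.mu_rho)

    def muen_rho_at(self, energy_kev) -> np.ndarray:
        return _loglog_interp(energy_kev, self.energies_kev, self.muen_rho)

    def mu_at(self, energy_kev) -> np.ndarray:
        """Linear attenuation coefficient, 1/cm."""
        return self.mu_rho_at(energy_kev) * self.density


@dataclass(frozen=True)
class Material:
    """Element mass-fraction mixture with a reference density (g/cm^3)."""

    name: str
    composition: dict[str, float]
    density: float
    hu_representative: float = 0.0  # HU used when rendering synthetic CT

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if not np.isclose(total, 1.0, atol=5e-3):
            raise ValueError(f"{self.name}: mass fractions sum to {total}")


MATERIALS: dict[str, Material] = {
    m.name: m
    for m in [
        Material("air", {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012827},
                 0.0012048, hu_representative=-1000.0),
        Material("water", {"H": 0.111894, "O": 0.888106}, 1.0, hu_representative=0.0),
        Material("soft_tissue", {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708,
                                 "Na": 0.002, "P": 0.003, "S": 0.003, "Cl": 0.002,
                                 "K": 0.003}, 1.06, hu_representative=40.0),
        Material("adipose", {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278,
                             "Na": 0.001, "S": 0.001, "Cl": 0.001}, 0.95,
                 hu_representative=-70.0),
        Material("lung_tissue", {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749,
                                 "Na": 0.002, "P": 0.002, "S": 0.003, "Cl": 0.003,
                                 "K": 0.002}, 0.26, hu_representative=-700.0),
        Material("bone_cortical", {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435,
                                   "Na": 0.001, "Mg": 0.002, "P": 0.103, "S": 0.003,
                                   "Ca": 0.225}, 1.92, hu_representative=800.0),
        Material("pmma", {"H": 0.080538, "C": 0.599848, "O": 0.319614}, 1.19,
                 hu_representative=120.0),
        Material("aluminum", {"Al": 1.0}, 2.699, hu_representative=2639.0),
        Material("carbon_fiber", {"C": 1.0}, 1.6, hu_representative=600.0),
        Material("foam", {"H": 0.077418, "C": 0.922582}, 0.015, hu_representative=-985.0),
        Material("tungsten", {"W": 1.0}, 17.0, hu_representative=3000.0),
    ]
}

_MATERIAL_TABLE_CACHE: dict[str, AttenuationTable] = {}


def element_table(symbol: str) -> AttenuationTable:
    """Attenuation table for a pure element at its catalog density (Al only has one)."""
    d = _load_element(symbol)
    density = {"Al": 2.699, "W": 19.3, "C": 2.0}.get(symbol, 1.0)
    return AttenuationTable(symbol, d["energy_kev"], d["total_cm2_g"],
                            d["energy_absorption_cm2_g"], density)


def _mix(composition: dict[str, float], column: str) -> np.ndarray:
    acc = None
    for sym, frac in composition.items():
        d = _load_element(sym)
        contrib = frac * d[column]
        acc = contrib if acc is None else acc + contrib
    return acc


def material_table(name: str, density: float | None = None) -> AttenuationTable:
    """Total mu/rho and muen/rho table for a catalog material."""
    if name not in _MATERIAL_TABLE_CACHE:
        mat = MATERIALS[name]
        grid = _load_element(next(iter(mat.composition)))["energy_kev"]
        _MATERIAL_TABLE_CACHE[name] = AttenuationTable(
            name, grid, _mix(mat.composition, "total_cm2_g"),
            _mix(mat.composition, "energy_absorption_cm2_g"), mat.density)
    table = _MATERIAL_TABLE_CACHE[name]
    if density is not None and density != table.density:
        table = AttenuationTable(name, table.energies_kev, table.mu_rho,
                                 table.muen_rho, density)
    return table


def material_partial_mu_rho(name: str) -> dict[str, np.ndarray]:
    """Partial mass attenuation coefficients on the bundled energy grid.

    Returns arrays keyed ``energy_kev``, ``photoelectric``, ``incoherent``,
    ``coherent`` (cm^2/g) for the named catalog material.
    """
    mat = MATERIALS[name]
    grid = _load_element(next(iter(mat.composition)))["energy_kev"]
    return {
        "energy_kev": grid,
        "photoelectric": _mix(mat.composition, "photoelectric_cm2_g"),
        "incoherent": _mix(mat.composition, "incoherent_cm2_g"),
        "coherent": _mix(mat.composition, "coherent_cm2_g"),
    }
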