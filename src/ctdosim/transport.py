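"""Monte Carlo photon transport with local energy deposition.

Photons are tracked through the voxel grid by Woodcock (delta) tracking
against a global majorant cross-section; real interactions branch into
photoelectric absorption, free-electron Klein-Nishina Compton scattering
(Kahn's method), and Thomson-shaped Rayleigh scattering. Energy transferred
to electrons is deposited at the interaction site (collision kerma); photons
falling below the 5 keV cutoff deposit their remaining energy locally.

All randomness inside the kernel comes from numba's per-call seeded legacy
generator, so a (seed, photon budget) pair is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .attenuation import MATERIALS, material_partial_mu_rho
from .geometry import (BowtieProfile, ScannerGeometry, ScanProtocol,
                       initial_photons, projection_schedule)
from .phantom import VoxelPhantom
from .spectrum import Spectrum

__all__ = [
    "TallyResult",
    "MaterialGrid",
    "run_projection",
    "run_scan",
    "transport_batch",
    "estimate_uncertainty",
    "sample_compton",
    "sample_rayleigh",
    "sample_interaction",
    "branch_probabilities",
    "compton_energy",
    "compton_scatter",
    "ENERGY_CUTOFF_KEV",
]

ENERGY_CUTOFF_KEV = 5.0
_ELECTRON_REST_KEV = 510.99895
KEV_TO_JOULE = 1.602176634e-16

_E_GRID_LO = 4.0
_E_GRID_STEP = 0.25


@dataclass
class MaterialGrid:
    """Per-material physics tables resampled onto a uniform energy grid."""

    mu_rho: np.ndarray      # (M, NE) total mass attenuation, cm^2/g
    p_photo: np.ndarray     # (M, NE) photoelectric branch probability
    p_compton: np.ndarray   # (M, NE) cumulative photo+incoherent probability
    e_lo: float
    e_step: float

    @classmethod
    def for_phantom(cls, phantom: VoxelPhantom) -> "MaterialGrid":
        tables = [material_partial_mu_rho(name) for name in phantom.materials]
        grid = tables[0]["energy_kev"]
        m = len(tables)
        mu = np.empty((m, grid.size))
        p_pe = np.empty_like(mu)
        p_pc = np.empty_like(mu)
        for i, t in enumerate(tables):
            total = t["photoelectric"] + t["incoherent"] + t["coherent"]
            mu[i] = total
            p_pe[i] = t["photoelectric"] / total
            p_pc[i] = (t["photoelectric"] + t["incoherent"]) / total
        return cls(mu, p_pe, p_pc, float(grid[0]), float(grid[1] - grid[0]))

    def majorant(self, phantom: VoxelPhantom) -> np.ndarray:
        """Global majorant linear attenuation (1/cm) per energy grid point."""
        mu_max = np.zeros(self.mu_rho.shape[1])
        for i in range(self.mu_rho.shape[0]):
            sel = phantom.material_id == i
            if not sel.any():
                continue
            rho_max = float(phantom.density[sel].max())
            mu_max = np.maximum(mu_max, self.mu_rho[i] * rho_max)
        return mu_max


@dataclass
class TallyResult:
    """Energy deposition tallies for one projection or an aggregated scan."""

    voxel_edep_kev: np.ndarray            # per-voxel keV (weighted sum, not per photon)
    label_edep_kev: np.ndarray            # (n_labels+1,) keV, index = label
    n_photons: int
    seed: int
    batch_label_edep: np.ndarray | None = None    # (n_batches, n_labels+1)
    per_projection_label_edep: np.ndarray | None = None  # (P, n_labels+1)

    def label_dose_gy_per_photon(self, phantom: VoxelPhantom) -> dict[int, float]:
        """Absorbed dose per source photon (Gy) per labeled region."""
        out = {}
        for label in range(1, self.label_edep_kev.size):
            mass_g = phantom.label_mass_g(label)
            if mass_g <= 0:
                continue
            joules = self.label_edep_kev[label] * KEV_TO_JOULE
            out[label] = joules / (mass_g * 1e-3) / self.n_photons
        return out

    def relative_uncertainty(self) -> np.ndarray:
        if self.batch_label_edep is None:
            raise ValueError("no batch sub-tallies stored")
        return estimate_uncertainty(self.batch_label_edep)

    def total_edep_kev(self) -> float:
        return float(self.label_edep_kev.sum())

    def save_h5(self, path) -> None:
        """Write the tally (voxel grid + per-region sums) to HDF5."""
        import h5py

        with h5py.File(path, "w") as f:
            f["voxel_edep_kev"] = self.voxel_edep_kev
            f["label_edep_kev"] = self.label_edep_kev
            f.attrs["n_photons"] = self.n_photons
            f.attrs["seed"] = self.seed
            if self.per_projection_label_edep is not None:
                f["per_projection_label_edep"] = self.per_projection_label_edep
            if self.batch_label_edep is not None:
                f["batch_label_edep"] = self.batch_label_edep


def export_dose_nifti(tally: TallyResult, phantom: VoxelPhantom, path) -> None:
    """Export the per-voxel dose map (Gy/source photon) as NIfTI."""
    import nibabel as nib

    mass_g = phantom.voxel_mass_g()
    with np.errstate(divide="ignore", invalid="ignore"):
        dose = np.where(mass_g > 0,
                        tally.voxel_edep_kev * KEV_TO_JOULE
                        / (mass_g * 1e-3) / tally.n_photons, 0.0)
    affine = np.diag(list(phantom.spacing) + [1.0])
    affine[:3, 3] = phantom.origin
    nib.save(nib.Nifti1Image(dose.astype(np.float32), affine), str(path))


def estimate_uncertainty(batch_tallies: np.ndarray) -> np.ndarray:
    """Relative standard error of the mean across >= 2 batch tallies."""
    batches = np.asarray(batch_tallies, dtype=float)
    n = batches.shape[0]
    if n < 2:
        raise ValueError("need at least 2 batches")
    mean = batches.mean(axis=0)
    sem = batches.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, sem / mean, 0.0)
    return rel


@njit(cache=True, inline="always")
def _kahn_cos(alpha):  # pragma: no cover
    """Kahn composition-rejection sampling of the Klein-Nishina polar angle."""
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * alpha) / (9.0 + 2.0 * alpha):
            eta = 1.0 + 2.0 * alpha * r2
            if r3 <= 4.0 * (1.0 / eta - 1.0 / (eta * eta)):
                return 1.0 - (eta - 1.0) / alpha, eta
        else:
            eta = (1.0 + 2.0 * alpha) / (1.0 + 2.0 * alpha * r2)
            mu_c = 1.0 - (eta - 1.0) / alpha
            if r3 <= 0.5 * (mu_c * mu_c + 1.0 / eta):
                return mu_c, eta


@njit(cache=True, inline="always")
def _rayleigh_cos():  # pragma: no cover
    """Thomson-shaped polar angle: pdf proportional to 1 + cos^2."""
    while True:
        mu_c = 2.0 * np.random.random() - 1.0
        if np.random.random() <= 0.5 * (1.0 + mu_c * mu_c):
            return mu_c


@njit(cache=True)
def _sample_compton_many(energy_kev, n, seed):  # pragma: no cover
    np.random.seed(seed)
    cos_t = np.empty(n)
    e_out = np.empty(n)
    alpha = energy_kev / 510.99895
    for i in range(n):
        mu_c, eta = _kahn_cos(alpha)
        cos_t[i] = mu_c
        e_out[i] = energy_kev / eta
    return cos_t, e_out


@njit(cache=True)
def _sample_rayleigh_many(n, seed):  # pragma: no cover
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _rayleigh_cos()
    return out


def sample_compton(energy_kev: float, n: int, seed: int):
    """Sample n Klein-Nishina scatters: (cos_theta, scattered energy keV)."""
    return _sample_compton_many(float(energy_kev), int(n), seed & 0x7FFFFFFF)


def sample_rayleigh(n: int, seed: int) -> np.ndarray:
    """Sample n Rayleigh (Thomson-shaped) polar-angle cosines."""
    return _sample_rayleigh_many(int(n), seed & 0x7FFFFFFF)


def compton_energy(energy_kev: float, cos_theta: float) -> float:
    """Scattered photon energy from the Compton relation."""
    alpha = energy_kev / _ELECTRON_REST_KEV
    return energy_kev / (1.0 + alpha * (1.0 - cos_theta))


def compton_scatter(energy_kev: float, rng_seed: int):
    """One Compton event: (scattered energy, polar angle rad, deposited energy)."""
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    cos_t, e_out = sample_compton(energy_kev, 1, rng_seed)
    return float(e_out[0]), float(np.arccos(cos_t[0])), float(energy_kev - e_out[0])


def sample_interaction(material: str, energy_kev, rng: np.random.Generator,
                       size: int | None = None):
    """Draw interaction branches for a material at the given energy.

    Returns 'photoelectric' | 'compton' | 'rayleigh' (array if size given),
    with probabilities proportional to the partial cross-sections.
    """
    grid = material_partial_mu_rho(material)["energy_kev"]
    if not grid[0] <= energy_kev <= grid[-1]:
        raise ValueError("energy outside cross-section tables")
    p = branch_probabilities(material, energy_kev)
    names = np.array(["photoelectric", "compton", "rayleigh"])
    cdf = np.cumsum([p[n] for n in names])
    n = 1 if size is None else size
    idx = np.minimum(np.searchsorted(cdf, rng.random(n)), 2)
    out = names[idx]
    return out[0] if size is None else out


def branch_probabilities(material: str, energy_kev: float) -> dict[str, float]:
    """Partial/total cross-section ratios at one energy (sums to 1)."""
    t = material_partial_mu_rho(material)
    grid = t["energy_kev"]
    pe = float(np.interp(energy_kev, grid, t["photoelectric"]))
    inc = float(np.interp(energy_kev, grid, t["incoherent"]))
    coh = float(np.interp(energy_kev, grid, t["coherent"]))
    total = pe + inc + coh
    return {"photoelectric": pe / total, "compton": inc / total,
            "rayleigh": coh / total}


@njit(cache=True)
def _transport_kernel(pos, dirn, energy, weight, matid, density, labels,
                      spacing, origin, mu_rho, p_pe, p_pc, mu_maj,
                      e_lo, e_step, cutoff, edep, label_edep, counters, seed):  # pragma: no cover
    np.random.seed(seed)
    nx, ny, nz = matid.shape
    box_lo0 = origin[0] - 0.5 * spacing[0]
    box_lo1 = origin[1] - 0.5 * spacing[1]
    box_lo2 = origin[2] - 0.5 * spacing[2]
    box_hi0 = box_lo0 + nx * spacing[0]
    box_hi1 = box_lo1 + ny * spacing[1]
    box_hi2 = box_lo2 + nz * spacing[2]
    ne = mu_maj.shape[0]

    for ip in range(pos.shape[0]):
        w = weight[ip]
        if w <= 0.0:
            continue
        x = pos[ip, 0]
        y = pos[ip, 1]
        z = pos[ip, 2]
        ux = dirn[ip, 0]
        uy = dirn[ip, 1]
        uz = dirn[ip, 2]
        e = energy[ip]

        # advance to the phantom bounding box (slab method)
        tmin = 0.0
        tmax = 1.0e30
        ok = True
        for axis in range(3):
            if axis == 0:
                p = x
                u = ux
                lo = box_lo0
                hi = box_hi0
            elif axis == 1:
                p = y
                u = uy
                lo = box_lo1
                hi = box_hi1
            else:
                p = z
                u = uz
                lo = box_lo2
                hi = box_hi2
            if abs(u) < 1e-12:
                if p < lo or p > hi:
                    ok = False
                    break
            else:
                t1 = (lo - p) / u
                t2 = (hi - p) / u
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
        if not ok or tmax <= tmin:
            continue
        if tmin > 0.0:
            x += (tmin + 1e-6) * ux
            y += (tmin + 1e-6) * uy
            z += (tmin + 1e-6) * uz

        alive = True
        collided = False
        while alive:
            if e < cutoff:
                # terminate below the cutoff, depositing the residual locally
                if (box_lo0 <= x < box_hi0 and box_lo1 <= y < box_hi1
                        and box_lo2 <= z < box_hi2):
                    i = int((x - box_lo0) / spacing[0])
                    j = int((y - box_lo1) / spacing[1])
                    k = int((z - box_lo2) / spacing[2])
                    edep[i, j, k] += w * e
                    label_edep[labels[i, j, k]] += w * e
                collided = True
                break
            eidx = int((e - e_lo) / e_step)
            if eidx < 0:
                eidx = 0
            elif eidx >= ne:
                eidx = ne - 1
            sigma_maj = mu_maj[eidx]
            if sigma_maj <= 0.0:
                break
            # Woodcock step (mm; mu is 1/cm)
            step = -np.log(np.random.random()) / sigma_maj * 10.0
            x += step * ux
            y += step * uy
            z += step * uz
            if (x < box_lo0 or x >= box_hi0 or y < box_lo1 or y >= box_hi1
                    or z < box_lo2 or z >= box_hi2):
                break
            i = int((x - box_lo0) / spacing[0])
            j = int((y - box_lo1) / spacing[1])
            k = int((z - box_lo2) / spacing[2])
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                break
            m = matid[i, j, k]
            mu_real = mu_rho[m, eidx] * density[i, j, k]
            if np.random.random() * sigma_maj > mu_real:
                continue  # fictitious collision

            collided = True
            r = np.random.random()
            if r < p_pe[m, eidx]:
                # photoelectric: full local absorption
                edep[i, j, k] += w * e
                label_edep[labels[i, j, k]] += w * e
                alive = False
            elif r < p_pc[m, eidx]:
                cos_t, eta = _kahn_cos(e / 510.99895)
                e_new = e / eta
                dep = e - e_new
                edep[i, j, k] += w * dep
                label_edep[labels[i, j, k]] += w * dep
                if e_new < cutoff:
                    edep[i, j, k] += w * e_new
                    label_edep[labels[i, j, k]] += w * e_new
                    alive = False
                else:
                    e = e_new
                    ux, uy, uz = _rotate(ux, uy, uz, cos_t)
            else:
                # Rayleigh: Thomson angular shape, no energy loss
                ux, uy, uz = _rotate(ux, uy, uz, _rayleigh_cos())
        if alive and not collided:
            counters[0] += 1


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cos_t):  # pragma: no cover
    """Rotate a unit vector by polar angle acos(cos_t), uniform azimuth."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = 2.0 * np.pi * np.random.random()
    cos_p = np.cos(phi)
    sin_p = np.sin(phi)
    if abs(uz) < 0.99999:
        denom = np.sqrt(1.0 - uz * uz)
        vx = ux * cos_t + sin_t * (ux * uz * cos_p - uy * sin_p) / denom
        vy = uy * cos_t + sin_t * (uy * uz * cos_p + ux * sin_p) / denom
        vz = uz * cos_t - denom * sin_t * cos_p
    else:
        vx = sin_t * cos_p
        vy = sin_t * sin_p
        vz = cos_t if uz > 0 else -cos_t
    norm = np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


def _check_finite(pos, dirn) -> None:
    if not (np.isfinite(pos).all() and np.isfinite(dirn).all()):
        raise ValueError("non-finite photon position or direction")


def transport_batch(pos, dirn, energy, weight, phantom: VoxelPhantom,
                    grid: MaterialGrid, mu_maj: np.ndarray, seed: int,
                    cutoff: float = ENERGY_CUTOFF_KEV,
                    return_uncollided: bool = False):
    """Transport pre-sampled photons; returns (voxel_edep, label_edep) in keV.

    With ``return_uncollided`` the count of photons leaving the grid without
    any real interaction is appended to the return tuple.
    """
    _check_finite(pos, dirn)
    n_labels = int(phantom.organ_label.max()) + 1
    edep = np.zeros(phantom.dims, dtype=np.float64)
    label_edep = np.zeros(n_labels, dtype=np.float64)
    counters = np.zeros(1, dtype=np.int64)
    _transport_kernel(
        np.ascontiguousarray(pos), np.ascontiguousarray(dirn),
        np.ascontiguousarray(energy, dtype=np.float64),
        np.ascontiguousarray(weight, dtype=np.float64),
        phantom.material_id, phantom.density.astype(np.float32),
        phantom.organ_label, phantom.spacing, phantom.origin,
        grid.mu_rho, grid.p_photo, grid.p_compton, mu_maj,
        grid.e_lo, grid.e_step, cutoff, edep, label_edep, counters,
        seed & 0x7FFFFFFF)
    if return_uncollided:
        return edep, label_edep, int(counters[0])
    return edep, label_edep


def run_projection(phantom: VoxelPhantom, geometry: ScannerGeometry,
                   spectrum: Spectrum, bowtie: BowtieProfile | None,
                   gantry_angle_deg: float, table_z_mm: float,
                   n_photons: int, seed: int, n_batches: int = 10,
                   cutoff: float = ENERGY_CUTOFF_KEV,
                   score_voxels: bool = True) -> TallyResult:
    """Analog transport of ``n_photons`` for a single projection."""
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    grid = MaterialGrid.for_phantom(phantom)
    mu_maj = grid.majorant(phantom)
    n_labels = int(phantom.organ_label.max()) + 1
    rng = np.random.default_rng(seed)
    edep = np.zeros(phantom.dims)
    batch_label = np.zeros((n_batches, n_labels))
    per_batch = np.array_split(np.arange(n_photons), n_batches)
    for b, chunk in enumerate(per_batch):
        if chunk.size == 0:
            continue
        pos, dirn, e, w = initial_photons(chunk.size, spectrum, bowtie, geometry,
                                          gantry_angle_deg, table_z_mm, rng)
        ed, le = transport_batch(pos, dirn, e, w, phantom, grid, mu_maj,
                                 seed=seed * 7919 + b)
        edep += ed
        batch_label[b] = le
    label_edep = batch_label.sum(axis=0)
    if label_edep.sum() == 0 and edep.sum() == 0:
        warnings.warn("beam missed the phantom entirely; zero tally", stacklevel=2)
    return TallyResult(edep if score_voxels else np.zeros(0),
                       label_edep, n_photons, seed, batch_label_edep=batch_label)


def run_scan(phantom: VoxelPhantom, geometry: ScannerGeometry,
             protocol: ScanProtocol, spectrum: Spectrum,
             bowtie: BowtieProfile | None, n_photons_per_projection: int,
             base_seed: int, weights: np.ndarray | None = None,
             score_voxels: bool = True, progress: bool = False) -> TallyResult:
    """Run every projection in the schedule and combine tallies.

    ``weights`` (one per projection, mean 1) reshape the per-projection
    contributions at constant total particle count; per-projection label
    sub-tallies are stored so alternative weightings can be applied exactly
    afterwards (see `tcm.apply_weights`).
    """
    schedule = projection_schedule(protocol, geometry)
    n_proj = schedule.shape[0]
    if weights is None:
        weights = np.ones(n_proj)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != n_proj:
        raise ValueError("weights length does not match schedule")

    grid = MaterialGrid.for_phantom(phantom)
    mu_maj = grid.majorant(phantom)
    n_labels = int(phantom.organ_label.max()) + 1
    edep = np.zeros(phantom.dims)
    per_proj = np.zeros((n_proj, n_labels))
    for p in range(n_proj):
        seed_p = base_seed + p
        rng = np.random.default_rng(seed_p)
        pos, dirn, e, w = initial_photons(n_photons_per_projection, spectrum,
                                          bowtie, geometry, schedule[p, 0],
                                          schedule[p, 1], rng)
        ed, le = transport_batch(pos, dirn, e, w, phantom, grid, mu_maj,
                                 seed=seed_p * 7919 + 104729)
        per_proj[p] = le
        if score_voxels:
            edep += weights[p] * ed
        if progress and (p + 1) % 10 == 0:
            print(f"projection {p + 1}/{n_proj}")

    label_edep = weights @ per_proj
    return TallyResult(edep, label_edep, n_proj * n_photons_per_projection,
                       base_seed, per_projection_label_edep=per_proj)
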