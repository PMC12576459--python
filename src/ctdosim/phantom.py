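"""Voxel phantoms: HU calibration, CT-series voxelization, coarse-graining,
the standard CTDI PMMA phantom, and synthetic labeled phantoms.

Coordinates: voxel indices are 0-based; world coordinates (mm) refer to voxel
centers; z increases toward the head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .attenuation import MATERIALS

__all__ = [
    "VoxelPhantom",
    "SchneiderCalibration",
    "load_default_calibration",
    "hu_to_material",
    "build_from_ct",
    "coarse_grain",
    "make_ctdi_phantom",
    "make_free_air_phantom",
    "make_synthetic_abdomen",
    "add_table",
]


@dataclass
class VoxelPhantom:
    """3-D grid of material ids, densities and optional region labels."""

    material_id: np.ndarray        # (nx, ny, nz) int16, index into `materials`
    density: np.ndarray            # (nx, ny, nz) float32, g/cm^3
    organ_label: np.ndarray        # (nx, ny, nz) int16, 0 = unlabeled
    spacing: np.ndarray            # (3,) mm
    origin: np.ndarray             # (3,) mm, world position of voxel (0,0,0) center
    materials: list[str]           # id -> catalog material name
    label_names: dict[int, str] = field(default_factory=dict)
    hu: np.ndarray | None = None   # optional HU channel (kept for coarse-graining)

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if self.material_id.shape != self.density.shape != self.organ_label.shape:
            raise ValueError("channel shape mismatch")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.material_id.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_mass_g(self) -> np.ndarray:
        return self.density * self.voxel_volume_cm3

    def total_mass_g(self) -> float:
        return float(self.voxel_mass_g().sum())

    def label_mass_g(self, label: int) -> float:
        return float(self.density[self.organ_label == label].sum()
                     * self.voxel_volume_cm3)

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin - 0.5 * self.spacing
        hi = lo + np.asarray(self.dims) * self.spacing
        return lo, hi

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f["material_id"] = self.material_id
            f["density"] = self.density
            f["organ_label"] = self.organ_label
            f.attrs["spacing"] = self.spacing
            f.attrs["origin"] = self.origin
            f.attrs["materials"] = [m.encode() for m in self.materials]

    @classmethod
    def load_h5(cls, path) -> "VoxelPhantom":
        import h5py

        with h5py.File(path, "r") as f:
            materials = [m.decode() if isinstance(m, bytes) else str(m)
                         for m in f.attrs["materials"]]
            return cls(f["material_id"][...], f["density"][...],
                       f["organ_label"][...], f.attrs["spacing"][...],
                       f.attrs["origin"][...], materials)


@dataclass(frozen=True)
class SchneiderCalibration:
    """Piecewise HU -> (material, density) mapping; density linear per bin."""

    hu_lo: np.ndarray
    hu_hi: np.ndarray
    materials: list[str]
    rho_lo: np.ndarray
    rho_hi: np.ndarray

    def __post_init__(self) -> None:
        if len(self.materials) == 0:
            raise ValueError("empty calibration")
        if not np.all(self.hu_lo[1:] == self.hu_hi[:-1]):
            raise ValueError("bins must be contiguous")
        for lo, hi in zip(self.rho_lo, self.rho_hi):
            if hi < lo:
                raise ValueError("density must be non-decreasing within bins")

    def lookup(self, hu) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized mapping; values outside the table are clamped (warning)."""
        hu = np.asarray(hu, dtype=float)
        lo, hi = self.hu_lo[0], self.hu_hi[-1]
        if np.any(hu < lo) or np.any(hu > hi):
            warnings.warn("HU outside calibration range; clamping", stacklevel=2)
            hu = np.clip(hu, lo, hi)
        idx = np.clip(np.searchsorted(self.hu_hi, hu, side="right"),
                      0, len(self.materials) - 1)
        frac = (hu - self.hu_lo[idx]) / (self.hu_hi[idx] - self.hu_lo[idx])
        rho = self.rho_lo[idx] + frac * (self.rho_hi[idx] - self.rho_lo[idx])
        return idx.astype(np.int16), rho.astype(np.float32)


def load_default_calibration() -> SchneiderCalibration:
    ref = resources.files("ctdosim.data").joinpath("hu_calibration.csv")
    with ref.open("r") as fh:
        header = fh.readline()
        rows = [line.strip().split(",") for line in fh if line.strip()]
    return SchneiderCalibration(
        hu_lo=np.array([float(r[0]) for r in rows]),
        hu_hi=np.array([float(r[1]) for r in rows]),
        materials=[r[2] for r in rows],
        rho_lo=np.array([float(r[3]) for r in rows]),
        rho_hi=np.array([float(r[4]) for r in rows]),
    )


def hu_to_material(hu: float, calib: SchneiderCalibration) -> tuple[str, float]:
    """Material name and density (g/cm^3) for a single HU value."""
    idx, rho = calib.lookup(np.array([hu]))
    return calib.materials[int(idx[0])], float(rho[0])


def _catalog_ids(names: list[str]) -> tuple[list[str], np.ndarray]:
    """Deduplicate material names preserving order; return map per input index."""
    catalog: list[str] = []
    idx_map = np.empty(len(names), dtype=np.int16)
    for i, n in enumerate(names):
        if n not in catalog:
            catalog.append(n)
        idx_map[i] = catalog.index(n)
    return catalog, idx_map


def build_from_ct(series, calib: SchneiderCalibration) -> VoxelPhantom:
    """Voxel phantom from a list of CT slice datasets (see `dicomlite`).

    Slices are sorted by z; RescaleSlope/Intercept convert stored values to HU.
    Arrays are indexed (x, y, z) with x along DICOM columns and y along rows.
    """
    if not series:
        raise ValueError("empty series")
    try:
        series = sorted(series, key=lambda ds: float(ds["ImagePositionPatient"][2]))
    except KeyError as exc:
        raise ValueError("slice missing ImagePositionPatient") from exc
    first = series[0]
    for key in ("PixelSpacing", "SliceThickness"):
        if key not in first:
            raise ValueError(f"series missing {key}")
    ps = [float(v) for v in first["PixelSpacing"]]  # (row, col) mm
    zs = np.array([float(ds["ImagePositionPatient"][2]) for ds in series])
    if len(series) > 1:
        dz = np.diff(zs)
        if np.ptp(dz) > 1e-3 or np.any(dz <= 0):
            raise ValueError("series z-spacing not uniform")
        slice_spacing = float(dz[0])
    else:
        slice_spacing = float(first["SliceThickness"])

    hu_slices = []
    for ds in series:
        slope = float(ds.get("RescaleSlope", 1.0))
        intercept = float(ds.get("RescaleIntercept", 0.0))
        hu_slices.append(ds["pixel_array"].astype(np.float32) * slope + intercept)
    hu = np.stack(hu_slices, axis=-1)            # (rows, cols, z)
    hu = np.transpose(hu, (1, 0, 2))             # -> (x=cols, y=rows, z)

    ids, rho = calib.lookup(hu)
    catalog, idx_map = _catalog_ids(list(calib.materials))
    mat = idx_map[ids]
    ipp = [float(v) for v in first["ImagePositionPatient"]]
    return VoxelPhantom(mat, rho, np.zeros_like(mat),
                        spacing=np.array([ps[1], ps[0], slice_spacing]),
                        origin=np.array([ipp[0], ipp[1], zs[0]]),
                        materials=catalog, hu=hu)


def _block_reduce_mean(arr: np.ndarray, f) -> np.ndarray:
    nx, ny, nz = arr.shape
    return (arr.reshape(nx // f[0], f[0], ny // f[1], f[1], nz // f[2], f[2])
            .mean(axis=(1, 3, 5)))


def _block_mode(arr: np.ndarray, f) -> np.ndarray:
    nx, ny, nz = arr.shape
    blocks = (arr.reshape(nx // f[0], f[0], ny // f[1], f[1], nz // f[2], f[2])
              .transpose(0, 2, 4, 1, 3, 5)
              .reshape(-1, f[0] * f[1] * f[2]))
    out = np.empty(blocks.shape[0], dtype=arr.dtype)
    for i, row in enumerate(blocks):
        vals, counts = np.unique(row, return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out.reshape(nx // f[0], ny // f[1], nz // f[2])


def coarse_grain(phantom: VoxelPhantom, factors=(4, 4, 1),
                 calib: SchneiderCalibration | None = None) -> VoxelPhantom:
    """Block-average the phantom, conserving mass.

    Block density is the plain mean (mass-conserving). When the phantom
    carries an HU channel the block material is obtained by re-binning the
    block-mean HU through the calibration; otherwise the block material is the
    majority vote of the fine voxels. Labels are always majority-voted.
    Dimensions not divisible by the factors are padded with air.
    """
    f = tuple(int(x) for x in factors)
    if any(x < 1 for x in f):
        raise ValueError("factors must be >= 1")
    pad = [(0, (-d) % x) for d, x in zip(phantom.dims, f)]
    if any(p[1] for p in pad):
        warnings.warn("dims not divisible by factors; padding with air", stacklevel=2)
        phantom = _pad_with_air(phantom, pad)

    rho = _block_reduce_mean(phantom.density.astype(np.float64), f).astype(np.float32)
    labels = _block_mode(phantom.organ_label, f)
    hu = None
    if phantom.hu is not None and calib is not None:
        hu = _block_reduce_mean(phantom.hu.astype(np.float64), f)
        ids, _ = calib.lookup(hu)
        catalog, idx_map = _catalog_ids(list(calib.materials))
        mat = idx_map[ids]
        materials = catalog
        hu = hu.astype(np.float32)
    else:
        mat = _block_mode(phantom.material_id, f)
        materials = phantom.materials
        if phantom.hu is not None:
            hu = _block_reduce_mean(phantom.hu.astype(np.float64), f).astype(np.float32)

    new_spacing = phantom.spacing * np.asarray(f)
    new_origin = phantom.origin - 0.5 * phantom.spacing + 0.5 * new_spacing
    return VoxelPhantom(mat, rho, labels, new_spacing, new_origin,
                        materials, dict(phantom.label_names), hu=hu)


def _pad_with_air(phantom: VoxelPhantom, pad) -> VoxelPhantom:
    materials = list(phantom.materials)
    if "air" not in materials:
        materials.append("air")
    air_id = materials.index("air")
    mat = np.pad(phantom.material_id, pad, constant_values=air_id)
    rho = np.pad(phantom.density, pad, constant_values=MATERIALS["air"].density)
    lab = np.pad(phantom.organ_label, pad, constant_values=0)
    hu = (np.pad(phantom.hu, pad, constant_values=-1000.0)
          if phantom.hu is not None else None)
    return replace(phantom, material_id=mat, density=rho, organ_label=lab,
                   materials=materials, hu=hu)


def _grid_coords(dims, spacing, origin):
    axes = [origin[i] + spacing[i] * np.arange(dims[i]) for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


CTDI_BORE_LABELS = {1: "center", 2: "12oclock", 3: "3oclock", 4: "6oclock", 5: "9oclock"}


def make_ctdi_phantom(diameter_cm: float = 32.0, length_cm: float = 15.0,
                      voxel_mm=(2.5, 2.5, 5.0), bore_radius_mm: float = 6.5,
                      chamber_length_mm: float = 100.0,
                      bore_material: str = "air"):
    """Standard body CTDI phantom: PMMA cylinder with five air bores.

    Peripheral bores sit at 12/3/6/9 o'clock with centers 1 cm below the
    surface. Voxels inside a bore within the central ``chamber_length_mm`` are
    labeled 1-5 (see ``CTDI_BORE_LABELS``). Returns (phantom, bore_xy) where
    bore_xy maps label name to the bore axis position in mm.

    ``bore_material`` defaults to the physical air chamber channel; a solid
    filling (e.g. ``"pmma"``) gives far better analog-tally statistics at
    small photon budgets and leaves the phantom's symmetry unchanged.
    """
    r_mm = diameter_cm * 5.0
    lz = length_cm * 10.0
    sp = np.asarray(voxel_mm, dtype=float)
    nx = int(np.ceil(2 * (r_mm + 5.0) / sp[0]))
    ny = int(np.ceil(2 * (r_mm + 5.0) / sp[1]))
    nz = int(round(lz / sp[2]))
    origin = np.array([-(nx - 1) / 2 * sp[0], -(ny - 1) / 2 * sp[1],
                       -(nz - 1) / 2 * sp[2]])
    x, y, z = _grid_coords((nx, ny, nz), sp, origin)

    inside = x**2 + y**2 <= r_mm**2
    materials = ["air", "pmma"]
    mat = np.where(inside, 1, 0).astype(np.int16)
    rho = np.where(inside, MATERIALS["pmma"].density,
                   MATERIALS["air"].density).astype(np.float32)
    labels = np.zeros_like(mat)

    if bore_material not in materials:
        materials.append(bore_material)
    bore_id = materials.index(bore_material)
    bore_rho = MATERIALS[bore_material].density

    rp = r_mm - 10.0
    bore_xy = {"center": (0.0, 0.0), "12oclock": (0.0, rp), "3oclock": (rp, 0.0),
               "6oclock": (0.0, -rp), "9oclock": (-rp, 0.0)}
    for label, name in CTDI_BORE_LABELS.items():
        bx, by = bore_xy[name]
        bore = (x - bx) ** 2 + (y - by) ** 2 <= bore_radius_mm**2
        mat[bore] = bore_id
        rho[bore] = bore_rho
        labels[bore & (np.abs(z) <= chamber_length_mm / 2)] = label

    ph = VoxelPhantom(mat, rho, labels, sp, origin, materials,
                      dict(CTDI_BORE_LABELS))
    return ph, bore_xy


def make_free_air_phantom(voxel_mm=(10.0, 10.0, 10.0),
                          chamber_length_mm: float = 100.0) -> VoxelPhantom:
    """Small all-air volume with a pencil-chamber region (label 1) at isocenter,
    used to simulate CTDI_air for the normalization factor."""
    sp = np.asarray(voxel_mm, dtype=float)
    dims = (5, 5, 16)
    origin = np.array([-(dims[0] - 1) / 2 * sp[0], -(dims[1] - 1) / 2 * sp[1],
                       -(dims[2] - 1) / 2 * sp[2]])
    mat = np.zeros(dims, dtype=np.int16)
    rho = np.full(dims, MATERIALS["air"].density, dtype=np.float32)
    labels = np.zeros(dims, dtype=np.int16)
    _, _, z = _grid_coords(dims, sp, origin)
    ctr = dims[0] // 2
    labels[ctr, ctr, :] = (np.abs(z[ctr, ctr, :]) <= chamber_length_mm / 2)
    return VoxelPhantom(mat, rho, labels.astype(np.int16), sp, origin,
                        ["air"], {1: "chamber"})


ABDOMEN_ORGAN_LABELS = {1: "liver", 2: "stomach", 3: "gallbladder", 4: "spleen",
                        5: "pancreas", 6: "kidneys", 7: "spine"}

# (center mm, semi-axes mm); kidneys are a mirrored pair. Placements are
# pairwise disjoint with margin even under the +-3 mm / +-5% jitter below
# (each pair is separated along at least one axis).
_ORGAN_SPECS = {
    "liver": ((60.0, 20.0, 130.0), (45.0, 40.0, 35.0)),
    "stomach": ((-50.0, 35.0, 120.0), (35.0, 28.0, 30.0)),
    "gallbladder": ((105.0, -45.0, 80.0), (14.0, 14.0, 18.0)),
    "spleen": ((-95.0, -30.0, 130.0), (22.0, 22.0, 22.0)),
    "pancreas": ((-30.0, -20.0, 95.0), (30.0, 15.0, 10.0)),
    "kidneys": (((60.0, -50.0, 50.0), (-60.0, -50.0, 50.0)), (20.0, 16.0, 26.0)),
}


def make_synthetic_abdomen(seed: int = 0, voxel_mm=(5.0, 5.0, 5.0),
                           dims=(64, 48, 36), body_semi_axes=(150.0, 100.0)):
    """Synthetic labeled abdomen: elliptic soft-tissue body with six
    ellipsoidal organs, a bone vertebral column, and air lung apices.

    Organ centers/axes are jittered deterministically from ``seed``. Overlaps
    resolve by stamping order (earlier organs win). Returns
    (phantom, organ_geometry) where organ_geometry records the jittered
    ellipsoid parameters for each stamped component.
    """
    rng = np.random.default_rng(seed)
    sp = np.asarray(voxel_mm, dtype=float)
    dims = tuple(dims)
    origin = np.array([-(dims[0] - 1) / 2 * sp[0], -(dims[1] - 1) / 2 * sp[1], 0.0])
    x, y, z = _grid_coords(dims, sp, origin)

    a, b = body_semi_axes
    body = (x / a) ** 2 + (y / b) ** 2 <= 1.0

    materials = ["air", "soft_tissue", "bone_cortical", "lung_tissue"]
    mat = np.where(body, 1, 0).astype(np.int16)
    rho = np.where(body, MATERIALS["soft_tissue"].density,
                   MATERIALS["air"].density).astype(np.float32)
    labels = np.zeros(dims, dtype=np.int16)

    # vertebral column
    spine = body & ((x**2 + (y + 65.0) ** 2) <= 18.0**2)
    mat[spine] = 2
    rho[spine] = MATERIALS["bone_cortical"].density
    labels[spine] = 7

    organ_geometry: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    label_of = {v: k for k, v in ABDOMEN_ORGAN_LABELS.items()}
    for name, (center, semi) in _ORGAN_SPECS.items():
        centers = center if name == "kidneys" else (center,)
        semi = np.asarray(semi) * (1.0 + rng.uniform(-0.05, 0.05, 3))
        parts = []
        for c in centers:
            c = np.asarray(c) + rng.uniform(-3.0, 3.0, 3)
            mask = (((x - c[0]) / semi[0]) ** 2 + ((y - c[1]) / semi[1]) ** 2
                    + ((z - c[2]) / semi[2]) ** 2) <= 1.0
            mask &= labels == 0
            labels[mask] = label_of[name]
            mat[mask] = 1
            rho[mask] = MATERIALS["soft_tissue"].density
            parts.append((c, semi.copy()))
        organ_geometry[name] = parts

    # lung apices (air-filled, near the top of the volume); stamped last so
    # labeled organs keep precedence
    zmax = origin[2] + (dims[2] - 1) * sp[2]
    for sx in (1.0, -1.0):
        lung = (body & (((x - sx * 60.0) / 48.0) ** 2 + ((y - 15.0) / 40.0) ** 2
                        + ((z - zmax) / 30.0) ** 2 <= 1.0))
        lung &= labels == 0
        mat[lung] = 0
        rho[lung] = MATERIALS["air"].density

    ph = VoxelPhantom(mat, rho, labels, sp, origin, materials,
                      dict(ABDOMEN_ORGAN_LABELS))
    return ph, organ_geometry


def add_table(phantom: VoxelPhantom, table=None) -> VoxelPhantom:
    """Extend the grid in -y with a patient-table slab (shell/core/shell)."""
    from .geometry import TableModel

    table = table or TableModel()
    sp = phantom.spacing
    t_total = 2 * table.shell_thickness_mm + table.core_thickness_mm
    n_extra = int(np.ceil((t_total + 5.0) / sp[1]))
    pad = [(0, 0), (n_extra, 0), (0, 0)]
    ph = _pad_with_air(phantom, pad)
    ph.origin = ph.origin - np.array([0.0, n_extra * sp[1], 0.0])

    materials = list(ph.materials)
    for name in (table.shell_material, table.core_material):
        if name not in materials:
            materials.append(name)
    shell_id = materials.index(table.shell_material)
    core_id = materials.index(table.core_material)

    y = ph.origin[1] + sp[1] * np.arange(ph.dims[1])
    top = table.top_offset_mm
    in_shell = ((y <= top) & (y > top - t_total)
                & ((y > top - table.shell_thickness_mm)
                   | (y <= top - table.shell_thickness_mm - table.core_thickness_mm)))
    in_core = ((y <= top - table.shell_thickness_mm)
               & (y > top - table.shell_thickness_mm - table.core_thickness_mm))
    air_like = ph.density < 0.01
    for idx, density, mask_y in ((shell_id, table.shell_density, in_shell),
                                 (core_id, table.core_density, in_core)):
        mask = air_like & mask_y[None, :, None]
        ph.material_id[mask] = idx
        ph.density[mask] = density
    ph.materials = materials
    return ph
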