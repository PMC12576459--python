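"""Synthetic CT fixture series: DICOM slices with TCM headers rendered from
the synthetic abdomen phantom, so header mining and phantom voxelization are
exercised by the same data with no external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .attenuation import MATERIALS
from .dicomlite import write_ct_slice
from .phantom import make_synthetic_abdomen

__all__ = ["FixtureSpec", "make_fixture_series", "ma_profile_values"]


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible description of a synthetic CT series."""

    n_slices: int = 280
    slice_thickness_mm: float = 0.625
    rows: int = 96
    cols: int = 96
    pixel_spacing_mm: float = 2.72
    ma_profile: str = "constant"      # constant | ramp | gaussian-bump
    base_ma: float = 100.0
    ma_amplitude: float = 0.0         # ramp span or bump height, mA
    noise_hu: float = 0.0
    seed: int = 0

    @property
    def scan_length_mm(self) -> float:
        return self.n_slices * self.slice_thickness_mm


def ma_profile_values(spec: FixtureSpec) -> np.ndarray:
    """Per-slice tube current for the requested profile shape."""
    t = np.linspace(0.0, 1.0, spec.n_slices)
    if spec.ma_profile == "constant":
        ma = np.full(spec.n_slices, spec.base_ma)
    elif spec.ma_profile == "ramp":
        ma = spec.base_ma + spec.ma_amplitude * t
    elif spec.ma_profile == "gaussian-bump":
        ma = spec.base_ma + spec.ma_amplitude * np.exp(-0.5 * ((t - 0.5) / 0.2) ** 2)
    else:
        raise ValueError(f"unknown ma_profile {spec.ma_profile!r}")
    return np.maximum(np.round(ma), 1.0)


def _uid(seed: int, kind: int, index: int = 0) -> str:
    return f"2.25.{seed % 10**6}{kind}{index:05d}"


def make_fixture_series(spec: FixtureSpec, outdir) -> list[Path]:
    """Write a standards-shaped CT series rendered from the synthetic abdomen.

    Each slice carries XRayTubeCurrent, Exposure, position/spacing and rescale
    tags; pixels are the phantom's representative HU plus optional noise.
    UIDs derive from the seed so identical specs produce identical headers.
    Returns the written file paths in slice order.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    phantom, _ = make_synthetic_abdomen(seed=spec.seed)
    hu_by_material = np.array([MATERIALS[m].hu_representative
                               for m in phantom.materials])
    ma = ma_profile_values(spec)

    nx, ny, nz = phantom.dims
    # map fixture pixel grid onto phantom world coordinates
    x_px = (np.arange(spec.cols) - (spec.cols - 1) / 2) * spec.pixel_spacing_mm
    y_px = (np.arange(spec.rows) - (spec.rows - 1) / 2) * spec.pixel_spacing_mm
    ix = np.clip(np.round((x_px - phantom.origin[0]) / phantom.spacing[0]).astype(int),
                 0, nx - 1)
    iy = np.clip(np.round((y_px - phantom.origin[1]) / phantom.spacing[1]).astype(int),
                 0, ny - 1)

    study_uid = _uid(spec.seed, 1)
    series_uid = _uid(spec.seed, 2)
    paths = []
    z0 = phantom.origin[2]
    phantom_zmax = phantom.origin[2] + (nz - 1) * phantom.spacing[2]
    for s in range(spec.n_slices):
        z = z0 + s * spec.slice_thickness_mm
        iz = int(np.clip(round((min(z, phantom_zmax) - phantom.origin[2])
                               / phantom.spacing[2]), 0, nz - 1))
        mat_slice = phantom.material_id[np.ix_(ix, iy, [iz])][:, :, 0]
        hu = hu_by_material[mat_slice].T  # (rows, cols)
        if spec.noise_hu > 0:
            hu = hu + rng.normal(0.0, spec.noise_hu, hu.shape)
        stored = np.clip(np.round(hu + 1024.0), 0, 4095).astype(np.uint16)

        path = outdir / f"slice_{s:04d}.dcm"
        write_ct_slice(path, {
            "SOPInstanceUID": _uid(spec.seed, 3, s),
            "StudyInstanceUID": study_uid,
            "SeriesInstanceUID": series_uid,
            "InstanceNumber": s + 1,
            "SliceThickness": spec.slice_thickness_mm,
            "KVP": 120.0,
            "XRayTubeCurrent": int(ma[s]),
            "Exposure": int(round(ma[s] * 0.5)),
            "ImagePositionPatient": [float(x_px[0]), float(y_px[0]), float(z)],
            "ImageOrientationPatient": [1, 0, 0, 0, 1, 0],
            "SliceLocation": float(z),
            "PixelSpacing": [spec.pixel_spacing_mm, spec.pixel_spacing_mm],
            "RescaleIntercept": -1024.0,
            "RescaleSlope": 1.0,
        }, pixel_array=stored)
        paths.append(path)
    return paths
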