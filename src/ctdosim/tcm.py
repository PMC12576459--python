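"""Tube-current-modulation profiles from DICOM headers and projection weights.

The per-slice tube current is mined from reconstructed image headers, averaged
per gantry rotation against table position, and converted into per-projection
weighting factors with mean exactly 1, so a weighted run keeps the total
simulated particle count constant while reshaping the per-projection
contributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TCMProfile",
    "ProjectionWeights",
    "extract_tube_currents",
    "per_rotation_average",
    "projection_weights",
    "apply_weights",
]


@dataclass(frozen=True)
class TCMProfile:
    """Rotation-averaged tube current versus table position."""

    rotation_index: np.ndarray     # (R,)
    z_mm: np.ndarray               # rotation-center table position
    mean_ma: np.ndarray            # mA
    slice_count: np.ndarray        # source slices per rotation (0 = interpolated)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.z_mm.size == 0:
            raise ValueError("empty profile")
        if np.any(np.diff(self.z_mm) <= 0):
            raise ValueError("table positions must be strictly monotone")
        if np.any(self.mean_ma <= 0):
            raise ValueError("tube current must be positive")

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.rotation_index, self.z_mm,
                                          self.mean_ma]),
                   delimiter=",", header="rotation,z_mm,mean_ma", comments="")


@dataclass(frozen=True)
class ProjectionWeights:
    """Per-projection weights (mean exactly 1) plus the mAs-per-projection scale."""

    weights: np.ndarray
    mas_per_projection: float

    def __post_init__(self) -> None:
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if abs(self.weights.mean() - 1.0) > 1e-12:
            raise ValueError("weights must average to 1")


def extract_tube_currents(series) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice (z mm, tube current mA) from a list of header datasets.

    Prefers XRayTubeCurrent (0018,1151); slices are sorted by z and duplicate
    z positions are averaged. Raises with the offending slice indices if the
    tag is missing, and rejects mixed series.
    """
    if not series:
        raise ValueError("empty series")
    uids = {ds.get("SeriesInstanceUID", "") for ds in series}
    if len(uids) > 1:
        raise ValueError(f"mixed series: {sorted(uids)}")
    missing = []
    zs, mas = [], []
    for i, ds in enumerate(series):
        ma = ds.get("XRayTubeCurrent")
        if ma is None:
            missing.append(i)
            continue
        if "ImagePositionPatient" in ds:
            z = float(ds["ImagePositionPatient"][2])
        elif "SliceLocation" in ds:
            z = float(ds["SliceLocation"])
        else:
            missing.append(i)
            continue
        zs.append(z)
        mas.append(float(ma))
    if missing:
        raise ValueError(f"slices missing tube-current or position tags: {missing}")
    z = np.asarray(zs)
    ma = np.asarray(mas)
    order = np.argsort(z, kind="stable")
    z, ma = z[order], ma[order]
    uz, inv = np.unique(z, return_inverse=True)
    if uz.size < z.size:
        ma = np.bincount(inv, weights=ma) / np.bincount(inv)
        z = uz
    return z, ma


def per_rotation_average(z: np.ndarray, ma: np.ndarray,
                         table_feed_mm: float, scan_start_z: float | None = None,
                         provenance: str = "") -> TCMProfile:
    """Average tube current over rotation windows of one table feed each.

    Window k covers [start + k*feed, start + (k+1)*feed); empty windows are
    filled by linear interpolation of neighboring rotations (flagged with a
    warning and slice_count 0).
    """
    if table_feed_mm <= 0:
        raise ValueError("table feed must be positive")
    z = np.asarray(z, dtype=float)
    ma = np.asarray(ma, dtype=float)
    if z.size == 0:
        raise ValueError("no tube-current samples")
    start = float(z.min()) if scan_start_z is None else float(scan_start_z)
    span = float(z.max()) - start
    n_rot = max(1, math.ceil(span / table_feed_mm - 1e-9))
    if span > 0 and np.isclose(span % table_feed_mm, 0.0):
        n_rot = int(round(span / table_feed_mm))
        n_rot = max(1, n_rot)
    idx = np.floor((z - start) / table_feed_mm).astype(int)
    idx = np.clip(idx, 0, n_rot - 1)
    sums = np.bincount(idx, weights=ma, minlength=n_rot)
    counts = np.bincount(idx, minlength=n_rot)
    mean = np.full(n_rot, np.nan)
    np.divide(sums, counts, out=mean, where=counts > 0)
    if np.any(counts == 0):
        warnings.warn("empty rotation windows filled by interpolation", stacklevel=2)
        filled = np.flatnonzero(counts > 0)
        mean = np.interp(np.arange(n_rot), filled, mean[filled])
    centers = start + (np.arange(n_rot) + 0.5) * table_feed_mm
    return TCMProfile(np.arange(n_rot), centers, mean, counts,
                      provenance=provenance)


def projection_weights(profile: TCMProfile, schedule: np.ndarray,
                       rotation_time_s: float, projections_per_rotation: int,
                       mode: str = "interp") -> ProjectionWeights:
    """Per-projection weighting factors from a rotation-averaged TCM profile.

    ``mode='interp'`` (default) interpolates the rotation means piecewise
    linearly at each projection's table position; ``mode='step'`` uses the
    rotation's mean unchanged. Projections outside the profile's z-range take
    the nearest rotation's value (overranging current is not recorded in the
    reconstructed headers).
    """
    zp = np.asarray(schedule)[:, 1]
    if mode == "interp":
        ma = np.interp(zp, profile.z_mm, profile.mean_ma)
    elif mode == "step":
        feed = (profile.z_mm[1] - profile.z_mm[0]) if profile.z_mm.size > 1 else np.inf
        if np.isfinite(feed):
            idx = np.floor((zp - profile.z_mm[0]) / feed + 0.5).astype(int)
        else:
            idx = np.zeros(zp.size, dtype=int)
        ma = profile.mean_ma[np.clip(idx, 0, profile.z_mm.size - 1)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = profile.z_mm[0], profile.z_mm[-1]
    if zp.min() < lo or zp.max() > hi:
        warnings.warn("projections outside TCM profile range; clamped to "
                      "nearest rotation", stacklevel=2)
    mean_ma = ma.mean()
    weights = ma / mean_ma
    weights = weights / weights.mean()  # exact mean 1
    mas = mean_ma * rotation_time_s / projections_per_rotation
    return ProjectionWeights(weights, float(mas))


def apply_weights(per_projection_tallies: np.ndarray,
                  weights: ProjectionWeights | np.ndarray) -> np.ndarray:
    """Weighted sum of per-projection tallies (projections on axis 0)."""
    w = weights.weights if isinstance(weights, ProjectionWeights) else np.asarray(weights)
    tallies = np.asarray(per_projection_tallies)
    if tallies.shape[0] != w.shape[0]:
        raise ValueError("tally/weight length mismatch")
    return np.tensordot(w, tallies, axes=(0, 0))
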