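"""Binned water density maps and the rotational-symmetry spectrum.

Maps accumulate inside-water oxygen positions over frames on half-open
bins; normalization divides by the most populated bin, optionally taken
jointly over a set of maps (cross-replica normalization) so that profiles
from different runs share one reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .confinement import classify_inside
from .core import AtomGroup, Trajectory
from .geometry import PoreRegion


@dataclass
class DensityMap:
    plane: str  # "xy", "xz" or "z"
    bin_size: float  # nm
    edges: tuple[np.ndarray, ...]  # per-dimension bin edges
    counts: np.ndarray  # occupancy integers
    normalized: np.ndarray | None = None  # in [0, 1] after normalize_map

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _inside_positions(traj: Trajectory, region: PoreRegion, waters: AtomGroup) -> np.ndarray:
    """Stacked (sum over frames) positions of inside waters, (M, 3)."""
    chunks = []
    for f in range(traj.n_frames):
        mask = classify_inside(traj.coords[f], region, waters, box=traj.box[f])
        if mask.any():
            chunks.append(traj.coords[f, waters.indices[mask]])
    return np.concatenate(chunks) if chunks else np.empty((0, 3))


def _axis_edges(lo: float, hi: float, bin_size: float) -> np.ndarray:
    n = max(1, int(np.ceil((hi - lo) / bin_size - 1e-9)))
    return lo + bin_size * np.arange(n + 1)


def density_map_xy(
    traj: Trajectory,
    region: PoreRegion,
    waters: AtomGroup,
    bin_size: float = 0.05,
) -> DensityMap:
    """2-D occupancy map of inside-water oxygens projected onto the xy plane.

    The grid spans the region's radial extent around its centre; bins are
    half-open so the binning is a partition.
    """
    cx, cy = region.center_xy
    r = region.radial_bound
    ex = _axis_edges(cx - r, cx + r, bin_size)
    ey = _axis_edges(cy - r, cy + r, bin_size)
    pos = _inside_positions(traj, region, waters)
    counts, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=(ex, ey))
    return DensityMap(plane="xy", bin_size=bin_size, edges=(ex, ey), counts=counts.astype(int))


def density_map_xz(
    traj: Trajectory,
    region: PoreRegion,
    waters: AtomGroup,
    bin_size: float = 0.05,
) -> DensityMap:
    """2-D occupancy map on the xz plane (x around the axis, z over the pore)."""
    cx, _ = region.center_xy
    r = region.radial_bound
    ex = _axis_edges(cx - r, cx + r, bin_size)
    ez = _axis_edges(region.z_lo, region.z_hi, bin_size)
    pos = _inside_positions(traj, region, waters)
    counts, _, _ = np.histogram2d(pos[:, 0], pos[:, 2], bins=(ex, ez))
    return DensityMap(plane="xz", bin_size=bin_size, edges=(ex, ez), counts=counts.astype(int))


def density_profile_z(
    traj: Trajectory,
    region: PoreRegion,
    waters: AtomGroup,
    bin_size: float = 0.05,
) -> DensityMap:
    """1-D occupancy profile of inside waters along the pore axis."""
    ez = _axis_edges(region.z_lo, region.z_hi, bin_size)
    pos = _inside_positions(traj, region, waters)
    counts, _ = np.histogram(pos[:, 2], bins=ez)
    return DensityMap(plane="z", bin_size=bin_size, edges=(ez,), counts=counts.astype(int))


def normalize_map(maps: DensityMap | list[DensityMap]) -> DensityMap | list[DensityMap]:
    """Normalize by the most populated bin, jointly over the supplied maps.

    With a list, all maps share one reference maximum (cross-replica
    normalization); the global max bin maps to exactly 1.  Idempotent.
    """
    single = isinstance(maps, DensityMap)
    group = [maps] if single else list(maps)
    if not group:
        raise ValueError("no maps to normalize")
    ref = max(m.counts.max() for m in group)
    if ref <= 0:
        raise ValueError("all-zero density maps cannot be normalized")
    out = [replace(m, normalized=m.counts / ref) for m in group]
    return out[0] if single else out


def angular_symmetry_spectrum(
    dmap: DensityMap,
    center: tuple[float, float] | None = None,
    radius_band: tuple[float, float] | None = None,
    max_mode: int = 12,
) -> np.ndarray:
    """Discrete angular Fourier power per rotational mode 1..max_mode.

    Bin mass in an annulus around the centre is resampled onto bin-centre
    angles; power of mode k is |sum_j m_j exp(-i k theta_j)|^2 normalized by
    the mode-0 power (total mass squared).  The band defaults to
    [0.2, 1.0] x the map's radial extent.
    """
    if dmap.plane != "xy":
        raise ValueError("symmetry spectrum requires an xy map")
    ex, ey = dmap.edges
    xc = (ex[:-1] + ex[1:]) / 2
    yc = (ey[:-1] + ey[1:]) / 2
    if center is None:
        center = (float((ex[0] + ex[-1]) / 2), float((ey[0] + ey[-1]) / 2))
    X, Y = np.meshgrid(xc - center[0], yc - center[1], indexing="ij")
    R = np.hypot(X, Y)
    r_extent = min(ex[-1] - center[0], ey[-1] - center[1])
    band = radius_band or (0.2 * r_extent, 1.0 * r_extent)
    sel = (R >= band[0]) & (R <= band[1]) & (dmap.counts > 0)
    if not sel.any():
        raise ValueError("no density mass in the radius band")
    theta = np.arctan2(Y[sel], X[sel])
    mass = dmap.counts[sel].astype(float)
    p0 = mass.sum() ** 2
    modes = np.arange(1, max_mode + 1)
    amp = (mass[None, :] * np.exp(-1j * modes[:, None] * theta[None, :])).sum(axis=1)
    return (np.abs(amp) ** 2) / p0
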