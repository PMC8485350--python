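"""Pore axis, region definition, radius profiles and nanotube tilt.

The channel axis is taken to be the membrane normal (+z) rather than fitted
per frame: all z-based analyses (occupancy, density profiles, ion traces)
share one fixed region convention.  The radius profile is a slab method: the
pore is cut into thin z-slabs and each slab reports the minimum
centre-to-atom-surface distance, i.e. the tightest constriction a probe
travelling on the axis would see in that slab.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AtomGroup, Topology

#: van der Waals radii in nm (Bondi-style), overridable per call
DEFAULT_VDW_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "P": 0.180,
    "S": 0.180,
    "Na": 0.227,
    "Cl": 0.175,
}
_VDW_FALLBACK = 0.150


@dataclass(frozen=True)
class PoreRegion:
    """Cylindrical "inside" region: axis +z through ``center_xy``.

    A point is inside iff ``z_lo <= z < z_hi`` and its radial distance from
    the axis is strictly less than ``radial_bound`` (points exactly on the
    upper z face or on the radial wall are outside).
    """

    center_xy: tuple[float, float]
    z_lo: float
    z_hi: float
    radial_bound: float

    def __post_init__(self) -> None:
        if not self.z_lo < self.z_hi:
            raise ValueError("z_lo must be < z_hi")
        if not self.radial_bound > 0:
            raise ValueError("radial_bound must be > 0")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean inside-mask for an (N, 3) array of positions (nm)."""
        pts = np.atleast_2d(points)
        dx = pts[:, 0] - self.center_xy[0]
        dy = pts[:, 1] - self.center_xy[1]
        r2 = dx * dx + dy * dy
        return (
            (pts[:, 2] >= self.z_lo)
            & (pts[:, 2] < self.z_hi)
            & (r2 < self.radial_bound**2)
        )


@dataclass
class RadiusProfile:
    """Minimum accessible radius per z-slab; NaN marks empty slabs."""

    z_grid: np.ndarray  # slab centres, nm, strictly increasing
    r_min: np.ndarray  # nm, >= 0 or NaN
    metadata: str = "slab minimum (atom radial distance minus vdW radius); probe-independent"


def derive_pore_region(
    topology: Topology,
    frame_coords: np.ndarray,
    margin: float = 0.0,
    radial_bound: float | None = None,
) -> PoreRegion:
    """Pore region from the peptide geometry of one frame.

    z-limits are the mean z of the two terminal-ring backbone planes,
    widened by ``margin`` at both ends; the axis passes through the backbone
    centroid.  ``radial_bound`` defaults to the mean backbone ring radius
    (the lumen boundary).
    """
    backbone = np.isin(topology.roles, ("backbone",))
    if not backbone.any() or topology.n_rings == 0:
        raise ValueError("no peptide ring atoms in topology")
    coords = frame_coords[backbone]
    rings = topology.ring_index[backbone]
    center_xy = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
    z_first = coords[rings == rings.min(), 2].mean()
    z_last = coords[rings == rings.max(), 2].mean()
    z_lo, z_hi = sorted((z_first, z_last))
    if radial_bound is None:
        radial = np.hypot(coords[:, 0] - center_xy[0], coords[:, 1] - center_xy[1])
        radial_bound = float(radial.mean())
    return PoreRegion(center_xy, z_lo - margin, z_hi + margin, radial_bound)


def radius_profile(
    frame_coords: np.ndarray,
    pore_atoms: AtomGroup,
    z_spacing: float = 0.05,
    vdw_map: dict[str, float] | None = None,
    center_xy: tuple[float, float] | None = None,
    z_range: tuple[float, float] | None = None,
) -> RadiusProfile:
    """Minimum pore radius per z-slab for one frame.

    For each half-open slab ``[z, z + dz)`` the radius is the minimum over
    atoms whose z lies in the slab of (radial distance to the axis minus the
    atom's vdW radius), floored at 0.  Slabs containing no atoms are
    recorded as NaN, never as 0.
    """
    if len(pore_atoms) == 0:
        raise ValueError("pore_atoms is empty")
    vdw = dict(DEFAULT_VDW_NM)
    if vdw_map:
        vdw.update(vdw_map)
    pos = frame_coords[pore_atoms.indices]
    elements = pore_atoms.topology.elements[pore_atoms.indices]
    radii = np.array([vdw.get(e, _VDW_FALLBACK) for e in elements])
    if center_xy is None:
        center_xy = (float(pos[:, 0].mean()), float(pos[:, 1].mean()))
    if z_range is None:
        z_range = (float(pos[:, 2].min()), float(pos[:, 2].max()) + 1e-9)
    n_slabs = max(1, int(np.ceil((z_range[1] - z_range[0]) / z_spacing)))
    edges = z_range[0] + z_spacing * np.arange(n_slabs + 1)
    slab = np.floor((pos[:, 2] - z_range[0]) / z_spacing).astype(int)
    in_range = (slab >= 0) & (slab < n_slabs)
    r_atom = np.hypot(pos[:, 0] - center_xy[0], pos[:, 1] - center_xy[1]) - radii
    r_min = np.full(n_slabs, np.inf)
    np.minimum.at(r_min, slab[in_range], r_atom[in_range])
    r_min = np.where(np.isinf(r_min), np.nan, np.maximum(r_min, 0.0))
    return RadiusProfile(z_grid=(edges[:-1] + edges[1:]) / 2, r_min=r_min)


def min_radius(profile: RadiusProfile) -> float:
    """Global minimum radius over defined slabs."""
    if np.all(np.isnan(profile.r_min)):
        raise ValueError("radius profile has no defined slabs")
    return float(np.nanmin(profile.r_min))


def tilt_angle(
    topology: Topology,
    frame_coords: np.ndarray,
) -> tuple[float, float]:
    """Nanotube tilt in degrees at both tube ends.

    The tilt is the angle between the membrane normal (+z) and the vector
    from the centroid of the whole peptide backbone stack to the centroid of
    a terminal ring, folded into [0°, 90°].  Returned as (first-ring end,
    last-ring end).
    """
    backbone = topology.roles == "backbone"
    rings = topology.ring_index[backbone]
    if topology.n_rings < 2:
        raise ValueError("tilt needs at least 2 rings")
    coords = frame_coords[backbone]
    stack_centroid = coords.mean(axis=0)
    out = []
    for ring in (rings.min(), rings.max()):
        v = coords[rings == ring].mean(axis=0) - stack_centroid
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise ValueError("ring centroid coincides with stack centroid")
        cosang = abs(v[2]) / norm  # fold into [0, 90]
        out.append(float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))))
    return out[0], out[1]
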