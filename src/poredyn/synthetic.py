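"""Synthetic trajectories and fixtures with known ground truth.

Every analysis stage in this package is validated against data whose answer
is known by construction:

* :func:`simulate_pore_system` — independent Brownian walkers (waters and
  ions) in a periodic box containing an impermeable membrane slab pierced by
  a cylindrical pore.  The input self-diffusion coefficient, the per-frame
  inside-pore counts and the identities of every entrant are recorded as
  ground truth.
* :func:`build_scpn_topology` — an idealized stack of cyclic-peptide rings
  whose pseudo-amide N–H / C=O sites are placed at H-bond geometry, so the
  number of detectable inter-ring H-bonds equals the arithmetic capacity
  ``amides_per_ring x (n_rings - 1)`` exactly.
* :func:`build_hydration_fixture` — one cation with a constructed first
  hydration shell, for coordination counting.
* :func:`make_density_phantom` — static points drawn from an angular density
  with a chosen rotational symmetry order, for the density-map spectrum.

Walkers do not interact (ideal gas): sufficient for every estimator tested
here, and stated as a limitation in the package docs.  Unit conversion used
throughout: **1 m²/s = 1e6 nm²/ps**.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Topology, Trajectory
from .geometry import PoreRegion
from .util import wrap

#: 1 m^2/s expressed in nm^2/ps
NM2_PER_PS = 1e6

# idealized H-bond geometry for the pseudo-amide sites (nm)
_D_NH = 0.101
_D_NO = 0.290
_D_CO = 0.123


@dataclass
class PoreSystemSpec:
    """Conditions for the Brownian pore-system generator.

    Defaults are a scaled-down analogue of a membrane-embedded nanotube
    system at experimental bulk-water diffusivity (2.3e-9 m²/s): a 6 nm box,
    a 2 nm membrane slab pierced by a 0.5 nm pore, 2000 waters and
    physiological-scale ion counts, 500 steps of 1 ps.
    """

    D_water: float = 2.3e-9  # m^2/s
    box: tuple[float, float, float] = (6.0, 6.0, 6.0)  # nm
    membrane_slab: tuple[float, float] | None = (2.0, 4.0)  # nm, None = free box
    pore_radius: float = 0.5  # nm
    n_waters: int = 2000
    n_cations: int = 20
    n_anions: int = 20
    anion_pore_penalty: float = 0.0  # probability of rejecting an anion step into the pore
    dt: float = 1.0  # ps
    n_steps: int = 500
    seed: int = 0

    def validate(self) -> None:
        """Raise ValueError naming every nonphysical field."""
        bad = []
        if self.D_water < 0:
            bad.append("D_water < 0")
        if any(b <= 0 for b in self.box):
            bad.append("box lengths must be > 0")
        if self.membrane_slab is not None:
            z_lo, z_hi = self.membrane_slab
            if not (0 <= z_lo < z_hi <= self.box[2]):
                bad.append("membrane_slab must satisfy 0 <= z_lo < z_hi <= box_z")
        if not (0 <= self.pore_radius < min(self.box[0], self.box[1]) / 2):
            bad.append("pore_radius must be in [0, min(box_x, box_y)/2)")
        if min(self.n_waters, self.n_cations, self.n_anions) < 0:
            bad.append("particle counts must be >= 0")
        if not 0 <= self.anion_pore_penalty <= 1:
            bad.append("anion_pore_penalty must be in [0, 1]")
        if (
            self.membrane_slab is not None
            and self.pore_radius == 0
            and self.membrane_slab[0] <= 0
            and self.membrane_slab[1] >= self.box[2]
        ):
            bad.append("slab spans the whole box with pore_radius 0: no accessible volume")
        if self.dt <= 0:
            bad.append("dt must be > 0")
        if self.n_steps < 1:
            bad.append("n_steps must be >= 1")
        if bad:
            raise ValueError("invalid PoreSystemSpec: " + "; ".join(bad))

    @property
    def step_sigma(self) -> float:
        """Per-axis Gaussian step std in nm: sqrt(2 D dt)."""
        return float(np.sqrt(2.0 * self.D_water * NM2_PER_PS * self.dt))

    def pore_region(self) -> PoreRegion | None:
        if self.membrane_slab is None:
            return None
        return PoreRegion(
            center_xy=(self.box[0] / 2, self.box[1] / 2),
            z_lo=self.membrane_slab[0],
            z_hi=self.membrane_slab[1],
            radial_bound=self.pore_radius if self.pore_radius > 0 else 1e-12,
        )


@dataclass
class GroundTruth:
    """What the generator knows that an analysis must recover."""

    D_water: float  # m^2/s as supplied
    region: PoreRegion | None
    inside_counts_water: np.ndarray  # per frame
    inside_counts_cation: np.ndarray
    inside_counts_anion: np.ndarray
    entrant_waters: set[int] = field(default_factory=set)  # atom ids ever inside
    entrant_cations: set[int] = field(default_factory=set)
    entrant_anions: set[int] = field(default_factory=set)


@dataclass
class PoreSystem:
    topology: Topology
    trajectory: Trajectory
    truth: GroundTruth


def _pore_topology(n_waters: int, n_cations: int, n_anions: int) -> Topology:
    names, resnames, resids, elements, roles = [], [], [], [], []
    rid = 0
    for _ in range(n_waters):
        rid += 1
        names.append("OW")
        resnames.append("SOL")
        resids.append(rid)
        elements.append("O")
        roles.append("water_oxygen")
    for _ in range(n_cations):
        rid += 1
        names.append("NA")
        resnames.append("NA")
        resids.append(rid)
        elements.append("Na")
        roles.append("cation")
    for _ in range(n_anions):
        rid += 1
        names.append("CL")
        resnames.append("CL")
        resids.append(rid)
        elements.append("Cl")
        roles.append("anion")
    n = len(names)
    return Topology(
        atom_names=np.array(names, dtype=object),
        residue_names=np.array(resnames, dtype=object),
        residue_ids=np.array(resids, dtype=int),
        elements=np.array(elements, dtype=object),
        roles=np.array(roles, dtype=object),
        ring_index=np.full(n, -1, dtype=int),
    )


def _forbidden(pts: np.ndarray, spec: PoreSystemSpec) -> np.ndarray:
    """Inside the membrane slab but outside the pore cylinder."""
    if spec.membrane_slab is None:
        return np.zeros(len(pts), dtype=bool)
    z_lo, z_hi = spec.membrane_slab
    in_slab = (pts[:, 2] >= z_lo) & (pts[:, 2] < z_hi)
    dx = pts[:, 0] - spec.box[0] / 2
    dy = pts[:, 1] - spec.box[1] / 2
    out_pore = dx * dx + dy * dy >= spec.pore_radius**2
    return in_slab & out_pore


def _reflect_step(old: np.ndarray, step: np.ndarray, spec: PoreSystemSpec) -> np.ndarray:
    """Legalize one particle step by iterative specular reflection.

    ``old`` is a legal wrapped position.  Reflections are applied off the
    slab faces (z) and off the pore cylinder wall (radial fold about the
    wall) until the endpoint is legal, up to 8 times; a step that cannot be
    classified is rejected (particle stays), which also preserves the
    uniform equilibrium density.
    """
    z_lo, z_hi = spec.membrane_slab
    box = np.asarray(spec.box)
    cx, cy = box[0] / 2, box[1] / 2
    p = old + step  # unwrapped, local to old
    for _ in range(8):
        q = wrap(p[None], box)[0]
        if not _forbidden(q[None], spec)[0]:
            return q
        moved = False
        # crossed a slab face from the bulk side
        if old[2] < z_lo and p[2] >= z_lo:
            p[2] = 2 * z_lo - p[2]
            moved = True
        elif old[2] >= z_hi and p[2] < z_hi:
            p[2] = 2 * z_hi - p[2]
            moved = True
        else:
            # inside the pore, hit the cylinder wall: fold radially
            r_new = np.hypot(p[0] - cx, p[1] - cy)
            if r_new >= spec.pore_radius and r_new > 0:
                r_fold = 2 * spec.pore_radius - r_new
                if r_fold > 0:
                    p[0] = cx + (p[0] - cx) * r_fold / r_new
                    p[1] = cy + (p[1] - cy) * r_fold / r_new
                    moved = True
        if not moved:
            return old
    return old


def _init_positions(n: int, spec: PoreSystemSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform positions over the accessible region (rejection sampling)."""
    box = np.asarray(spec.box)
    pts = rng.uniform(0, 1, size=(n, 3)) * box
    bad = _forbidden(pts, spec)
    while bad.any():
        pts[bad] = rng.uniform(0, 1, size=(int(bad.sum()), 3)) * box
        bad = _forbidden(pts, spec)
    return pts


def simulate_pore_system(spec: PoreSystemSpec) -> PoreSystem:
    """Brownian walkers in a periodic box with a slab + pore obstacle.

    Each particle performs independent Gaussian steps with per-axis variance
    ``2 D dt``.  Steps ending inside the membrane slab but outside the pore
    cylinder are specularly reflected; anion steps *entering* the pore
    region are additionally rejected with probability
    ``anion_pore_penalty``.  Coordinates are wrapped into the primary box.

    Randomness uses named substreams spawned from ``spec.seed`` in a fixed
    order (init, steps, anion gate), so replicas differ only by seed and
    reruns are bit-reproducible.
    """
    spec.validate()
    n_total = spec.n_waters + spec.n_cations + spec.n_anions
    topology = _pore_topology(spec.n_waters, spec.n_cations, spec.n_anions)
    ss_init, ss_steps, ss_gate = np.random.SeedSequence(spec.seed).spawn(3)
    rng_init = np.random.default_rng(ss_init)
    rng_steps = np.random.default_rng(ss_steps)
    rng_gate = np.random.default_rng(ss_gate)

    box = np.asarray(spec.box, dtype=float)
    region = spec.pore_region()
    coords = np.empty((spec.n_steps + 1, n_total, 3))
    coords[0] = _init_positions(n_total, spec, rng_init)
    sigma = spec.step_sigma
    is_anion = np.asarray(topology.roles) == "anion"
    anion_idx = np.nonzero(is_anion)[0]

    for t in range(spec.n_steps):
        old = coords[t]
        steps = rng_steps.normal(0.0, sigma, size=(n_total, 3)) if sigma > 0 else np.zeros((n_total, 3))
        new = wrap(old + steps, box)
        # anion selectivity gate: reject entries into the pore region
        if region is not None and spec.anion_pore_penalty > 0 and len(anion_idx):
            gate = rng_gate.uniform(size=len(anion_idx))
            was_in = region.contains(old[anion_idx])
            now_in = region.contains(new[anion_idx])
            rejected = anion_idx[(~was_in) & now_in & (gate < spec.anion_pore_penalty)]
            new[rejected] = old[rejected]
            steps[rejected] = 0.0
        bad = _forbidden(new, spec)
        for i in np.nonzero(bad)[0]:
            new[i] = _reflect_step(old[i], steps[i], spec)
        coords[t + 1] = new

    traj = Trajectory(
        coords=coords,
        box=np.tile(box, (spec.n_steps + 1, 1)),
        times=spec.dt * np.arange(spec.n_steps + 1),
    )
    truth = _bookkeep(topology, traj, region, spec.D_water)
    return PoreSystem(topology=topology, trajectory=traj, truth=truth)


def _bookkeep(topology: Topology, traj: Trajectory, region: PoreRegion | None, d_water: float) -> GroundTruth:
    n_frames = traj.n_frames
    counts = {r: np.zeros(n_frames, dtype=int) for r in ("water_oxygen", "cation", "anion")}
    entrants: dict[str, set[int]] = {r: set() for r in counts}
    if region is not None:
        for role in counts:
            idx = np.nonzero(topology.roles == role)[0]
            if len(idx) == 0:
                continue
            for f in range(n_frames):
                inside = region.contains(traj.coords[f, idx])
                counts[role][f] = int(inside.sum())
                entrants[role].update(int(i) for i in idx[inside])
    return GroundTruth(
        D_water=d_water,
        region=region,
        inside_counts_water=counts["water_oxygen"],
        inside_counts_cation=counts["cation"],
        inside_counts_anion=counts["anion"],
        entrant_waters=entrants["water_oxygen"],
        entrant_cations=entrants["cation"],
        entrant_anions=entrants["anion"],
    )


# ---------------------------------------------------------------------------
# Idealized stacked-ring peptide topology
# ---------------------------------------------------------------------------


@dataclass
class ScpnSpec:
    """Idealized stacked cyclic-peptide nanotube.

    Each ring carries ``amides_per_ring`` pseudo-amide units (N, H, C, O
    sites on a circle of ``ring_radius``); adjacent rings are placed
    ``ring_spacing`` apart with donors and acceptors aligned at H-bond
    geometry, so the detectable inter-ring H-bond count equals
    ``amides_per_ring x (n_rings - 1)`` by construction.  ``antiparallel``
    stacking alternates the donation direction between neighbouring amides;
    ``parallel`` has every ring donating upward.
    """

    n_rings: int = 8
    residues_per_ring: int = 8
    amides_per_ring: int = 8
    ring_spacing: float = 0.48  # nm
    ring_radius: float = 0.50  # nm
    stacking: str = "antiparallel"

    def validate(self) -> None:
        bad = []
        if self.n_rings < 1:
            bad.append("n_rings must be >= 1")
        if self.amides_per_ring < 1:
            bad.append("amides_per_ring must be >= 1")
        if self.ring_spacing <= _D_NO + _D_CO:
            bad.append(f"ring_spacing must exceed {_D_NO + _D_CO} nm")
        if self.ring_radius <= 0:
            bad.append("ring_radius must be > 0")
        if self.stacking not in ("parallel", "antiparallel"):
            bad.append("stacking must be 'parallel' or 'antiparallel'")
        if bad:
            raise ValueError("invalid ScpnSpec: " + "; ".join(bad))

    @property
    def capacity(self) -> int:
        """Inter-ring H-bond capacity: amides_per_ring x (n_rings - 1)."""
        return self.amides_per_ring * (self.n_rings - 1)


def build_scpn_topology(spec: ScpnSpec, z0: float = 2.0) -> tuple[Topology, np.ndarray, np.ndarray]:
    """Idealized SCPN: topology, single-frame coords (nm) and a box.

    Per amide j on ring k the donation direction is +z for parallel
    stacking (every N–H points up toward the acceptor C=O of the ring
    above) and alternates with j for antiparallel stacking.  Atom order per
    amide is N, H, C, O so donor hydrogens resolve by file order.
    """
    spec.validate()
    m, n = spec.amides_per_ring, spec.n_rings
    theta = 2 * np.pi * np.arange(m) / m
    names, resnames, resids, elements, roles, rings = [], [], [], [], [], []
    xyz = []
    cx = cy = max(4.0, 2 * spec.ring_radius + 2.0) / 2
    for k in range(n):
        z_k = z0 + k * spec.ring_spacing
        for j in range(m):
            u = 1.0 if (spec.stacking == "parallel" or j % 2 == 0) else -1.0
            x = cx + spec.ring_radius * np.cos(theta[j])
            y = cy + spec.ring_radius * np.sin(theta[j])
            sites = {
                "N": z_k,
                "H": z_k + u * _D_NH,
                "C": z_k - u * (spec.ring_spacing - _D_NO - _D_CO),
                "O": z_k - u * (spec.ring_spacing - _D_NO),
            }
            for name, z in sites.items():
                names.append(name)
                resnames.append("CPR")
                resids.append(k + 1)
                elements.append(name)
                roles.append("backbone")
                rings.append(k)
                xyz.append((x, y, z))
    topology = Topology(
        atom_names=np.array(names, dtype=object),
        residue_names=np.array(resnames, dtype=object),
        residue_ids=np.array(resids, dtype=int),
        elements=np.array(elements, dtype=object),
        roles=np.array(roles, dtype=object),
        ring_index=np.array(rings, dtype=int),
    )
    coords = np.asarray(xyz, dtype=float)
    box = np.array([2 * cx, 2 * cy, z0 + n * spec.ring_spacing + z0])
    return topology, coords, box


# ---------------------------------------------------------------------------
# Static fixtures
# ---------------------------------------------------------------------------


def _fibonacci_directions(n: int, phase: float = 0.0) -> np.ndarray:
    """n well-separated unit vectors (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + np.sqrt(5))
    theta = golden * i + phase
    return np.stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)


def build_hydration_fixture(
    n_shell: int,
    r_shell: float,
    n_far: int = 0,
    r_far: float = 1.0,
    min_separation: float = 0.05,
) -> tuple[Topology, np.ndarray, np.ndarray]:
    """One cation at the box centre with constructed oxygen shells.

    ``n_shell`` water oxygens sit at exactly ``r_shell`` in well-separated
    directions and ``n_far`` at ``r_far``.  Raises if any two placements come
    closer than ``min_separation``.
    """
    if n_far > 0 and not r_far > r_shell:
        raise ValueError("r_far must exceed r_shell")
    half = max(2.0, r_far + 1.0)
    center = np.array([half, half, half])
    pts = [center]
    if n_shell:
        pts.extend(center + r_shell * _fibonacci_directions(n_shell))
    if n_far:
        pts.extend(center + r_far * _fibonacci_directions(n_far, phase=1.234))
    coords = np.asarray(pts)
    if len(coords) > 1:
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < min_separation:
            raise ValueError("overlapping placements in hydration fixture")
    n_ox = n_shell + n_far
    topology = Topology(
        atom_names=np.array(["NA"] + ["OW"] * n_ox, dtype=object),
        residue_names=np.array(["NA"] + ["SOL"] * n_ox, dtype=object),
        residue_ids=np.arange(1, n_ox + 2),
        elements=np.array(["Na"] + ["O"] * n_ox, dtype=object),
        roles=np.array(["cation"] + ["water_oxygen"] * n_ox, dtype=object),
        ring_index=np.full(n_ox + 1, -1, dtype=int),
    )
    return topology, coords, np.full(3, 2 * half)


def make_density_phantom(
    symmetry_order: int,
    n_points: int,
    seed: int,
    amplitude: float = 1.0,
    radius_band: tuple[float, float] = (0.3, 0.6),
) -> tuple[Topology, Trajectory, int]:
    """Static points with angular density ∝ 1 + amplitude·cos(k·θ).

    Returns a water-oxygen topology, a single-frame trajectory centred in a
    2x2x1 nm box, and the ground-truth symmetry order.  ``amplitude = 0``
    gives a rotationally uniform ring.
    """
    if symmetry_order < 1:
        raise ValueError("symmetry_order must be >= 1")
    if not 0 <= amplitude <= 1:
        raise ValueError("amplitude must be in [0, 1]")
    rng = np.random.default_rng(seed)
    theta = np.empty(n_points)
    filled = 0
    while filled < n_points:  # rejection sampling of the angular density
        cand = rng.uniform(0, 2 * np.pi, size=2 * (n_points - filled))
        accept = rng.uniform(0, 1 + amplitude, size=len(cand)) < 1 + amplitude * np.cos(symmetry_order * cand)
        kept = cand[accept][: n_points - filled]
        theta[filled : filled + len(kept)] = kept
        filled += len(kept)
    r = rng.uniform(radius_band[0], radius_band[1], size=n_points)
    box = np.array([2.0, 2.0, 1.0])
    coords = np.stack(
        [box[0] / 2 + r * np.cos(theta), box[1] / 2 + r * np.sin(theta), np.full(n_points, box[2] / 2)],
        axis=1,
    )
    topology = Topology(
        atom_names=np.array(["OW"] * n_points, dtype=object),
        residue_names=np.array(["SOL"] * n_points, dtype=object),
        residue_ids=np.arange(1, n_points + 1),
        elements=np.array(["O"] * n_points, dtype=object),
        roles=np.array(["water_oxygen"] * n_points, dtype=object),
        ring_index=np.full(n_points, -1, dtype=int),
    )
    traj = Trajectory(coords=coords[None], box=box[None], times=np.zeros(1))
    return topology, traj, symmetry_order
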