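"""Geometric hydrogen-bond detection, group counting and lifetime kinetics.

A bond is the triplet (donor heavy atom D, its hydrogen H, acceptor A)
satisfying a distance-plus-linearity criterion.  Defaults follow the common
geometric convention: D–A distance <= 0.35 nm and deviation of D–H···A from
linearity <= 30 degrees, both configurable.  All distances use the
minimum-image convention.

Lifetime kinetics are reported as the *intermittent* autocorrelation
c(t) = <h(t0) h(t0+t)> / <h(t0)>, where h indicates bond presence and the
bond may break and reform between t0 and t0+t; the stricter *continuous*
variant (the bond must persist through every intermediate frame) is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import AtomGroup, Topology, Trajectory
from .util import minimum_image, wrap


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 0.35  # nm, donor-acceptor
    max_angle: float = 30.0  # degrees, deviation of D-H...A from linear

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be > 0")
        if not 0 < self.max_angle <= 90:
            raise ValueError("max_angle must be in (0, 90]")


@dataclass
class HBondOccupancy:
    """Presence matrix for every bond ever observed in a trajectory."""

    bonds: list[tuple[int, int, int]]  # (donor, hydrogen, acceptor) atom ids
    presence: np.ndarray  # (n_bonds, n_frames) bool
    times: np.ndarray  # ps


@dataclass
class ACFCurve:
    lags: np.ndarray  # ps
    values: np.ndarray  # [0, 1]


def donor_hydrogens(topology: Topology) -> dict[int, list[int]]:
    """Map each N/O heavy atom to its bonded hydrogens by file order.

    Each hydrogen attaches to the most recent preceding non-hydrogen atom
    of its residue — the layout standard PDB/GRO writers emit.  Heavy atoms
    with no trailing hydrogens simply do not appear (pure acceptors).
    """
    parents: dict[int, list[int]] = {}
    last_heavy = -1
    last_rid = None
    for i in range(topology.n_atoms):
        rid = topology.residue_ids[i]
        if rid != last_rid:
            last_heavy = -1
            last_rid = rid
        if topology.elements[i] == "H":
            if last_heavy >= 0 and topology.elements[last_heavy] in ("N", "O"):
                parents.setdefault(last_heavy, []).append(i)
        else:
            last_heavy = i
    return parents


def detect_hbonds(
    frame_coords: np.ndarray,
    box: np.ndarray,
    donors: AtomGroup,
    acceptors: AtomGroup,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[tuple[int, int, int]]:
    """All (D, H, A) triplets meeting the geometric criterion in one frame.

    ``donors`` is a heavy-atom group; hydrogens are resolved from the
    topology (donors without a bonded hydrogen are skipped).  Neighbour
    search is a periodic k-d tree on the acceptor positions.
    """
    topology = donors.topology
    box = np.asarray(box, dtype=float)
    parents = donor_hydrogens(topology)
    donor_ids = [int(d) for d in donors.indices if int(d) in parents]
    if not donor_ids or len(acceptors) == 0:
        return []
    pos = wrap(frame_coords, box)
    acc_ids = acceptors.indices
    tree = cKDTree(pos[acc_ids], boxsize=box)
    neighbours = tree.query_ball_point(pos[donor_ids], r=criteria.max_da_distance)
    out: list[tuple[int, int, int]] = []
    cos_min = np.cos(np.radians(criteria.max_angle))
    for d, hits in zip(donor_ids, neighbours):
        if not hits:
            continue
        for h in parents[d]:
            dh = minimum_image(pos[h] - pos[d], box)
            dh_norm = np.linalg.norm(dh)
            for ai in hits:
                a = int(acc_ids[ai])
                if a == d or a == h:
                    continue
                ha = minimum_image(pos[a] - pos[h], box)
                denom = dh_norm * np.linalg.norm(ha)
                if denom <= 0:
                    continue
                # deviation from linear D-H...A = angle between D->H and H->A
                if np.dot(dh, ha) / denom >= cos_min:
                    out.append((d, h, a))
    return sorted(out)


def count_hbonds_between(
    traj: Trajectory,
    group_a: AtomGroup,
    group_b: AtomGroup,
    criteria: HBondCriteria = HBondCriteria(),
    t_start: float = 0.0,
) -> tuple[float, float]:
    """Time-averaged H-bond count between two groups (both directions pooled).

    Counts bonds with the donor in one group and the acceptor in the other;
    with ``group_a is group_b`` this is the intra-group count.  Returns the
    mean and sd over frames with ``time >= t_start``.
    """
    per_frame = per_frame_hbond_counts(traj, group_a, group_b, criteria)
    sel = traj.times >= t_start
    if not sel.any():
        raise ValueError("no frames at or after t_start")
    vals = per_frame[sel]
    return float(vals.mean()), float(vals.std(ddof=0))


def per_frame_hbond_counts(
    traj: Trajectory,
    group_a: AtomGroup,
    group_b: AtomGroup,
    criteria: HBondCriteria = HBondCriteria(),
) -> np.ndarray:
    counts = np.zeros(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        counts[f] = len(_bonds_between(traj.coords[f], traj.box[f], group_a, group_b, criteria))
    return counts


def _bonds_between(frame_coords, box, group_a, group_b, criteria) -> set[tuple[int, int, int]]:
    bonds = set(detect_hbonds(frame_coords, box, group_a, group_b, criteria))
    if group_a.indices is not group_b.indices:
        bonds |= set(detect_hbonds(frame_coords, box, group_b, group_a, criteria))
    return bonds


def max_backbone_capacity(n_rings: int, amides_per_ring: int) -> int:
    """Ideal inter-ring backbone H-bond count: amides_per_ring x (n_rings - 1).

    Each pair of adjacent rings in the stack can form one H-bond per amide,
    so a stack of n rings has n - 1 bonded interfaces.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    if amides_per_ring < 1:
        raise ValueError("amides_per_ring must be >= 1")
    return amides_per_ring * (n_rings - 1)


def hbond_occupancy(
    traj: Trajectory,
    donors: AtomGroup,
    acceptors: AtomGroup,
    criteria: HBondCriteria = HBondCriteria(),
) -> HBondOccupancy:
    """Presence matrix over all bonds observed anywhere in the trajectory."""
    per_frame: list[set[tuple[int, int, int]]] = []
    universe: dict[tuple[int, int, int], int] = {}
    for f in range(traj.n_frames):
        bonds = set(detect_hbonds(traj.coords[f], traj.box[f], donors, acceptors, criteria))
        for b in bonds:
            universe.setdefault(b, len(universe))
        per_frame.append(bonds)
    presence = np.zeros((len(universe), traj.n_frames), dtype=bool)
    for f, bonds in enumerate(per_frame):
        for b in bonds:
            presence[universe[b], f] = True
    ordered = sorted(universe, key=universe.get)
    return HBondOccupancy(bonds=ordered, presence=presence, times=traj.times.copy())


def intermittent_acf(
    occupancy: HBondOccupancy | np.ndarray,
    dt: float | None = None,
    max_lag: float | None = None,
    continuous: bool = False,
) -> ACFCurve:
    """Bond-lifetime autocorrelation c(t), averaged over bonds and origins.

    c(t) = sum_bonds sum_t0 h(t0) h(t0+t) / sum_bonds sum_t0 h(t0), with t0
    running over every frame that leaves room for the lag (maximal
    averaging), so c(0) = 1 and c stays in [0, 1].  With
    ``continuous=True`` the product requires presence at every intermediate
    frame as well.
    """
    if isinstance(occupancy, HBondOccupancy):
        presence = occupancy.presence
        if dt is None:
            dt = float(occupancy.times[1] - occupancy.times[0]) if len(occupancy.times) > 1 else 1.0
    else:
        presence = np.asarray(occupancy, dtype=bool)
        if dt is None:
            dt = 1.0
    if presence.size == 0 or not presence.any():
        raise ValueError("no bonds observed")
    n_frames = presence.shape[1]
    max_lag_frames = n_frames - 1 if max_lag is None else min(n_frames - 1, int(round(max_lag / dt)))
    h = presence.astype(float)
    if continuous:
        # running product: h_cont[:, t0, L] nonzero only for unbroken runs
        values = np.empty(max_lag_frames + 1)
        run = h.copy()
        values[0] = 1.0
        denom_all = h.sum()
        for lag in range(1, max_lag_frames + 1):
            run = run[:, :-1] * h[:, lag:]
            denom = h[:, : n_frames - lag].sum()
            values[lag] = run.sum() / denom if denom > 0 else 0.0
        return ACFCurve(lags=dt * np.arange(max_lag_frames + 1), values=values)
    values = np.empty(max_lag_frames + 1)
    for lag in range(max_lag_frames + 1):
        num = (h[:, : n_frames - lag] * h[:, lag:]).sum()
        den = h[:, : n_frames - lag].sum()
        values[lag] = num / den if den > 0 else 0.0
    return ACFCurve(lags=dt * np.arange(max_lag_frames + 1), values=values)
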