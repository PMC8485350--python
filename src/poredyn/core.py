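"""Data model and I/O for molecular systems and trajectories.

Internal conventions (GROMACS-style) used throughout the package:

* lengths in **nm**, times in **ps**, angles reported in degrees;
* 0-based atom and frame indices everywhere in memory; 1-based numbering
  appears only inside file records where the format demands it;
* orthorhombic boxes only — triclinic input raises :class:`UnsupportedBoxError`.

The :class:`Topology` assigns every atom a *role* (backbone, sidechain,
water_oxygen, water_hydrogen, cation, anion, lipid_phosphorus, other) from a
configurable residue/atom-name mapping, and a *ring index* identifying which
stacked cyclic peptide an atom belongs to (``-1`` for non-peptide atoms).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

ROLES = (
    "backbone",
    "sidechain",
    "water_oxygen",
    "water_hydrogen",
    "cation",
    "anion",
    "lipid_phosphorus",
    "other",
)

#: residue names recognised as water models (3- and 4/5-site alike)
WATER_RESIDUES = frozenset({"SOL", "HOH", "WAT", "TIP3", "TIP4", "TIP5", "T3P", "T4P", "OPC", "SPC"})
CATION_RESIDUES = frozenset({"NA", "NA+", "SOD", "K", "K+", "POT"})
ANION_RESIDUES = frozenset({"CL", "CL-", "CLA"})
LIPID_RESIDUES = frozenset({"POPC", "POPE", "POPG", "DPPC", "DOPC", "DMPC"})
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class ParseError(ValueError):
    """A structure/trajectory file violated its format."""


class UnsupportedBoxError(ValueError):
    """Raised for triclinic (non-orthorhombic) simulation boxes."""


@dataclass(frozen=True)
class RoleMap:
    """Residue/atom-name rules used to assign atom roles.

    Parameters
    ----------
    water_residues, cation_residues, anion_residues, lipid_residues
        Residue names mapped to the corresponding roles.  Within a water
        residue, atoms whose element is O become ``water_oxygen`` and H
        atoms ``water_hydrogen``; within a lipid residue only phosphorus
        becomes ``lipid_phosphorus`` (the rest are ``other``).
    peptide_residues
        Residue names treated as cyclic-peptide units.  Their atoms split
        into ``backbone``/``sidechain`` by ``backbone_names``; these are the
        only atoms that receive a ring index.
    backbone_names
        Atom names considered backbone within peptide residues.  The default
        covers amide N/H, the alpha-carbon and the carbonyl C/O, which is
        also the sensible choice for non-natural gamma/delta residues whose
        ring-forming amides carry the same names.
    """

    water_residues: frozenset = WATER_RESIDUES
    cation_residues: frozenset = CATION_RESIDUES
    anion_residues: frozenset = ANION_RESIDUES
    lipid_residues: frozenset = LIPID_RESIDUES
    peptide_residues: frozenset = frozenset(STANDARD_AMINO_ACIDS | {"CPR"})
    backbone_names: frozenset = frozenset({"N", "H", "HN", "CA", "C", "O"})


DEFAULT_ROLE_MAP = RoleMap()


def _element_from_name(name: str) -> str:
    """Best-effort element symbol from an atom name (PDB/GRO convention)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Na", "Cl", "Mg", "Ca", "Br"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def assign_roles(
    atom_names: Sequence[str],
    residue_names: Sequence[str],
    elements: Sequence[str],
    role_map: RoleMap = DEFAULT_ROLE_MAP,
) -> np.ndarray:
    """Assign a role string to every atom by residue/atom-name rules.

    Unknown residues map to ``other`` with a logged warning (once per name).
    """
    roles = np.empty(len(atom_names), dtype=object)
    warned: set[str] = set()
    for i, (aname, rname, elem) in enumerate(zip(atom_names, residue_names, elements)):
        rname_u = rname.upper()
        if rname_u in role_map.water_residues:
            if elem == "O":
                roles[i] = "water_oxygen"
            elif elem == "H":
                roles[i] = "water_hydrogen"
            else:
                roles[i] = "other"  # virtual sites of 4/5-site models
        elif rname_u in role_map.cation_residues:
            roles[i] = "cation"
        elif rname_u in role_map.anion_residues:
            roles[i] = "anion"
        elif rname_u in role_map.lipid_residues:
            roles[i] = "lipid_phosphorus" if elem == "P" else "other"
        elif rname_u in role_map.peptide_residues:
            roles[i] = "backbone" if aname.strip().upper() in role_map.backbone_names else "sidechain"
        else:
            if rname_u not in warned:
                logger.warning("unknown residue %r: assigning role 'other'", rname)
                warned.add(rname_u)
            roles[i] = "other"
    return roles


@dataclass
class Topology:
    """Static description of the system: names, residues, roles, rings.

    ``ring_index`` is ``-1`` exactly for non-peptide atoms and otherwise in
    ``0..n_rings-1`` identifying the stacked cyclic peptide.
    """

    atom_names: np.ndarray
    residue_names: np.ndarray
    residue_ids: np.ndarray
    elements: np.ndarray
    roles: np.ndarray
    ring_index: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for attr in ("residue_names", "residue_ids", "elements", "roles", "ring_index"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length mismatch with atom_names")
        bad = set(np.unique(self.roles)) - set(ROLES)
        if bad:
            raise ValueError(f"undefined roles: {sorted(bad)}")
        peptide = np.isin(self.roles, ("backbone", "sidechain"))
        if np.any((self.ring_index >= 0) != peptide):
            raise ValueError("ring_index must be set exactly for peptide atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def atom_ids(self) -> np.ndarray:
        return np.arange(self.n_atoms)

    @property
    def n_rings(self) -> int:
        return int(self.ring_index.max()) + 1 if np.any(self.ring_index >= 0) else 0

    def water_hydrogens_of(self, oxygen_id: int) -> np.ndarray:
        """Atom ids of the hydrogens bonded to a water oxygen (0 or 2).

        Hydrogens are resolved by file order: the H atoms of the same
        residue that directly follow the oxygen, the layout every standard
        GRO/PDB writer emits.
        """
        out = []
        rid = self.residue_ids[oxygen_id]
        j = oxygen_id + 1
        while j < self.n_atoms and self.residue_ids[j] == rid and len(out) < 2:
            if self.roles[j] == "water_hydrogen":
                out.append(j)
            j += 1
        return np.asarray(out, dtype=int)


@dataclass
class AtomGroup:
    """A sorted, duplicate-free set of atom ids referencing a topology."""

    topology: Topology
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if idx.size and (idx[0] < 0 or idx[-1] >= self.topology.n_atoms):
            raise IndexError("atom id outside topology")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates in nm on a uniform time grid in ps."""

    coords: np.ndarray  # (n_frames, n_atoms, 3) nm
    box: np.ndarray  # (n_frames, 3) nm, orthorhombic
    times: np.ndarray  # (n_frames,) ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.box.shape != (self.n_frames, 3) or np.any(self.box <= 0):
            raise ValueError("box must be (n_frames, 3) with positive lengths")
        if len(self.times) != self.n_frames:
            raise ValueError("times length mismatch")
        if self.n_frames > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise ValueError("dt undefined for a single frame")
        return float(self.times[1] - self.times[0])


# ---------------------------------------------------------------------------
# GRO I/O (native): fixed-column format, multi-frame by concatenation.
# MDAnalysis reads only the first frame of a concatenated GRO, hence the
# native reader here; PDB and compressed formats go through MDAnalysis.
# ---------------------------------------------------------------------------


def _parse_gro_frame(lines: list[str], offset: int) -> tuple[dict, int]:
    title = lines[offset]
    try:
        n_atoms = int(lines[offset + 1])
    except (IndexError, ValueError):
        raise ParseError(f"line {offset + 2}: expected atom count")
    start = offset + 2
    end = start + n_atoms
    if end >= len(lines) + 1 or end > len(lines):
        raise ParseError(f"line {start + 1}: truncated frame ({n_atoms} atoms expected)")
    resids, resnames, names, xyz = [], [], [], np.empty((n_atoms, 3))
    for i, ln in enumerate(lines[start:end]):
        try:
            resids.append(int(ln[0:5]))
            resnames.append(ln[5:10].strip())
            names.append(ln[10:15].strip())
            xyz[i, 0] = float(ln[20:28])
            xyz[i, 1] = float(ln[28:36])
            xyz[i, 2] = float(ln[36:44])
        except (ValueError, IndexError):
            raise ParseError(f"line {start + i + 1}: malformed GRO atom record: {ln!r}")
    try:
        box_fields = [float(x) for x in lines[end].split()]
    except (IndexError, ValueError):
        raise ParseError(f"line {end + 1}: malformed GRO box line")
    if len(box_fields) not in (3, 9):
        raise ParseError(f"line {end + 1}: box line needs 3 or 9 fields")
    if len(box_fields) == 9 and any(abs(v) > 1e-12 for v in box_fields[3:]):
        raise UnsupportedBoxError("triclinic box not supported")
    time = None
    if "t=" in title:
        try:
            time = float(title.rsplit("t=", 1)[1].split()[0])
        except (ValueError, IndexError):
            time = None
    frame = {
        "title": title,
        "resids": resids,
        "resnames": resnames,
        "names": names,
        "xyz": xyz,
        "box": np.asarray(box_fields[:3]),
        "time": time,
    }
    return frame, end + 1


def read_gro(path: str | Path) -> list[dict]:
    """Read all frames of a (possibly concatenated multi-frame) GRO file."""
    lines = Path(path).read_text().splitlines()
    frames, offset = [], 0
    while offset < len(lines) and lines[offset].strip():
        frame, offset = _parse_gro_frame(lines, offset)
        frames.append(frame)
    if not frames:
        raise ParseError(f"{path}: empty GRO file")
    return frames


def write_gro(
    path: str | Path,
    topology: Topology,
    coords: np.ndarray,
    box: np.ndarray,
    times: np.ndarray | None = None,
    title: str = "poredyn",
) -> None:
    """Write single- or multi-frame GRO (coords nm, %.3f precision)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    box = np.atleast_2d(np.asarray(box, dtype=float))
    if box.shape[0] == 1:
        box = np.repeat(box, coords.shape[0], axis=0)
    with open(path, "w") as fh:
        for f in range(coords.shape[0]):
            t = "" if times is None else f" t= {times[f]:.4f}"
            fh.write(f"{title}{t}\n{topology.n_atoms:5d}\n")
            for i in range(topology.n_atoms):
                resid = int(topology.residue_ids[i]) % 100000
                atomid = (i + 1) % 100000
                fh.write(
                    f"{resid:5d}{topology.residue_names[i]:<5.5s}"
                    f"{topology.atom_names[i]:>5.5s}{atomid:5d}"
                    f"{coords[f, i, 0]:8.3f}{coords[f, i, 1]:8.3f}{coords[f, i, 2]:8.3f}\n"
                )
            fh.write(f"{box[f, 0]:10.5f}{box[f, 1]:10.5f}{box[f, 2]:10.5f}\n")


def write_trajectory_gro(path: str | Path, topology: Topology, traj: Trajectory) -> None:
    write_gro(path, topology, traj.coords, traj.box, times=traj.times)


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("gro", "pdb", "xtc", "trr"):
        return suffix
    raise ValueError(f"cannot infer format of {path}")


def _topology_from_fields(
    names: Sequence[str],
    resnames: Sequence[str],
    resids: Sequence[int],
    role_map: RoleMap,
    residues_per_ring: int | None,
) -> Topology:
    elements = np.array([_element_from_name(n) for n in names], dtype=object)
    roles = assign_roles(names, resnames, elements, role_map)
    ring = _assign_rings(np.asarray(resids), roles, residues_per_ring)
    return Topology(
        atom_names=np.array(names, dtype=object),
        residue_names=np.array(resnames, dtype=object),
        residue_ids=np.asarray(resids, dtype=int),
        elements=elements,
        roles=roles,
        ring_index=ring,
    )


def _assign_rings(resids: np.ndarray, roles: np.ndarray, residues_per_ring: int | None) -> np.ndarray:
    """Ring indices for peptide atoms from residue blocks.

    With ``residues_per_ring`` given, consecutive peptide residues are
    grouped in blocks of that size; otherwise each contiguous run of peptide
    residues (a gap in residue numbering or intervening non-peptide residue
    breaks a run) forms one ring.
    """
    ring = np.full(len(resids), -1, dtype=int)
    peptide = np.isin(roles, ("backbone", "sidechain"))
    if not peptide.any():
        return ring
    pep_resids = np.unique(resids[peptide])
    ring_of_resid: dict[int, int] = {}
    if residues_per_ring is not None:
        for k, rid in enumerate(pep_resids):
            ring_of_resid[rid] = k // residues_per_ring
    else:
        current, prev = 0, None
        for rid in pep_resids:
            if prev is not None and rid != prev + 1:
                current += 1
            ring_of_resid[rid] = current
            prev = rid
    for i in np.nonzero(peptide)[0]:
        ring[i] = ring_of_resid[int(resids[i])]
    return ring


def load_topology(
    path: str | Path,
    format: str | None = None,
    role_map: RoleMap = DEFAULT_ROLE_MAP,
    residues_per_ring: int | None = None,
) -> Topology:
    """Load a :class:`Topology` from a PDB or GRO file.

    Roles come from ``role_map``; ring indices from peptide residue blocks
    (see :func:`_assign_rings`).
    """
    fmt = format or _infer_format(path)
    if fmt == "gro":
        frame = read_gro(path)[0]
        return _topology_from_fields(frame["names"], frame["resnames"], frame["resids"], role_map, residues_per_ring)
    if fmt == "pdb":
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        return _topology_from_fields(
            [str(n) for n in u.atoms.names],
            [str(r) for r in u.atoms.resnames],
            [int(r) for r in u.atoms.resids],
            role_map,
            residues_per_ring,
        )
    raise ValueError(f"unsupported topology format: {fmt}")


def _check_orthorhombic(dimensions: np.ndarray) -> np.ndarray:
    if dimensions is None or np.any(dimensions[:3] <= 0):
        raise ValueError("missing or degenerate box")
    if not np.allclose(dimensions[3:6], 90.0, atol=1e-3):
        raise UnsupportedBoxError("triclinic box not supported")
    return np.asarray(dimensions[:3], dtype=float)


def load_trajectory(
    path: str | Path,
    topology: Topology,
    format: str | None = None,
    time_grid: tuple[float, float] | None = None,
) -> Trajectory:
    """Load a trajectory (multi-frame GRO/PDB, or XTC/TRR via MDAnalysis).

    Coordinates are converted to nm.  Times come from the file when present,
    else from ``time_grid = (t0, dt)`` in ps (default ``(0, 1)``).
    """
    fmt = format or _infer_format(path)
    if fmt == "gro":
        frames = read_gro(path)
        for k, fr in enumerate(frames):
            if fr["xyz"].shape[0] != topology.n_atoms:
                raise ValueError(f"frame {k}: atom count {fr['xyz'].shape[0]} != topology {topology.n_atoms}")
        coords = np.stack([fr["xyz"] for fr in frames])
        box = np.stack([fr["box"] for fr in frames])
        file_times = [fr["time"] for fr in frames]
        if all(t is not None for t in file_times) and len(set(file_times)) == len(file_times):
            times = np.asarray(file_times, dtype=float)
        else:
            t0, dt = time_grid or (0.0, 1.0)
            times = t0 + dt * np.arange(len(frames))
    elif fmt in ("pdb", "xtc", "trr"):
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt == "pdb":
                u = mda.Universe(str(path))
            else:
                u = mda.Universe.empty(topology.n_atoms, trajectory=True)
                u.load_new(str(path))
        if u.atoms.n_atoms != topology.n_atoms:
            raise ValueError(f"atom count {u.atoms.n_atoms} != topology {topology.n_atoms}")
        coords_l, box_l, times_l = [], [], []
        for ts in u.trajectory:
            coords_l.append(u.atoms.positions / 10.0)  # Angstrom -> nm
            box_l.append(_check_orthorhombic(ts.dimensions) / 10.0)
            times_l.append(ts.time)
        coords = np.stack(coords_l)
        box = np.stack(box_l)
        times = np.asarray(times_l, dtype=float)
        if len(times) > 1 and (np.any(np.diff(times) <= 0)):
            t0, dt = time_grid or (0.0, 1.0)
            times = t0 + dt * np.arange(len(times))
        elif time_grid is not None:
            t0, dt = time_grid
            times = t0 + dt * np.arange(len(times))
    else:
        raise ValueError(f"unsupported trajectory format: {fmt}")
    return Trajectory(coords=coords, box=box, times=times)


# ---------------------------------------------------------------------------
# Selection and RMSD
# ---------------------------------------------------------------------------


def select_group(
    topology: Topology,
    role: str | Iterable[str] | None = None,
    ring_index: int | None = None,
    residue_name: str | None = None,
) -> AtomGroup:
    """Select atoms by role and/or ring index and/or residue name.

    Criteria combine with logical AND; no criteria selects all atoms.
    Selection is deterministic (sorted ids) and may be empty.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    if role is not None:
        roles = (role,) if isinstance(role, str) else tuple(role)
        unknown = set(roles) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown role(s): {sorted(unknown)}")
        mask &= np.isin(topology.roles, roles)
    if ring_index is not None:
        mask &= topology.ring_index == ring_index
    if residue_name is not None:
        mask &= topology.residue_names == residue_name
    return AtomGroup(topology, np.nonzero(mask)[0])


def backbone_rmsd(traj: Trajectory, group: AtomGroup, reference: int = 0) -> np.ndarray:
    """Per-frame RMSD (nm) of a group after optimal rigid-body superposition.

    Each frame's group coordinates are superposed onto the reference frame
    (translation to common centroid + Kabsch rotation) before the RMSD is
    taken, so RMSD at the reference frame is 0 and the series is invariant
    to global rotation/translation of any frame.
    """
    if len(group) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    if not (0 <= reference < traj.n_frames):
        raise IndexError("reference frame out of range")
    ref = traj.coords[reference, group.indices]
    ref_c = ref - ref.mean(axis=0)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.coords[f, group.indices]
        mob_c = mob - mob.mean(axis=0)
        _, rssd = Rotation.align_vectors(ref_c, mob_c)
        out[f] = rssd / np.sqrt(len(group))
    return out
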